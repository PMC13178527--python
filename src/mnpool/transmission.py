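"""Linear-transmission analysis: how faithfully a continuous common input is
recovered from the band-filtered cumulative spike train, with and without a
concurrent impulsive common input.

Transmission is quantified as the maximum over lags (bounded to ±1 s) of the
Pearson correlation between the common input and the CST bandpass filtered
(2nd-order Butterworth, 1 Hz bandwidth) around the input frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .spikes import SpikeTrainSet, CumulativeSpikeTrain, cumulative_spike_train

__all__ = [
    "bandpass_cst",
    "max_crosscorrelation",
    "subpool_transmission",
    "TransmissionResult",
]


def bandpass_cst(cst: CumulativeSpikeTrain, centre: float,
                 bandwidth: float = 1.0, order: int = 2) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth bandpass of a CST around ``centre``."""
    lo, hi = centre - bandwidth / 2, centre + bandwidth / 2
    if lo <= 0:
        raise ValueError("band extends to or below 0 Hz")
    if hi >= cst.fs / 2:
        raise ValueError("band outside Nyquist")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=cst.fs, output="sos")
    return sps.sosfiltfilt(sos, cst.samples)


def max_crosscorrelation(x: np.ndarray, y: np.ndarray, fs: float,
                         max_lag: float = 1.0) -> tuple[float, float]:
    """Maximum over lags of the Pearson correlation between ``x`` and the
    lagged ``y``; returns ``(correlation, lag_s)`` with positive lag meaning
    ``y`` trails ``x``.

    The lag search is bounded to ±``max_lag`` (physiological transmission
    delays are far shorter; an unbounded search only inflates the null).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance signal")
    L = int(round(max_lag * fs))
    n = x.size
    best, best_lag = -2.0, 0.0
    for lag in range(-L, L + 1):
        if lag >= 0:
            a, b = x[:n - lag], y[lag:]
        else:
            a, b = x[-lag:], y[:n + lag]
        if a.size < 8:
            continue
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        r = np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)
        if r > best:
            best, best_lag = float(r), lag / fs
    return best, best_lag


def _decimate_to(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    q = int(round(fs / target_fs))
    if q <= 1:
        return x
    return sps.resample_poly(x, 1, q)


def subpool_transmission(sts: SpikeTrainSet, common: np.ndarray, fs: float,
                         centre: float, pool_size: int, iterations: int,
                         seed: int = 0, work_fs: float = 100.0) -> float:
    """Mean max-correlation between a common input and band-filtered CSTs of
    random ``pool_size`` subpools (single evaluation when the subpool is the
    whole pool).

    Both signals are decimated to ``work_fs`` after filtering; they are
    narrowband far below that rate, so the correlation is unaffected.
    """
    rng = np.random.default_rng(seed)
    common = np.asarray(common, dtype=float)
    sosin = sps.butter(2, [centre - 0.5, centre + 0.5], btype="bandpass",
                       fs=fs, output="sos")
    cin = _decimate_to(sps.sosfiltfilt(sosin, common - common.mean()), fs,
                       work_fs)
    if pool_size >= sts.n_units:
        iterations = 1
    vals = []
    for _ in range(iterations):
        if pool_size >= sts.n_units:
            ids = sts.unit_ids
        else:
            ids = rng.choice(sts.unit_ids, size=pool_size, replace=False)
        cst = cumulative_spike_train(sts, ids, fs, detrend="mean")
        filt = _decimate_to(bandpass_cst(cst, centre), fs, work_fs)
        r, _ = max_crosscorrelation(cin, filt, work_fs)
        vals.append(r)
    return float(np.mean(vals))


@dataclass
class TransmissionResult:
    """Tidy per-cell grid of mean max-correlations.

    One row per (cCI frequency, cCI power fraction, iCI on/off, pool size)
    cell, as produced by :func:`mnpool.experiments.transmission_experiment`.
    """

    table: pd.DataFrame

    def cell(self, freq: float, power_frac: float, ici: bool,
             pool_size: int) -> float:
        t = self.table
        m = ((t.freq == freq) & (np.isclose(t.power_frac, power_frac))
             & (t.ici == ici) & (t.pool_size == pool_size))
        if not m.any():
            raise KeyError("no such grid cell")
        return float(t.loc[m, "correlation"].iloc[0])

    def drop(self, freq: float, power_frac: float, pool_size: int) -> float:
        """Correlation drop caused by the iCI (without minus with)."""
        return (self.cell(freq, power_frac, False, pool_size)
                - self.cell(freq, power_frac, True, pool_size))
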