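"""Welch spectra, subpool-resampled pooled PSD, intramuscular coherence and
input-output gain of the cumulative spike train.

All estimators use 1 s Hamming windows with 0.5 s overlap; the 0.25 Hz grid
is obtained by zero-padding each segment to four times its length (the only
reading under which 1 s windows can yield a 0.25 Hz spacing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .spikes import SpikeTrainSet, cumulative_spike_train

__all__ = [
    "SpectralEstimate",
    "welch_psd",
    "pooled_psd",
    "intramuscular_coherence",
    "gain_at_frequency",
    "power_at",
]

SEG_S = 1.0
OVERLAP_S = 0.5
DF = 0.25


@dataclass
class SpectralEstimate:
    freqs: np.ndarray
    values: np.ndarray
    settings: dict

    def nearest_bin(self, f: float) -> int:
        return int(np.argmin(np.abs(self.freqs - f)))


def export_csv(est: SpectralEstimate, path) -> None:
    """Write (frequency, value) CSV with the estimator settings in a JSON
    sidecar."""
    import json
    from pathlib import Path
    import pandas as pd
    pd.DataFrame({"freq_hz": est.freqs, "value": est.values}).to_csv(
        path, index=False)
    Path(str(path) + ".json").write_text(json.dumps(est.settings, indent=2,
                                                    default=str))


def _welch_args(fs: float, window: str = "hamming"):
    nperseg = int(round(fs * SEG_S))
    noverlap = int(round(fs * OVERLAP_S))
    nfft = int(round(fs / DF))
    return dict(window=window, nperseg=nperseg, noverlap=noverlap, nfft=nfft,
                detrend=False)


def welch_psd(x: np.ndarray, fs: float, window: str = "hamming") -> SpectralEstimate:
    """Welch PSD (density scaling) of an already-detrended signal."""
    x = np.asarray(x, dtype=float)
    if x.size < 2 * int(fs * SEG_S):
        raise ValueError("signal shorter than two Welch segments")
    kw = _welch_args(fs, window)
    f, p = sps.welch(x, fs=fs, scaling="density", **kw)
    n_seg = 1 + (x.size - kw["nperseg"]) // (kw["nperseg"] - kw["noverlap"])
    return SpectralEstimate(f, p, {"fs": fs, "window": window,
                                   "seg_s": SEG_S, "overlap_s": OVERLAP_S,
                                   "df": DF, "n_segments": int(n_seg)})


def power_at(est: SpectralEstimate, f: float) -> float:
    """Band power of the single bin nearest ``f`` (PSD value times the grid
    spacing)."""
    return float(est.values[est.nearest_bin(f)] * DF)


def pooled_psd(sts: SpikeTrainSet, subpool: int = 30, iterations: int = 80,
               seed: int = 0, fs: float | None = None) -> SpectralEstimate:
    """Average Welch PSD over random ``subpool``-sized cumulative spike
    trains (80 draws of 30 MNs for the simulated pool)."""
    if sts.n_units < subpool:
        raise ValueError("subpool larger than the pool")
    fs = sts.fs if fs is None else fs
    rng = np.random.default_rng(seed)
    acc = None
    for _ in range(iterations):
        ids = rng.choice(sts.unit_ids, size=subpool, replace=False)
        cst = cumulative_spike_train(sts, ids, fs, detrend="mean")
        est = welch_psd(cst.samples, fs)
        acc = est.values if acc is None else acc + est.values
    est.values = acc / iterations
    est.settings["iterations"] = iterations
    est.settings["subpool"] = subpool
    return est


def intramuscular_coherence(sts: SpikeTrainSet, subpool: int | None = None,
                            iterations: int = 80, seed: int = 0,
                            fs: float | None = None) -> SpectralEstimate:
    """Magnitude-squared coherence between two disjoint random subpools,
    averaged over iterations.

    ``subpool`` defaults to half the available units (the experimental-data
    convention); the simulated-data convention is ``subpool=15``.
    """
    if subpool is None:
        subpool = sts.n_units // 2
    if sts.n_units < 2 * subpool:
        raise ValueError("pool too small for two disjoint subpools")
    fs = sts.fs if fs is None else fs
    rng = np.random.default_rng(seed)
    kw = _welch_args(fs)
    acc = None
    for _ in range(iterations):
        ids = rng.choice(sts.unit_ids, size=2 * subpool, replace=False)
        a = cumulative_spike_train(sts, ids[:subpool], fs, detrend="mean")
        b = cumulative_spike_train(sts, ids[subpool:], fs, detrend="mean")
        f, c = sps.coherence(a.samples, b.samples, fs=fs, **kw)
        acc = c if acc is None else acc + c
    vals = acc / iterations
    n_seg = 1 + (int(round(sts.duration * fs)) - kw["nperseg"]) \
        // (kw["nperseg"] - kw["noverlap"])
    return SpectralEstimate(f, vals, {"fs": fs, "subpool": subpool,
                                      "iterations": iterations,
                                      "n_segments": int(n_seg), "df": DF})


def gain_at_frequency(common_input, cst, frequency: float) -> float:
    """Ratio of cumulative-spike-train power to common-input power at the
    bin nearest ``frequency`` (both Welch estimates on the same grid)."""
    in_est = welch_psd(np.asarray(common_input.samples, dtype=float)
                       - np.mean(common_input.samples), common_input.fs)
    out_est = welch_psd(cst.samples, cst.fs)
    if in_est.freqs.size != out_est.freqs.size or \
            abs(in_est.freqs[1] - out_est.freqs[1]) > 1e-12:
        raise ValueError("input and output spectra are on different grids")
    p_in = power_at(in_est, frequency)
    if p_in == 0:
        raise ValueError(f"zero input power at {frequency} Hz")
    return power_at(out_est, frequency) / p_in
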