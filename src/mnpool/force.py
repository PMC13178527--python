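"""Simplified motor-unit twitch force model.

Force exists in this package solely to make the continuous-common-input
power calibration executable: the calibration criterion is a relative change
in the coefficient of variation of the plateau force, so only the *shape* of
the force fluctuations matters, never absolute units.

Each unit contributes a critically damped twitch
``f(t) = A * (t / T) * exp(1 - t / T)`` per spike (peak ``A`` at the
contraction time ``T``), scaled by a sigmoidal gain of the Fuglevand type
that depends on the unit's contraction time and the instantaneous
interspike interval: unity below a normalised rate ``T/ISI`` of 0.4, then
saturating non-linearly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .spikes import SpikeTrainSet

__all__ = ["TwitchParams", "twitch_gain", "spikes_to_force", "force_cov"]

_R0 = 0.4  # normalised rate below which the twitch gain is 1


@dataclass
class TwitchParams:
    amplitude: np.ndarray        # per-unit twitch peak, arbitrary units
    contraction_time: np.ndarray  # per-unit, seconds

    def __post_init__(self):
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.contraction_time = np.asarray(self.contraction_time, dtype=float)
        if np.any(self.amplitude <= 0) or np.any(self.contraction_time <= 0):
            raise ValueError("twitch amplitudes and contraction times must be > 0")

    @classmethod
    def default(cls, n_units: int, params: dict | None = None) -> "TwitchParams":
        if params is None:
            from .params import default_params
            params = default_params()
        f = params["force"]
        # exponential amplitude spread; larger units twitch faster
        amp = np.exp(np.linspace(np.log(f["amp_min"]), np.log(f["amp_max"]),
                                 n_units))
        ct = f["ct_max_ms"] / 1000.0 * (amp / f["amp_min"]) ** -f["ct_exponent"]
        return cls(amp, ct)


def _sigmoid(r: float | np.ndarray) -> np.ndarray:
    return (1.0 - np.exp(-2.0 * np.asarray(r) ** 3)) / np.asarray(r)


def twitch_gain(contraction_time, isi) -> np.ndarray:
    """Gain applied to a twitch fired after interspike interval ``isi``.

    For normalised rate ``r = T/ISI <= 0.4`` the gain is 1 (linear
    summation); above, it follows the saturating form
    ``(1 - exp(-2 r^3)) / r`` normalised to be continuous at ``r = 0.4``.
    """
    r = np.asarray(contraction_time / np.asarray(isi), dtype=float)
    g = np.ones_like(r)
    hi = r > _R0
    if np.any(hi):
        g[hi] = _sigmoid(r[hi]) / _sigmoid(_R0)
    return g


def spikes_to_force(sts: SpikeTrainSet, tw: TwitchParams, fs: float) -> np.ndarray:
    """Sum gain-scaled twitch responses of all units on a grid at ``fs``.

    Causal by construction (no response before a spike); an empty pool gives
    a zero trace.
    """
    n = int(round(sts.duration * fs))
    out = np.zeros(n)
    if sts.n_units == 0:
        return out
    if len(tw.amplitude) < sts.n_units:
        raise ValueError("need twitch parameters for every unit")
    for i, spikes in enumerate(sts.trains):
        if spikes.size == 0:
            continue
        A = tw.amplitude[i]
        T = tw.contraction_time[i]
        # kernel long enough for the twitch tail to fall below 1e-7 of its
        # peak; a leading zero keeps the response strictly after the spike bin
        klen = int(round(22 * T * fs))
        tk = np.arange(1, klen + 1) / fs
        kernel = np.r_[0.0, A * (tk / T) * np.exp(1.0 - tk / T)]
        isi = np.diff(spikes, prepend=-np.inf)
        gains = twitch_gain(T, isi)
        impulses = np.zeros(n)
        idx = np.minimum((spikes * fs).astype(np.int64), n - 1)
        np.add.at(impulses, idx, gains)
        out += fftconvolve(impulses, kernel)[:n]
    # scrub FFT round-off (magnitudes ~1e-16 of the peak, either sign)
    if out.any():
        out[np.abs(out) < 1e-12 * np.abs(out).max()] = 0.0
    np.clip(out, 0.0, None, out=out)
    return out


def force_cov(force: np.ndarray, window: tuple[float, float] | None = None,
              fs: float | None = None) -> float:
    """Coefficient of variation (SD/mean) of the force over ``window`` (s)."""
    if window is not None:
        if fs is None:
            raise ValueError("fs required when a window is given")
        i0, i1 = int(window[0] * fs), int(window[1] * fs)
        if i0 < 0 or i1 > force.size or i1 <= i0:
            raise ValueError("window outside the trace")
        force = force[i0:i1]
    mu = force.mean()
    if mu <= 0:
        raise ValueError("zero or negative mean force in the analysis window")
    return float(force.std(ddof=0) / mu)
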