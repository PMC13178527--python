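"""Spike-train containers, binning, cumulative spike trains and the
discharge-variability exclusion filter.

The :class:`SpikeTrainSet` is the exchange object between the simulator, the
synthetic generator and every analysis module.  The cumulative spike train
(CST) — the sample-wise sum of the binned per-unit trains, optionally
mean-detrended — is the population signal consumed by all spectral and
synchrony operations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrainSet",
    "CumulativeSpikeTrain",
    "bin_spike_trains",
    "cumulative_spike_train",
    "cov_exclusion_filter",
    "read_spike_csv",
    "write_spike_csv",
    "select_steady_segment",
]


@dataclass
class SpikeTrainSet:
    """Per-unit sorted spike times (seconds) over a common recording.

    Parameters
    ----------
    trains
        One float array of strictly increasing spike times per unit.
    duration
        Recording length in seconds; all times must lie in ``[0, duration]``.
    fs
        Source sampling rate in Hz (resolution at which times were produced).
    provenance
        Free tag: ``"simulated"``, ``"synthetic"`` or ``"external"``.
    unit_ids
        Optional integer labels; defaults to ``0..n_units-1``.
    """

    trains: list
    duration: float
    fs: float
    provenance: str = "simulated"
    unit_ids: np.ndarray | None = None

    def __post_init__(self):
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for i, t in enumerate(self.trains):
            if t.size and (np.any(np.diff(t) <= 0)):
                raise ValueError(f"unit {i}: spike times must be strictly increasing")
            if t.size and (t[0] < 0 or t[-1] > self.duration):
                raise ValueError(f"unit {i}: spike times outside [0, duration]")
        if self.unit_ids is None:
            self.unit_ids = np.arange(len(self.trains))
        else:
            self.unit_ids = np.asarray(self.unit_ids, dtype=int)
            if len(self.unit_ids) != len(self.trains):
                raise ValueError("unit_ids length mismatch")

    @property
    def n_units(self) -> int:
        return len(self.trains)

    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.trains])

    def rates(self) -> np.ndarray:
        """Mean discharge rate per unit, spikes/s."""
        return self.counts() / self.duration

    def mean_rate(self) -> float:
        """Pool mean discharge rate (the F_DR used for band selection)."""
        return float(self.rates().mean())

    def subset(self, ids) -> "SpikeTrainSet":
        idx = {u: i for i, u in enumerate(self.unit_ids)}
        try:
            rows = [idx[u] for u in ids]
        except KeyError as exc:
            raise KeyError(f"unknown unit id {exc.args[0]}") from None
        return replace(self, trains=[self.trains[r] for r in rows],
                       unit_ids=np.array([self.unit_ids[r] for r in rows]))


@dataclass
class CumulativeSpikeTrain:
    samples: np.ndarray
    fs: float
    unit_ids: np.ndarray
    detrend: str = "mean"   # "mean", "linear" or "none"
    mean_rate: float = 0.0  # pool mean discharge rate of contributing units


def bin_spike_trains(sts: SpikeTrainSet, fs: float) -> np.ndarray:
    """Bin each train into a binary vector at rate ``fs``.

    Bin index is ``floor(time * fs)``.  Two spikes of one unit falling in the
    same bin signal that ``fs`` is too low and raise an error.
    """
    n = int(round(sts.duration * fs))
    out = np.zeros((sts.n_units, n), dtype=np.float64)
    for i, t in enumerate(sts.trains):
        if t.size == 0:
            continue
        idx = np.minimum((t * fs).astype(np.int64), n - 1)
        if np.any(np.diff(idx) == 0):
            raise ValueError(
                f"unit {sts.unit_ids[i]}: two spikes in one bin at fs={fs} Hz; "
                "increase the binning rate")
        out[i, idx] = 1.0
    return out


def cumulative_spike_train(sts: SpikeTrainSet, unit_subset=None,
                           fs: float = 1000.0,
                           detrend: str = "mean") -> CumulativeSpikeTrain:
    """Sum the binned trains of ``unit_subset`` (default: all units)."""
    sub = sts if unit_subset is None else sts.subset(unit_subset)
    if sub.n_units == 0:
        raise ValueError("unit subset is empty")
    cst = bin_spike_trains(sub, fs).sum(axis=0)
    if detrend == "mean":
        cst = cst - cst.mean()
    elif detrend == "linear":
        x = np.arange(cst.size, dtype=float)
        a, b = np.polyfit(x, cst, 1)
        cst = cst - (a * x + b)
    elif detrend != "none":
        raise ValueError(f"unknown detrend method {detrend!r}")
    return CumulativeSpikeTrain(cst, fs, np.asarray(sub.unit_ids),
                                detrend, sub.mean_rate())


def window_counts(train: np.ndarray, duration: float,
                  window: float = 1.0) -> np.ndarray:
    """Spike count per non-overlapping window (the instantaneous firing rate
    sequence used by the exclusion filter)."""
    n_win = int(np.floor(duration / window))
    edges = np.arange(n_win + 1) * window
    counts, _ = np.histogram(train, bins=edges)
    return counts.astype(float)


def cov_exclusion_filter(sts: SpikeTrainSet, threshold: float = 0.3,
                         window: float = 1.0):
    """Exclude units whose window-rate coefficient of variation exceeds
    ``threshold`` (strictly greater), flagging units with no spikes.

    Returns ``(retained SpikeTrainSet, report DataFrame)`` with per-unit CoV.
    """
    if sts.duration < 2 * window:
        raise ValueError("recording too short for the exclusion filter")
    rows = []
    keep = []
    for i, t in enumerate(sts.trains):
        uid = int(sts.unit_ids[i])
        if t.size == 0:
            rows.append((uid, np.nan, False, "no spikes"))
            continue
        c = window_counts(t, sts.duration, window)
        mu = c.mean()
        cov = np.nan if mu == 0 else c.std(ddof=0) / mu
        retained = bool(np.isfinite(cov) and cov <= threshold)
        rows.append((uid, cov, retained, "" if retained else "CoV > threshold"))
        if retained:
            keep.append(uid)
    report = pd.DataFrame(rows, columns=["unit_id", "cov", "retained", "note"])
    return sts.subset(keep), report


# ---------------------------------------------------------------------------
# CSV interchange: header `unit_id,spike_time_s`, '.' decimal, sorted by unit
# then time.

def write_spike_csv(sts: SpikeTrainSet, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("unit_id,spike_time_s\n")
        for uid, t in zip(sts.unit_ids, sts.trains):
            for s in t:
                fh.write(f"{int(uid)},{s:.6f}\n")


def read_spike_csv(path, duration: float | None = None,
                   fs: float = 5000.0,
                   provenance: str = "external") -> SpikeTrainSet:
    """Read a spike CSV, validating per-unit monotonicity.

    Malformed rows (non-numeric, unsorted within a unit) raise ``ValueError``
    naming the first offending line.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    lines = text.strip().splitlines()
    if not lines or lines[0].strip().lower() != "unit_id,spike_time_s":
        raise ValueError("missing or malformed header 'unit_id,spike_time_s'")
    try:
        df = pd.read_csv(io.StringIO(text), dtype={"unit_id": np.int64,
                                                   "spike_time_s": np.float64})
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed spike CSV: {exc}") from None
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2
        raise ValueError(f"non-numeric value at line {bad}")
    trains, ids = [], []
    for uid, grp in df.groupby("unit_id", sort=True):
        t = grp["spike_time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            k = int(np.argmax(np.diff(t) <= 0))
            line = grp.index[k + 1] + 2
            raise ValueError(f"unit {uid}: unsorted spike time at line {line}")
        trains.append(t)
        ids.append(uid)
    if duration is None:
        duration = float(max((t[-1] for t in trains if t.size), default=0.0)) + 1e-6
    return SpikeTrainSet(trains, duration, fs, provenance, np.array(ids))


def select_steady_segment(sts: SpikeTrainSet, segment: float = 30.0,
                          threshold: float = 0.3,
                          step: float = 1.0) -> tuple[float, int]:
    """Sliding-window helper: the segment start that maximizes the number of
    units passing the exclusion filter.  Offered as a convenience for long
    external recordings; not claimed to be how reference segments were chosen.
    """
    best_t0, best_n = 0.0, -1
    t0 = 0.0
    while t0 + segment <= sts.duration + 1e-9:
        shifted = []
        for t in sts.trains:
            sel = t[(t >= t0) & (t < t0 + segment)] - t0
            shifted.append(sel)
        sub = SpikeTrainSet(shifted, segment, sts.fs, sts.provenance,
                            sts.unit_ids)
        retained, _ = cov_exclusion_filter(sub, threshold)
        if retained.n_units > best_n:
            best_t0, best_n = t0, retained.n_units
        t0 += step
    return best_t0, best_n
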