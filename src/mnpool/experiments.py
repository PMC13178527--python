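"""Scenario runner: wiring the simulator, the input generators and the
analysis pipeline into the study's result sets.

Four simulation scenarios are supported (each on top of the per-MN constant
plus noisy independent input):

* ``control`` — no common input.
* ``ici`` — impulsive CI: rectangular burst train, amplitude calibrated to
  recruit 50% of the pool per burst.
* ``cci`` — continuous CI: 1 Hz-wide narrowband noise at F_DR, 20 Hz or
  1 Hz, at the force-CoV-calibrated maximum power.
* ``combined`` — cCI plus an iCI at 1 burst/s.

A master seed expands deterministically into per-run seeds so every run is
independently reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import params as prm
from .force import force_cov
from .inputs import (NarrowbandSpec, PulseTrainSpec, calibrate_burst_amplitude,
                     calibrate_cci_power, make_cci, make_combined_ci, make_ici,
                     make_matched_sinusoid)
from .model import (PoolConfig, calibrate_constant_drive, default_rate_targets,
                    run_simulation)
from .spectral import gain_at_frequency, intramuscular_coherence, pooled_psd
from .spikes import (SpikeTrainSet, cov_exclusion_filter,
                     cumulative_spike_train, read_spike_csv, write_spike_csv)
from .synchrony import event_triggered_profile, surrogate_profiles
from .transmission import TransmissionResult, subpool_transmission

__all__ = [
    "expand_seed",
    "CalibratedPool",
    "build_calibrated_pool",
    "scenario_input",
    "sync_scenario_stats",
    "gain_curve",
    "fit_exponential",
    "fit_linear",
    "transmission_experiment",
    "ScenarioConfig",
    "run_scenario",
    "analyze_external",
]


def expand_seed(master: int, tag: str) -> int:
    """Deterministic per-task seed below 2**31 derived from a master seed."""
    return (master * 2654435761 + zlib.crc32(tag.encode())) % (2 ** 31 - 1)


@dataclass
class CalibratedPool:
    """A pool configuration with calibrated constant drives and the
    quantities every scenario reuses."""

    config: PoolConfig            # template (C filled in)
    targets: np.ndarray
    report: dict
    f_dr: float                   # realized pool mean discharge rate
    alpha: float | None = None    # calibrated burst amplitude
    alpha_fraction: float | None = None
    cci_power: dict = field(default_factory=dict)  # centre -> max power

    def sim_config(self, duration: float, seed: int) -> PoolConfig:
        c = self.config
        return PoolConfig(n_mn=c.n_mn, duration=duration, fs=c.fs,
                          dt_ms=c.dt_ms, C=c.C, seed=seed,
                          renshaw=c.renshaw, params=c.params)


def pool_to_json(pool: CalibratedPool, path) -> None:
    payload = {
        "C": pool.config.C.tolist(),
        "targets": pool.targets.tolist(),
        "f_dr": pool.f_dr,
        "rc_rate": pool.report.get("rc_rate"),
        "alpha": pool.alpha,
        "alpha_fraction": pool.alpha_fraction,
        "cci_power": pool.cci_power,
        "n_mn": pool.config.n_mn,
        "seed": pool.config.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def pool_from_json(path) -> CalibratedPool:
    cal = json.loads(Path(path).read_text())
    cfg = PoolConfig(n_mn=int(cal["n_mn"]), C=np.array(cal["C"]),
                     seed=int(cal.get("seed", 0)))
    return CalibratedPool(cfg, np.array(cal["targets"]),
                          {"rc_rate": cal.get("rc_rate")}, cal["f_dr"],
                          cal.get("alpha"), cal.get("alpha_fraction"),
                          cal.get("cci_power") or {})


def build_calibrated_pool(seed: int, n_mn: int = 177,
                          cal_duration: float = 12.0, max_iter: int = 6,
                          check_duration: float = 30.0) -> CalibratedPool:
    """Calibrate the constant drives to the reference rate spread and
    measure the realized pool mean rate on an independent run."""
    targets = default_rate_targets(n_mn)
    cfg = PoolConfig(n_mn=n_mn, seed=expand_seed(seed, "calibration"))
    C, report = calibrate_constant_drive(targets, cfg, cal_duration=cal_duration,
                                         max_iter=max_iter)
    cfg.C = C
    check = run_simulation(
        PoolConfig(n_mn=n_mn, duration=check_duration, C=C,
                   seed=expand_seed(seed, "calibration-check")),
        compute_force=False)
    f_dr = check.mn_spikes.mean_rate()
    report = dict(report)
    report["check_rates"] = check.mn_spikes.rates()
    report["rc_rate"] = float(check.rc_spikes.rates().mean())
    return CalibratedPool(cfg, targets, report, f_dr)


def attach_input_calibrations(pool: CalibratedPool, seed: int,
                              cci_centres=(None, 20.0, 1.0),
                              burst_duration: float = 12.0,
                              cci_duration: float = 20.0,
                              cci_seeds: int = 3) -> CalibratedPool:
    """Calibrate the iCI burst amplitude and the maximum cCI powers."""
    cfg = pool.sim_config(burst_duration, expand_seed(seed, "alpha"))
    pool.alpha, pool.alpha_fraction = calibrate_burst_amplitude(cfg)
    for centre in cci_centres:
        c = pool.f_dr if centre is None else centre
        key = "f_dr" if centre is None else f"{centre:g}"
        cfgp = pool.sim_config(cci_duration, expand_seed(seed, f"ccipow-{key}"))
        p, _ = calibrate_cci_power(cfgp, c, n_seeds=cci_seeds,
                                   duration=cci_duration)
        pool.cci_power[key] = p
    return pool


def scenario_input(scenario: str, pool: CalibratedPool, duration: float,
                   fs: float, seed: int, ici_rate: float = 1.0,
                   jitter: bool = True, cci_centre: float | str = "f_dr",
                   power_frac: float = 1.0):
    """Build the common-input waveform for a scenario (None for control)."""
    if scenario == "control":
        return None
    jf = 0.2 if jitter else 0.0
    if scenario == "ici":
        if ici_rate == 0:
            return None
        spec = PulseTrainSpec(amplitude=pool.alpha, rate=ici_rate,
                              jitter_frac=jf, seed=seed)
        return make_ici(spec, duration, fs)
    centre = pool.f_dr if cci_centre == "f_dr" else float(cci_centre)
    key = "f_dr" if cci_centre == "f_dr" else f"{float(cci_centre):g}"
    power = pool.cci_power[key] * power_frac
    nspec = NarrowbandSpec(centre=centre, power=power, seed=seed)
    if scenario == "cci":
        return make_cci(nspec, duration, fs)
    if scenario == "combined":
        pspec = PulseTrainSpec(amplitude=pool.alpha, rate=ici_rate,
                               jitter_frac=jf, seed=seed + 1)
        return make_combined_ci(nspec, pspec, duration, fs)
    raise ValueError(f"unknown scenario {scenario!r}")


def sync_scenario_stats(scenario: str, pool: CalibratedPool, seed: int,
                        n_sims: int = 3, iterations: int = 20,
                        subpool: int = 30, duration: float = 30.0,
                        grid_fs: float = 500.0, cci_centre="f_dr") -> dict:
    """Event rate and event-triggered SPIKE-distance minimum for one
    scenario, averaged over simulations (profile averaged, then minimised)."""
    profiles = []
    rates = []
    for s in range(n_sims):
        run_seed = expand_seed(seed, f"{scenario}-{cci_centre}-sim{s}")
        cfg = pool.sim_config(duration, run_seed)
        ci = scenario_input(scenario, pool, duration, cfg.fs, run_seed + 13,
                            cci_centre=cci_centre)
        res = run_simulation(cfg, ci, compute_force=False)
        prof = event_triggered_profile(res.mn_spikes, subpool=subpool,
                                       iterations=iterations,
                                       seed=run_seed + 29, grid_fs=grid_fs,
                                       f_dr=res.mn_spikes.mean_rate())
        profiles.append(prof)
        rates.append(prof.event_rate)
    values = np.mean([p.values for p in profiles], axis=0)
    lags = profiles[0].lags
    imin = int(np.argmin(values))
    return {
        "scenario": scenario,
        "cci_centre": cci_centre if scenario in ("cci", "combined") else None,
        "event_rate": float(np.mean(rates)),
        "event_rate_sd": float(np.std(rates)),
        "min_spike_distance": float(values[imin]),
        "min_lag": float(lags[imin]),
        "lags": lags,
        "profile": values,
        "n_sims": n_sims,
        "iterations": iterations,
    }


# ---------------------------------------------------------------------------
# gain vs pool size (linearity analysis)

def fit_exponential(x, y):
    """Least-squares fit of y = a*exp(b*x) (nonlinear, initialised from the
    log-linear solution); R^2 evaluated on the original scale."""
    from scipy.optimize import curve_fit
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("exponential fit requires positive values")
    b0, loga = np.polyfit(x, np.log(y), 1)
    popt, _ = curve_fit(lambda t, a, b: a * np.exp(b * t), x, y,
                        p0=[np.exp(loga), b0], maxfev=20000)
    a, b = popt
    yhat = a * np.exp(b * x)
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return float(a), float(b), float(1 - ss_res / ss_tot)


def fit_linear(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c1, c0 = np.polyfit(x, y, 1)
    yhat = c0 + c1 * x
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return float(c0), float(c1), float(1 - ss_res / ss_tot)


def gain_curve(pool: CalibratedPool, seed: int, kind: str = "ici",
               pool_sizes=(10, 20, 30, 45, 60, 90, 120, 150, 177),
               n_sims: int = 2, subset_draws: int = 3,
               duration: float = 30.0, ici_rate: float = 1.0) -> dict:
    """Input-output gain at F_DR versus number of MNs in the CST.

    ``kind="ici"`` drives the pool with the jitter-free burst train;
    ``kind="sinusoid"`` with a pure cosine at F_DR whose line power matches
    the burst train's harmonic at F_DR.
    """
    gains = np.zeros((n_sims, len(pool_sizes)))
    for s in range(n_sims):
        run_seed = expand_seed(seed, f"gain-{kind}-{s}")
        cfg = pool.sim_config(duration, run_seed)
        pspec = PulseTrainSpec(amplitude=pool.alpha, rate=ici_rate,
                               jitter_frac=0.0, seed=run_seed)
        if kind == "ici":
            ci = make_ici(pspec, duration, cfg.fs)
        elif kind == "sinusoid":
            ci = make_matched_sinusoid(pspec, pool.f_dr, duration, cfg.fs)
        else:
            raise ValueError(f"unknown input kind {kind!r}")
        res = run_simulation(cfg, ci, compute_force=False)
        rng = np.random.default_rng(run_seed + 3)
        sts = res.mn_spikes
        for k, size in enumerate(pool_sizes):
            draws = 1 if size >= sts.n_units else subset_draws
            vals = []
            for _ in range(draws):
                ids = (sts.unit_ids if size >= sts.n_units
                       else rng.choice(sts.unit_ids, size=size, replace=False))
                cst = cumulative_spike_train(sts, ids, cfg.fs, detrend="mean")
                vals.append(gain_at_frequency(ci, cst, pool.f_dr))
            gains[s, k] = np.mean(vals)
    mean_gain = gains.mean(axis=0)
    a, b, r2_exp = fit_exponential(pool_sizes, mean_gain)
    c0, c1, r2_lin = fit_linear(pool_sizes, mean_gain)
    return {"kind": kind, "pool_sizes": np.asarray(pool_sizes),
            "gain": mean_gain, "a": a, "b": b, "r2_exp": r2_exp,
            "r2_lin": r2_lin, "n_sims": n_sims}


# ---------------------------------------------------------------------------
# transmission experiment

def transmission_experiment(pool: CalibratedPool, seed: int,
                            freqs=(1.0, 20.0),
                            power_fracs=(0.25, 0.5, 1.0),
                            pool_sizes=(10, 30, 177),
                            iterations: int = 20,
                            duration: float = 30.0,
                            n_sims: int = 2,
                            max_power_key: str = "20") -> TransmissionResult:
    """Mean max-correlation between a cCI and the band-filtered CST over the
    (frequency x power x iCI x pool size) grid, averaged over ``n_sims``
    replications per cell.

    The 100% power level is the force-CoV-calibrated maximum for the 20 Hz
    cCI; the iCI, when present, runs at 1 burst/s.  Within a replication
    the with- and without-iCI runs share the cCI realization so the drop is
    a paired contrast.
    """
    rows = []
    pmax = pool.cci_power[max_power_key]
    for f in freqs:
        for frac in power_fracs:
            acc = {(ici, size): [] for ici in (False, True)
                   for size in pool_sizes}
            for s in range(n_sims):
                base_seed = expand_seed(seed, f"trans-{f}-{frac}-{s}")
                nspec = NarrowbandSpec(centre=f, power=pmax * frac,
                                       seed=base_seed + 7)
                cci_part = make_cci(nspec, duration,
                                    pool.config.fs).samples
                for ici in (False, True):
                    run_seed = base_seed + (1 if ici else 0)
                    cfg = pool.sim_config(duration, run_seed)
                    if ici:
                        pspec = PulseTrainSpec(amplitude=pool.alpha, rate=1.0,
                                               seed=base_seed + 11)
                        ci = make_combined_ci(nspec, pspec, duration, cfg.fs)
                    else:
                        ci = make_cci(nspec, duration, cfg.fs)
                    res = run_simulation(cfg, ci, compute_force=False)
                    for size in pool_sizes:
                        r = subpool_transmission(res.mn_spikes, cci_part,
                                                 cfg.fs, f, size, iterations,
                                                 seed=run_seed + 17)
                        acc[(ici, size)].append(r)
            for ici in (False, True):
                for size in pool_sizes:
                    rows.append({"freq": f, "power_frac": frac, "ici": ici,
                                 "pool_size": size,
                                 "correlation": float(np.mean(acc[(ici, size)])),
                                 "iterations": (1 if size >= pool.config.n_mn
                                                else iterations)})
    return TransmissionResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# scenario runner and external-data analysis

@dataclass
class ScenarioConfig:
    scenario: str = "control"            # control | ici | cci | combined
    n_sims: int = 3
    duration: float = 30.0
    iterations: int = 20                 # subpool iterations per simulation
    subpool: int = 30
    cci_centre: float | str = "f_dr"
    master_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.scenario not in ("control", "ici", "cci", "combined"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_sims < 1:
            raise ValueError("replication count must be >= 1")


def run_scenario(cfg: ScenarioConfig, pool: CalibratedPool | None = None) -> dict:
    """Execute one scenario end to end: simulations, pooled PSD, IMC,
    event detection and event-triggered profiles; optionally serialize the
    bundle (summary JSON + spike CSVs + profile CSV) to ``out_dir``."""
    seed = cfg.master_seed
    if pool is None:
        pool = build_calibrated_pool(seed)
        if cfg.scenario != "control":
            attach_input_calibrations(pool, seed)
    stats = sync_scenario_stats(cfg.scenario, pool, seed, n_sims=cfg.n_sims,
                                iterations=cfg.iterations, subpool=cfg.subpool,
                                duration=cfg.duration,
                                cci_centre=cfg.cci_centre)
    run_seed = expand_seed(seed, f"{cfg.scenario}-{cfg.cci_centre}-sim0")
    sim_cfg = pool.sim_config(cfg.duration, run_seed)
    ci = scenario_input(cfg.scenario, pool, cfg.duration, sim_cfg.fs,
                        run_seed + 13, cci_centre=cfg.cci_centre)
    res = run_simulation(sim_cfg, ci, compute_force=False)
    psd = pooled_psd(res.mn_spikes, subpool=cfg.subpool,
                     iterations=cfg.iterations, seed=run_seed + 41)
    imc = intramuscular_coherence(res.mn_spikes, subpool=15,
                                  iterations=cfg.iterations,
                                  seed=run_seed + 43)
    pars = sim_cfg.resolved_params()
    summary = {
        "scenario": cfg.scenario,
        "cci_centre": str(cfg.cci_centre),
        "master_seed": seed,
        "params_hash": prm.params_hash(pars),
        "f_dr": pool.f_dr,
        "alpha": pool.alpha,
        "cci_power": pool.cci_power,
        "event_rate": stats["event_rate"],
        "min_spike_distance": stats["min_spike_distance"],
        "n_sims": cfg.n_sims,
        "iterations": cfg.iterations,
        "psd_peak_hz": float(psd.freqs[int(np.argmax(psd.values))]),
        "imc_peak_hz": float(imc.freqs[int(np.argmax(imc.values))]),
    }
    bundle = {"summary": summary, "stats": stats, "psd": psd, "imc": imc,
              "first_sim": res, "pool": pool}
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        write_spike_csv(res.mn_spikes, out / "spikes_sim0.csv")
        pd.DataFrame({"lag_s": stats["lags"], "spike_distance":
                      stats["profile"]}).to_csv(out / "profile.csv", index=False)
        pd.DataFrame({"freq_hz": psd.freqs, "psd": psd.values}).to_csv(
            out / "psd.csv", index=False)
        pd.DataFrame({"freq_hz": imc.freqs, "coherence": imc.values}).to_csv(
            out / "imc.csv", index=False)
    return bundle


def analyze_external(path, seed: int = 0, n_surrogates: int = 20,
                     grid_fs: float = 500.0, out_dir: str | None = None) -> dict:
    """Analysis pipeline for externally decomposed spike trains (CSV with
    header ``unit_id,spike_time_s``): exclusion filter, pooled spectra,
    half-pool IMC, event detection and the event-triggered profile with its
    circular-shift surrogate null (all retained units, no subpooling)."""
    sts = read_spike_csv(path)
    retained, report = cov_exclusion_filter(sts)
    if retained.n_units < 2:
        raise ValueError("fewer than 2 units retained after the exclusion filter")
    f_dr = retained.mean_rate()
    cst_fs = 1000.0
    prof = event_triggered_profile(retained, subpool=None, seed=seed,
                                   grid_fs=grid_fs, cst_fs=cst_fs, f_dr=f_dr)
    minima, surr_mean, _ = surrogate_profiles(
        retained, n_surrogates=n_surrogates, seed=seed + 1, subpool=None,
        grid_fs=grid_fs, cst_fs=cst_fs, f_dr=f_dr)
    cst = cumulative_spike_train(retained, fs=cst_fs, detrend="mean")
    from .spectral import welch_psd
    psd = welch_psd(cst.samples, cst_fs)
    imc = intramuscular_coherence(retained, seed=seed + 2)
    out = {
        "n_units_total": sts.n_units,
        "n_units_retained": retained.n_units,
        "f_dr": f_dr,
        "event_rate": prof.event_rate,
        "min_spike_distance": prof.min_value,
        "surrogate_mean_min": surr_mean,
        "surrogate_minima": minima,
        "filter_report": report,
        "profile": prof,
        "psd": psd,
        "imc": imc,
    }
    if out_dir is not None:
        o = Path(out_dir)
        o.mkdir(parents=True, exist_ok=True)
        summary = {k: out[k] for k in ("n_units_total", "n_units_retained",
                                       "f_dr", "event_rate",
                                       "min_spike_distance",
                                       "surrogate_mean_min")}
        with open(o / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        report.to_csv(o / "exclusion_report.csv", index=False)
    return out
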