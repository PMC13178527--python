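"""Pooled PSD and intramuscular coherence per scenario.

Reproduces the dissociation that motivates the study: with an impulsive
common input the cumulative-spike-train PSD is dominated by the peak at
the pool mean discharge rate while the IMC stays flat there (transient
synchrony is invisible to a stationary coherence estimator), whereas a
continuous common input leaves a coherence peak at its own frequency.

Writes results/spectra/{scenario}_psd.csv and _imc.csv plus a summary.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mnpool.experiments import expand_seed, pool_from_json, scenario_input
from mnpool.model import run_simulation
from mnpool.spectral import intramuscular_coherence, pooled_psd

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"

SCENARIOS = [("ici", "f_dr"), ("control", "f_dr"),
             ("cci", "f_dr"), ("cci", "20")]


def main():
    pool = pool_from_json(OUT / "calibration.json")
    (OUT / "spectra").mkdir(parents=True, exist_ok=True)
    rows = []
    for scen, centre in SCENARIOS:
        label = (scen if scen != "cci" else f"cci_{centre}")
        seed = expand_seed(SEED, f"spectra-{label}")
        cfg = pool.sim_config(30.0, seed)
        ci = scenario_input(scen, pool, 30.0, cfg.fs, seed + 13,
                            cci_centre=centre)
        print(f"Simulating {label}...")
        res = run_simulation(cfg, ci, compute_force=False)
        psd = pooled_psd(res.mn_spikes, subpool=30, iterations=20,
                         seed=seed + 41)
        imc = intramuscular_coherence(res.mn_spikes, subpool=15,
                                      iterations=20, seed=seed + 43)
        keep = psd.freqs <= 100.0   # the physiological band; keeps files small
        pd.DataFrame({"freq_hz": psd.freqs[keep],
                      "psd": psd.values[keep]}).to_csv(
            OUT / "spectra" / f"{label}_psd.csv", index=False)
        keep = imc.freqs <= 100.0
        pd.DataFrame({"freq_hz": imc.freqs[keep],
                      "coherence": imc.values[keep]}).to_csv(
            OUT / "spectra" / f"{label}_imc.csv", index=False)
        sel = (psd.freqs > 2) & (psd.freqs < 40)
        psd_peak = psd.freqs[sel][np.argmax(psd.values[sel])]
        iself = (imc.freqs > 2) & (imc.freqs < 40)
        imc_peak = imc.freqs[iself][np.argmax(imc.values[iself])]
        imc_at_fdr = imc.values[imc.nearest_bin(pool.f_dr)]
        floor = float(np.median(imc.values[iself]))
        rows.append({"scenario": label, "psd_peak_hz": psd_peak,
                     "imc_peak_hz": imc_peak, "imc_at_fdr": imc_at_fdr,
                     "imc_floor": floor})
        print(f"  PSD peak {psd_peak:.2f} Hz; IMC at F_DR {imc_at_fdr:.3f} "
              f"(floor {floor:.3f})")
    pd.DataFrame(rows).to_csv(OUT / "spectra" / "summary.csv", index=False)
    print("\nThe impulsive scenario keeps its PSD peak at F_DR without a "
          "matching IMC peak - the signature the study looks for in "
          "experimental pools.")


if __name__ == "__main__":
    main()
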