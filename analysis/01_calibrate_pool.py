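"""Calibrate the 177-MN pool and the common-input amplitudes.

Adjusts the per-MN constant drives until the pool fires at the reference
spread (7.3-13.4 Hz, mean 10.4 Hz), verifies the Renshaw baseline, then
calibrates the burst amplitude (50% recruitment per 5 ms burst) and the
maximum continuous-input powers (force-CoV criterion) at F_DR and 20 Hz.

Writes results/calibration.json, consumed by every later script.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mnpool.experiments import (attach_input_calibrations,
                                build_calibrated_pool, pool_to_json)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    print("Calibrating constant drives (probe run + damped iterations)...")
    pool = build_calibrated_pool(SEED)
    r = pool.report["check_rates"]
    print(f"  realized rates: mean {r.mean():.2f} Hz (target 10.4), "
          f"SD {r.std():.2f} (1.4), range {r.min():.2f}-{r.max():.2f} "
          f"(7.3-13.4)")
    print(f"  Renshaw population rate: {pool.report['rc_rate']:.2f} spikes/s "
          f"(target ~11)")

    print("Calibrating input amplitudes...")
    attach_input_calibrations(pool, SEED, cci_centres=(None, 20.0))
    print(f"  burst amplitude alpha = {pool.alpha:.3f} mS/cm^2 "
          f"(recruits {pool.alpha_fraction:.0%} of the pool per burst)")
    for k, v in pool.cci_power.items():
        print(f"  max cCI power @ {k}: {v:g} (mS/cm^2)^2")

    pool_to_json(pool, OUT / "calibration.json")
    print(f"Wrote {OUT / 'calibration.json'}")


if __name__ == "__main__":
    main()
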