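"""Compare health losses with gold-mining revenue.

Computes gold revenue from production and price, the annual and cumulative
loss-to-earning ratios of the synthetic pipeline, the compound growth rate
of the published loss endpoints ($0.59B in 1970 to $7.1B in 2012: 6.1% per
year), the published cumulative comparison ($154B of losses against $319B
of revenue: 48.3%), the retort-programme cost ($300M for 15 million
miners), and the ratio of the general-population risk to the
miner-community risk (~1.5).  Writes results/economics/comparison.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from asgm_hg import (
    geometric_growth_rate,
    gold_revenue,
    intervention_cost,
    loss_earning_ratio,
    miner_vs_global_ratio,
    run_pipeline,
)
from asgm_hg.synthetic_data import calibrated_world


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/economics"))
    args = ap.parse_args()

    world = calibrated_world(seed=args.seed)
    a = world.anchors
    result = run_pipeline(world)
    args.outdir.mkdir(parents=True, exist_ok=True)
    result.economics.to_csv(args.outdir / "comparison.csv", index=False)

    g = world.gold
    rev70 = gold_revenue(float(g.production_t[0]), float(g.price_usd_oz[0]))
    rev12 = gold_revenue(float(g.production_t[-1]), float(g.price_usd_oz[-1]))
    print(f"gold revenue: ${rev70 / 1e6:.0f}M (1970) -> "
          f"${rev12 / 1e9:.1f}B (2012)")

    cum = loss_earning_ratio(
        pd.Series({2012: a["cumulative_loss_usd"]}),
        pd.Series({2012: a["cumulative_revenue_usd"]}))
    print(f"published cumulative loss / revenue: {cum.cumulative:.1%}")
    print(f"published 2012 loss / computed 2012 revenue: "
          f"{a['loss_2012_usd'] / rev12:.1%}")
    rate = geometric_growth_rate(a["loss_1970_usd"], a["loss_2012_usd"], 42)
    print(f"average loss growth 1970-2012: {rate:.1%} per year")

    synth = result.economics
    print(f"synthetic-world cumulative loss / revenue: "
          f"{synth['loss_usd'].sum() / synth['revenue_usd'].sum():.1%}")

    cost = intervention_cost(a["n_miners"], a["retort_unit_cost_usd"])
    print(f"retort programme: ${cost / 1e6:.0f}M for "
          f"{a['n_miners'] / 1e6:.0f}M miners")
    ratio = miner_vs_global_ratio(a["loss_2012_usd"],
                                  a["total_mehg_loss_usd"],
                                  a["miner_loss_fraction"])
    print(f"general-population vs miner-community risk: x{ratio:.1f}")


if __name__ == "__main__":
    main()
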