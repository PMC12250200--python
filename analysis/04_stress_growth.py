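#!/usr/bin/env python
"""Relate fruit growth to integrated water stress on the held-out season.

Requires 01 (cohorts) and 03 (predictions).  Builds the per-tree growth
record for each measurement method — caliper (mean of two replicate
readings) and the image-based estimate at each resolution tier (one random
photograph per endpoint day) — computes the integrated stress S_psi over
the whole season and monthly sub-periods, and reports the coefficient of
determination between growth and S_psi per period and method.

Writes results/stress/stress_growth.csv and stress_correlations.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from fruitgauge import SimConfig
from fruitgauge.pipeline import stage_stress


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    config = SimConfig(seed=args.seed)
    stage_stress(config, args.out)

    corr = pd.read_csv(args.out / "stress" / "stress_correlations.csv")
    corr["period"] = corr["period_start"] + ".." + corr["period_end"]
    pivot = corr.pivot(index="method", columns="period", values="r2").round(4)
    print("R^2 between per-tree growth and integrated stress, by period:")
    print(pivot.to_string())
    season = corr[corr["period_start"] == corr["period_start"].min()]
    whole = corr[corr["period_end"].eq(corr["period_end"].max())
                 & corr["period_start"].eq(corr["period_start"].min())]
    print("\nwhole season:")
    print(whole[["method", "r2", "slope"]].round(4).to_string(index=False))


if __name__ == "__main__":
    main()
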