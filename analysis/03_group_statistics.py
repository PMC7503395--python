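#!/usr/bin/env python
"""Age-group statistics on the analyzed cohort, with the normality-gated branch.

For each electrophysiological variable, cells are biological replicates; for
AIS length, animals are (per-animal mean of the technical replicates). Each
variable is Shapiro-Wilk-gated into one-way ANOVA + Bonferroni pairwise t
tests or Kruskal-Wallis + Dunn's test; starred summary tables are written
per variable.

Reads results/run/features.csv + ais.csv, writes results/stats_report/.
"""

import argparse
from pathlib import Path

import pandas as pd

from aismature.group_stats import (
    GroupedMeasurements,
    compare_groups,
    render_summary,
    significance_stars,
)

ROOT = Path(__file__).resolve().parent.parent
EPHYS_VARS = ["cm_pF", "rin_Mohm", "rheobase_pA", "threshold_mV",
              "gain_Hz_per_pA", "max_dvdt_Vps", "half_width_ms", "est_i_in_ais_pA"]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--run", type=Path, default=ROOT / "results" / "run")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "stats_report")
    args = ap.parse_args()

    features = pd.read_csv(args.run / "features.csv")
    ais = pd.read_csv(args.run / "ais.csv")
    args.out.mkdir(parents=True, exist_ok=True)

    for var in EPHYS_VARS:
        gm = GroupedMeasurements.from_frame(features.dropna(subset=[var]),
                                            "group", var)
        cmp_ = compare_groups(gm)
        render_summary(cmp_).to_csv(args.out / f"{var}.csv", index=False)
        print(f"{var}: {cmp_.omnibus_test} p={cmp_.omnibus_p:.2e} "
              f"{significance_stars(cmp_.omnibus_p)}")

    gm = GroupedMeasurements.from_frame(ais, "group", "length_um",
                                        replicate_mode="animal_mean_as_unit")
    cmp_ = compare_groups(gm)
    render_summary(cmp_).to_csv(args.out / "ais_length_um.csv", index=False)
    print(f"ais_length_um (animal means): {cmp_.omnibus_test} "
          f"p={cmp_.omnibus_p:.2e} {significance_stars(cmp_.omnibus_p)}")


if __name__ == "__main__":
    main()
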