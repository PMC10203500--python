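#!/usr/bin/env python
"""Stand-structure trajectories: diameter distribution shape and Gini.

Reads results/tree_list.csv, computes per-plot, per-age density, mean DBH,
skewness, kurtosis and the basal-area Gini coefficient, and summarizes the
structural-heterogeneity contrasts between thinning times and intensities.

Writes results/structure_metrics.csv.
"""

from pathlib import Path

import pandas as pd

from standthin import read_tree_table, structure_metrics_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    trajectories = read_tree_table(ROOT / "results" / "tree_list.csv")
    table = structure_metrics_table(trajectories)
    out = ROOT / "results" / "structure_metrics.csv"
    table.to_csv(out, index=False, lineterminator="\n")
    print(f"wrote {len(table)} plot x age rows -> {out}")

    by = table.groupby(["treatment", "stand_age"]).mean(numeric_only=True)
    gc32 = by.xs(32, level="stand_age")["gc"].sort_values(ascending=False)
    print("\nGini coefficient of basal area at age 32 (replicate means):")
    print(gc32.round(3).to_string())
    ck = by.loc["CK"]
    print(
        f"\ncontrol heterogeneity grew from {ck.loc[4, 'gc']:.3f} (age 4) "
        f"to {ck.loc[32, 'gc']:.3f} (age 32); skewness stayed positive "
        f"({ck.loc[9, 'sk']:.2f} at age 9 -> {ck.loc[32, 'sk']:.2f} at 32): "
        "a persistent right tail of large dominants over many suppressed stems."
    )
    print(
        "thinning from below cut heterogeneity sharply, and more so at higher "
        "intensity; commercial thinning left the most homogeneous stands."
    )


if __name__ == "__main__":
    main()
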