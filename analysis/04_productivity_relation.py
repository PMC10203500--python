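#!/usr/bin/env python
"""Productivity and the structure-productivity relation.

Computes periodic annual increment (PAI) per plot and age, summarizes the
post-treatment productivity of each thinning intensity, and fits the
fixed-effects line PAI = b0 + b1 * GC separately for the pre-commercial
and commercial scenarios (one summary point per plot; 1,000-resample
bootstrap CI on the slope).

Writes results/pai.csv and results/structure_productivity.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from standthin import pai, read_tree_table, relation_points, structure_productivity_fit
from standthin.pipeline import _relation_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    trajectories = read_tree_table(ROOT / "results" / "tree_list.csv")
    from standthin import pai_table

    table = pai_table(trajectories)
    table.to_csv(ROOT / "results" / "pai.csv", index=False, lineterminator="\n")

    print("mean annual volume increment over the post-treatment period (m3/ha/yr):")
    for trt in ("CK", "TE3250", "TE2500", "TE1750", "TL400", "TL278", "TL156"):
        vals = []
        for tr in trajectories:
            if tr.treatment != trt:
                continue
            le = tr.last_event_age or tr.ages[0]
            series = pai(tr)
            vals.append(np.mean([v for a, v in series.entries.items() if a > le]))
        print(f"  {trt:>7}: {np.mean(vals):5.2f}")

    rel = _relation_table(trajectories, seed=1)
    rel.to_csv(ROOT / "results" / "structure_productivity.csv", index=False, lineterminator="\n")
    print("\nstructure-productivity slopes (PAI per unit Gini, bootstrap 95% CI):")
    for _, row in rel.iterrows():
        print(
            f"  {row.scenario:>15}: {row.slope:8.1f}  [{row.ci_low:.1f}, {row.ci_high:.1f}]"
        )
    print(
        "\npre-commercial productivity rises with thinning intensity while "
        "heterogeneity falls (negative slope); commercial productivity falls "
        "with intensity together with heterogeneity (positive slope)."
    )


if __name__ == "__main__":
    main()
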