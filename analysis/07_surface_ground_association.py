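#!/usr/bin/env python
"""Consistency of surface-water and groundwater contamination rankings.

Maps the absolute rank difference per country between the two score sets
(low = consistent pollution trend) and tests the association: Spearman
correlation (significance at p < 0.1) plus a simple regression of
groundwater scores on surface scores.
"""

import json
from pathlib import Path

from dataclasses import asdict

import pandas as pd

from pestiscore.association import associate, rank_difference_table
from pestiscore.data_io import write_results_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    surf = pd.read_csv(ROOT / "scores_surface.csv")
    ground = pd.read_csv(ROOT / "scores_ground.csv")

    ranks = rank_difference_table(surf, ground)
    write_results_table(ranks, ROOT / "rank_difference.csv")
    consistent = ranks[ranks["abs_rank_diff"] <= 1]
    print(f"{len(ranks)} countries in both compartments; "
          f"{len(consistent)} with |rank diff| <= 1 "
          f"(max diff {ranks['abs_rank_diff'].max():.0f})")

    res = associate(surf, ground)
    (ROOT / "association.json").write_text(
        json.dumps(asdict(res), indent=2) + "\n")
    flag = "significant" if res.spearman_significant_at_01 else "n.s."
    print(f"Spearman r={res.spearman_r:.2f} (p={res.spearman_p:.3f}, {flag} "
          f"at p<0.1); regression ground = {res.intercept:.2f} + "
          f"{res.slope:.2f}*surface, R²={res.r_squared:.2f}, "
          f"p={res.regression_p:.4f}")


if __name__ == "__main__":
    main()
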