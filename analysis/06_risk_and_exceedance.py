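#!/usr/bin/env python
"""Hazard-quotient screening and drinking-water exceedance rates.

Screens countries whose surface-water score exceeds 2 with the chronic
ingestion model (max detected site mean, adult residential defaults), then
computes per-country and global exceedance rates of the five screening
pesticides against national drinking-water standards with WHO fallback.
"""

from pathlib import Path

import pandas as pd

from pestiscore.data_io import (
    default_rfd_table,
    default_who_guidelines,
    harmonize_records,
    read_concentration_table,
    read_wqs_table,
    write_results_table,
)
from pestiscore.risk_exceedance import (
    exceedance_rates,
    hq_screen,
    screen_high_score_groups,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    scores = pd.read_csv(ROOT / "scores_surface.csv")
    surf, _ = read_concentration_table(ROOT / "synthetic" / "conc_surface.csv")
    ground, _ = read_concentration_table(ROOT / "synthetic" / "conc_ground.csv")
    surf = harmonize_records(surf).kept
    ground = harmonize_records(ground).kept

    hot = screen_high_score_groups(scores, threshold=2.0)
    print(f"countries with S > 2: {hot or 'none'}")
    screened = hot or screen_high_score_groups(scores, threshold=0.0)[:2]
    if not hot:
        print(f"  screening the top positive-score countries instead: "
              f"{screened}")
    hq = hq_screen(surf, screened, default_rfd_table())
    write_results_table(hq, ROOT / "hazard_quotients.csv")
    if not hq.empty:
        worst = hq.sort_values("hq", ascending=False).iloc[0]
        print(f"  max HQ {worst.hq:.2f} ({worst.country}, "
              f"CAS {worst.pesticide_cas}, C={worst.concentration_used:.3g} "
              f"ug/L); {int((hq.hq > 1).sum())} pesticide-country pairs "
              f"with HQ > 1")

    standards, _ = read_wqs_table(ROOT / "synthetic" / "drinking_standards.csv")
    rates, missing = exceedance_rates(surf + ground, standards,
                                      default_who_guidelines())
    write_results_table(rates, ROOT / "exceedance.csv")
    print("\nglobal exceedance of drinking-water standards:")
    glob = rates[rates["scope"] == "global"].sort_values("rate",
                                                         ascending=False)
    for _, row in glob.iterrows():
        print(f"  {row.pesticide_cas}: {100 * row.rate:.1f}% "
              f"({row.n_exceed}/{row.n_samples}, {row.standard_source})")
    if missing:
        print(f"  {len(missing)} pesticide-country pairs lacked any standard")


if __name__ == "__main__":
    main()
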