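#!/usr/bin/env python
"""Score every country's surface and groundwater pesticide contamination.

Reads the simulated monitoring tables, harmonizes them and writes one
score table per water body; prints the ranking with classification bands.
"""

from pathlib import Path

from pestiscore.contamination import score_all, site_table
from pestiscore.data_io import (
    harmonize_records,
    read_concentration_table,
    write_results_table,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    for water_body in ("surface", "ground"):
        records, rejects = read_concentration_table(
            ROOT / "synthetic" / f"conc_{water_body}.csv")
        result = harmonize_records(records)
        scores = score_all(site_table(result.kept, water_body),
                           water_body=water_body)
        write_results_table(scores, ROOT / f"scores_{water_body}.csv")

        print(f"\n{water_body} water — {len(result.kept)} records kept, "
              f"{len(result.excluded)} excluded, {len(rejects)} rejected")
        shown = scores.sort_values("score", ascending=False)
        for _, row in shown.iterrows():
            print(f"  {row.group_id}  S={row.score:+.2f}  M={row.n_sites:3d}  "
                  f"{row.band}")
        n_high = (shown["score"] > 2).sum()
        n_low = (shown["score"] <= 0).sum()
        print(f"  -> {n_high} countries significantly above the global level, "
              f"{n_low} at or below it")


if __name__ == "__main__":
    main()
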