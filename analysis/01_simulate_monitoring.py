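#!/usr/bin/env python
"""Generate the synthetic monitoring world every later analysis step reads.

Writes surface and groundwater concentration tables, the ground-truth
expected-score parameters, a synthetic standards table per medium and a
usage/land table under results/synthetic/.
"""

from pathlib import Path

import pandas as pd

from pestiscore.data_io import write_concentration_table
from pestiscore.synthetic import (
    default_config,
    default_ground_config,
    generate_dataset,
    generate_usage,
    generate_wqs,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20260928


def wqs_frame(records):
    return pd.DataFrame(
        [(r.jurisdiction, r.pesticide_cas, r.medium, r.value, "ug/L",
          r.system_id) for r in records],
        columns=["jurisdiction", "pesticide_cas", "medium", "value", "unit",
                 "system_id"])


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    surf = default_config(SEED)
    ground = default_ground_config(SEED + 1)

    for cfg, name in [(surf, "surface"), (ground, "ground")]:
        records = generate_dataset(cfg)
        write_concentration_table(records, OUT / f"conc_{name}.csv")
        truth = pd.DataFrame(
            [(c.code, c.n_sites, c.offset) for c in cfg.countries],
            columns=["group_id", "n_sites", "offset_log10"])
        truth.to_csv(OUT / f"truth_{name}.csv", index=False)
        print(f"{name}: {len(records)} records, "
              f"{sum(c.n_sites for c in cfg.countries)} sites, "
              f"{len(cfg.countries)} countries")

    wqs_frame(generate_wqs(surf, medium="surface")
              + generate_wqs(ground, medium="ground")
              ).to_csv(OUT / "wqs.csv", index=False)
    # five countries set national drinking-water standards; the rest will
    # fall back to WHO guideline values downstream
    wqs_frame(generate_wqs(
        surf, medium="drinking",
        jurisdictions=[c.code for c in surf.countries[:5]]
    )).to_csv(OUT / "drinking_standards.csv", index=False)

    usage = generate_usage(surf)
    pd.DataFrame([(r.country, r.year, r.pesticide_use, r.agricultural_land)
                  for r in usage],
                 columns=["country", "year", "pesticide_use_t",
                          "agri_land_km2"]).to_csv(OUT / "usage.csv",
                                                   index=False)
    print(f"standards: {OUT / 'wqs.csv'}; usage: {OUT / 'usage.csv'}")


if __name__ == "__main__":
    main()
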