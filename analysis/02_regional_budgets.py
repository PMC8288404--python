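#!/usr/bin/env python
"""Bottom-up net ecosystem exchange: regional values and global aggregates.

Reads results/budget_table.csv (from 01_build_budget_table.py), computes
every regional NEE with quadrature errors, the tropical and northern-
hemisphere sums, and the global total and anthropogenic NEE.  Writes
results/nee_summary.csv and results/global_nee.json.

Expected headline numbers: a small tropical sink (-0.55 +/- 0.47), a larger
northern sink (-1.8 +/- 0.4), a global land uptake of -2.8 +/- 0.7 and an
anthropogenic uptake of -2.2 PgC yr^-1.
"""

import argparse
from pathlib import Path

import pandas as pd

from carbonledger import REGIONS, aggregate, global_nee, regional_nee, round_printed
from carbonledger.budget_core import NORTHERN_REGIONS, TROPICAL_REGIONS
from carbonledger.io_cli import read_budget_table, write_json


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--table", type=Path, default=Path("results/budget_table.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = read_budget_table(args.table)
    nees = {r: regional_nee(table.regions[r]) for r in REGIONS}
    pd.DataFrame(
        [{"region": r, "nee_value": e.value, "nee_sigma": e.sigma} for r, e in nees.items()]
    ).to_csv(args.out / "nee_summary.csv", index=False)

    tropical = aggregate([nees[r] for r in TROPICAL_REGIONS])
    northern = aggregate([nees[r] for r in NORTHERN_REGIONS])
    total, anthro = global_nee(table)
    write_json(
        {
            "tropical": {"value": tropical.value, "sigma": tropical.sigma},
            "northern": {"value": northern.value, "sigma": northern.sigma},
            "total": {"value": total.value, "sigma": total.sigma},
            "anthropogenic": {"value": anthro.value, "sigma": anthro.sigma},
        },
        args.out / "global_nee.json",
    )

    fmt = lambda e: f"{round_printed(e.value):+.1f} +/- {round_printed(e.sigma):.1f}"
    print(f"tropical regions   {fmt(tropical)} PgC/yr")
    print(f"northern regions   {fmt(northern)} PgC/yr")
    print(f"global total       {fmt(total)} PgC/yr")
    print(f"anthropogenic      {round_printed(anthro.value):+.1f} PgC/yr")


if __name__ == "__main__":
    main()
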