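#!/usr/bin/env python
"""Assemble the study-style summary tables and the sire-EBV regression.

Produces: the first-parity category cost table (LSM, SEM, percent of total
health cost, treatment frequency), the parity distribution, and the
regression of per-sire daughter THC means on sire EBVs for sires with at
least 10 daughters -- raw and herd-adjusted slopes.  All tables land in
results/ as CSV plus a plain-text rendering.
"""

from pathlib import Path

import pandas as pd

from herdhealth.report import (
    category_cost_table,
    parity_distribution,
    render_summary,
    sire_daughter_regression,
)

ROOT = Path(__file__).resolve().parent.parent
HERD = ROOT / "scratch" / "herd"
RESULTS = ROOT / "results"


def main() -> None:
    phen = pd.read_csv(HERD / "phenotypes.csv")
    events = pd.read_csv(HERD / "events_clean.csv")
    pedigree = pd.read_csv(HERD / "pedigree.csv", dtype=str)
    lsm_tab = pd.read_csv(RESULTS / "lsm_univariate.csv")
    lsm = {r.trait: (r.lsm, r.sem) for r in lsm_tab.itertuples()}

    costs = category_cost_table(phen, events=events, lsm=lsm)
    costs.round(2).to_csv(RESULTS / "table_category_costs.csv", index=False)

    parity = parity_distribution(phen)
    parity.to_csv(RESULTS / "table_parity.csv", index=False)

    ebv_table = pd.read_csv(RESULTS / "ebv_sires.csv", index_col=0)
    reg = sire_daughter_regression(ebv_table, phen, pedigree, min_daughters=10)
    reg_adj = sire_daughter_regression(
        ebv_table, phen, pedigree, min_daughters=10, herd_adjust=True
    )
    reg.table.round(2).to_csv(RESULTS / "sire_regression.csv", index=False)

    text = render_summary(costs, "Category treatment costs, first parity")
    text += "\n" + render_summary(parity, "Lactations by parity")
    text += (
        f"\nSire EBV regression ({len(reg.table)} sires with >= "
        f"{reg.min_daughters} daughters):\n"
        f"  slope (raw daughter means)          {reg.slope:.2f}\n"
        f"  slope (herd-adjusted daughter means) {reg_adj.slope:.2f}\n"
        f"  EBV spread ${reg.ebv_range:.0f}\n"
    )
    (RESULTS / "summary.txt").write_text(text)
    print(text)
    print(f"wrote tables to {RESULTS}")


if __name__ == "__main__":
    main()
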