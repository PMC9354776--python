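#!/usr/bin/env python
"""Select differential metabolites (VIP > 1 and Welch-t p < 0.05) and check
recovery of the planted truth; also writes the metabolite correlation matrix.
"""

import json
from pathlib import Path

import pandas as pd

from macsnet.datatypes import MetaboliteTable
from macsnet.differential import (metabolite_correlation, select_differential,
                                  univariate_test)
from macsnet.multivariate import compute_vip, fit_oplsda

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    table = MetaboliteTable.from_tsv(RESULTS / "inputs" / "metabolite_table.tsv")
    truth = json.loads((RESULTS / "inputs" / "truth.json").read_text())
    vip = compute_vip(fit_oplsda(table, 1))
    pvals = univariate_test(table)
    diff = select_differential(vip, pvals, table)

    pd.DataFrame([d.__dict__ for d in diff]).to_csv(
        RESULTS / "03_differential_metabolites.tsv", sep="\t", index=False)
    ids = [d.metabolite_id for d in diff]
    if len(ids) >= 2:
        r, _ = metabolite_correlation(table, ids)
        r.to_csv(RESULTS / "03_correlation.tsv", sep="\t")

    planted = set(truth["differential_metabolites"])
    found = set(ids)
    print(f"selected {len(diff)} differential metabolites "
          f"({sum(d.direction == 'up' for d in diff)} up, "
          f"{sum(d.direction == 'down' for d in diff)} down)")
    print(f"planted recovery: {len(planted & found)}/{len(planted)}; "
          f"false positives: {len(found - planted)}")


if __name__ == "__main__":
    main()
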