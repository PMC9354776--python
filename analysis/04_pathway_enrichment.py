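#!/usr/bin/env python
"""Over-representation of the differential metabolites across pathways:
hypergeometric p, Holm and BH adjustment, topology impact, core flags.
"""

import json
from pathlib import Path

import pandas as pd

from macsnet.enrichment import enrich_pathways, load_pathway_db, results_to_frame

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    diff = pd.read_csv(RESULTS / "03_differential_metabolites.tsv", sep="\t")
    hits = set(diff["metabolite_id"])
    table = pd.read_csv(RESULTS / "inputs" / "metabolite_table.tsv", sep="\t",
                        index_col="sample_id")
    universe = set(table.columns) - {"group"}
    pathways = load_pathway_db(RESULTS / "inputs" / "pathway_db.json")
    res = enrich_pathways(hits, pathways, universe)
    frame = results_to_frame(res).sort_values("raw_p")
    frame.to_csv(RESULTS / "04_pathway_enrichment.tsv", sep="\t", index=False)

    truth = json.loads((RESULTS / "inputs" / "truth.json").read_text())
    core = [r.pathway_id for r in res if r.is_core]
    print(frame.to_string(index=False,
                          formatters={"raw_p": "{:.4g}".format,
                                      "holm_p": "{:.4g}".format,
                                      "fdr_q": "{:.4g}".format,
                                      "impact": "{:.3f}".format}))
    print(f"core pathways (raw p < 0.05): {core}")
    print(f"planted core pathways:        {truth['planted_core_pathways']}")


if __name__ == "__main__":
    main()
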