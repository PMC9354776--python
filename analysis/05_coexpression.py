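#!/usr/bin/env python
"""Map core-pathway differential metabolites to metabolic genes and compute
the consensus target x metabolic-gene coexpression matrix over the cohorts.
"""

from pathlib import Path

import pandas as pd

from macsnet.coexpression import (aggregate_coexpression, compute_coexpression,
                                  filter_candidate_targets)
from macsnet.datatypes import ExpressionDataset
from macsnet.differential import DifferentialMetabolite
from macsnet.enrichment import load_pathway_db
from macsnet.network import load_annotation, map_metabolites_to_genes

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    enr = pd.read_csv(RESULTS / "04_pathway_enrichment.tsv", sep="\t")
    core_ids = set(enr.loc[enr["is_core"], "pathway_id"])
    core = [p for p in load_pathway_db(RESULTS / "inputs" / "pathway_db.json")
            if p.pathway_id in core_ids]
    diff_tab = pd.read_csv(RESULTS / "03_differential_metabolites.tsv", sep="\t")
    diff = [DifferentialMetabolite(r.metabolite_id, r.vip, r.p_value, r.direction,
                                   r.control_mean, r.treated_mean)
            for r in diff_tab.itertuples()]
    ann = load_annotation(RESULTS / "inputs" / "annotation.tsv")
    _, genes = map_metabolites_to_genes(core, diff, ann)
    (RESULTS / "05_metabolic_genes.txt").write_text("".join(f"{g}\n" for g in genes))

    targets = [t for t in (RESULTS / "inputs" / "targets.txt").read_text().split()
               if t]
    mats = []
    for p in sorted((RESULTS / "inputs").glob("expression_*.tsv")):
        ds = ExpressionDataset.from_tsv(p, dataset_id=p.stem)
        mats.append(compute_coexpression(ds, genes, targets, subset="tumor"))
    consensus = aggregate_coexpression(mats)
    consensus.r.to_csv(RESULTS / "05_coexpression_consensus.tsv", sep="\t",
                       index_label="target")
    kept = filter_candidate_targets(consensus, r_min=0.3)
    print(f"{len(genes)} metabolic genes behind core-pathway differential metabolites")
    print(f"consensus matrix over {len(mats)} cohorts: "
          f"{consensus.r.shape[0]} targets x {consensus.r.shape[1]} genes")
    print(f"candidates with max |r| >= 0.3: {len(kept)}/{len(targets)}: {kept}")


if __name__ == "__main__":
    main()
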