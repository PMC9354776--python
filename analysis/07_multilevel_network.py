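#!/usr/bin/env python
"""Assemble the compound-target-gene-metabolite-pathway network from the
retained targets and export it as GraphML and SIF.
"""

from pathlib import Path

import networkx as nx
import pandas as pd

from macsnet.differential import DifferentialMetabolite
from macsnet.enrichment import load_pathway_db
from macsnet.network import (build_multilevel_network, load_annotation,
                             map_metabolites_to_genes, write_graphml, write_sif)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    macs = pd.read_csv(RESULTS / "06_macs_targets.tsv", sep="\t")
    retained = list(macs.loc[macs["retained"], "target"])
    enr = pd.read_csv(RESULTS / "04_pathway_enrichment.tsv", sep="\t")
    core_ids = set(enr.loc[enr["is_core"], "pathway_id"])
    core = [p for p in load_pathway_db(RESULTS / "inputs" / "pathway_db.json")
            if p.pathway_id in core_ids]
    diff_tab = pd.read_csv(RESULTS / "03_differential_metabolites.tsv", sep="\t")
    diff = [DifferentialMetabolite(r.metabolite_id, r.vip, r.p_value, r.direction,
                                   r.control_mean, r.treated_mean)
            for r in diff_tab.itertuples()]
    ann = load_annotation(RESULTS / "inputs" / "annotation.tsv")
    bip, genes = map_metabolites_to_genes(core, diff, ann)

    links_df = pd.read_csv(RESULTS / "inputs" / "target_gene_links.tsv", sep="\t",
                           dtype=str)
    links = [(t, g) for t, g in links_df.itertuples(index=False, name=None)
             if g in set(genes)]
    memberships = {p.pathway_id: list(p.members) for p in core}
    net = build_multilevel_network("DEMO_COMPOUND", retained, links, bip,
                                   memberships)
    write_graphml(net, RESULTS / "07_multilevel_network.graphml")
    write_sif(net, RESULTS / "07_multilevel_network.sif")

    layers = nx.get_node_attributes(net, "layer")
    counts = pd.Series(list(layers.values())).value_counts().to_dict()
    print(f"network: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges, "
          f"{nx.number_connected_components(net)} component(s)")
    print(f"layer sizes: {counts}")


if __name__ == "__main__":
    main()
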