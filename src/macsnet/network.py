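"""Metabolite→gene mapping and the compound–target–gene–metabolite–pathway
multilevel network.

The multilevel network has five typed node layers — compound, target,
metabolic_gene, metabolite, pathway — and typed edges between adjacent layers:
compound→target (predicted drug targets), target–metabolic_gene (protein
association links, supplied as a table), metabolic_gene–metabolite (annotation
of differential metabolites in core pathways), and metabolite–pathway
(membership). Exported as GraphML (round-trippable) and SIF.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .differential import DifferentialMetabolite
from .enrichment import PathwayDefinition

__all__ = [
    "map_metabolites_to_genes",
    "build_multilevel_network",
    "write_graphml",
    "read_graphml",
    "write_sif",
    "LAYERS",
]

logger = logging.getLogger(__name__)

LAYERS = ("compound", "target", "metabolic_gene", "metabolite", "pathway")


def load_annotation(path) -> pd.DataFrame:
    """Read the metabolite→gene annotation TSV (columns metabolite_id, gene_id)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    need = {"metabolite_id", "gene_id"}
    if not need <= set(df.columns):
        raise ValueError(f"annotation table must have columns {sorted(need)}")
    return df


def map_metabolites_to_genes(core_pathways: list[PathwayDefinition],
                             differential: list[DifferentialMetabolite],
                             annotation: pd.DataFrame):
    """Metabolic genes behind the differential metabolites of core pathways.

    Returns (bipartite metabolite–gene graph, sorted gene list). Only
    differential metabolites that are members of at least one core pathway
    contribute; their genes come from the annotation table.
    """
    core_members = set()
    for pw in core_pathways:
        core_members |= set(pw.members)
    diff_ids = {d.metabolite_id for d in differential}
    active = sorted(diff_ids & core_members)
    ann = annotation.groupby("metabolite_id")["gene_id"].agg(lambda s: sorted(set(s)))
    bip = nx.Graph()
    genes: set[str] = set()
    for m in active:
        for g in ann.get(m, []):
            bip.add_node(m, bipartite="metabolite")
            bip.add_node(g, bipartite="gene")
            bip.add_edge(m, g)
            genes.add(g)
    if not genes:
        raise ValueError(
            "no metabolic genes found: check that the annotation table covers the "
            "differential metabolites of the core pathways"
        )
    return bip, sorted(genes)


def build_multilevel_network(compound_id: str, retained_targets,
                             target_gene_links, metabolite_gene_graph: nx.Graph,
                             pathway_memberships: dict) -> nx.Graph:
    """Assemble the five-layer network.

    ``target_gene_links`` is an iterable of (target, metabolic_gene) pairs;
    ``pathway_memberships`` maps pathway id -> member metabolite ids (only
    metabolites present in the metabolite–gene graph are linked). Duplicate
    edges collapse; dangling references raise.
    """
    g = nx.Graph()
    metabolites = sorted(n for n, d in metabolite_gene_graph.nodes(data=True)
                         if d.get("bipartite") == "metabolite")
    genes = sorted(n for n, d in metabolite_gene_graph.nodes(data=True)
                   if d.get("bipartite") == "gene")
    targets = sorted(set(retained_targets))

    layered = {compound_id: "compound"}
    for ids, layer in ((targets, "target"), (genes, "metabolic_gene"),
                       (metabolites, "metabolite"),
                       (sorted(pathway_memberships), "pathway")):
        for node in ids:
            if node in layered:
                raise ValueError(
                    f"node id {node!r} appears in layers {layered[node]!r} and {layer!r}"
                )
            layered[node] = layer

    g.add_node(compound_id, layer="compound")
    for t in targets:
        g.add_node(t, layer="target")
        g.add_edge(compound_id, t, edge_type="compound-target")
    for mg in genes:
        g.add_node(mg, layer="metabolic_gene")
    for m in metabolites:
        g.add_node(m, layer="metabolite")
    for pw in sorted(pathway_memberships):
        g.add_node(pw, layer="pathway")

    for t, mg in target_gene_links:
        if t not in targets:
            continue  # link table may cover unretained targets
        if mg not in set(genes):
            raise ValueError(f"target-gene link references unknown metabolic gene {mg!r}")
        g.add_edge(t, mg, edge_type="target-metabolic_gene")
    for m, mg in metabolite_gene_graph.edges():
        a, b = (m, mg) if metabolite_gene_graph.nodes[m].get("bipartite") == "metabolite" else (mg, m)
        g.add_edge(b, a, edge_type="metabolic_gene-metabolite")
    for pw, members in pathway_memberships.items():
        for m in members:
            if m in set(metabolites):
                g.add_edge(m, pw, edge_type="metabolite-pathway")

    n_comp = nx.number_connected_components(g)
    logger.info("multilevel network: %d nodes, %d edges, %d connected component(s)",
                g.number_of_nodes(), g.number_of_edges(), n_comp)
    return g


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def write_sif(g: nx.Graph, path) -> None:
    """SIF with the edge type as the relation column."""
    with open(path, "w") as fh:
        for u, v, d in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{d.get('edge_type', 'link')}\t{v}\n")
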