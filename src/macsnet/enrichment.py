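"""Metabolite-set over-representation analysis with topology-based impact.

Each pathway is tested with the one-sided hypergeometric tail (equivalently a
right-tailed Fisher exact test) against the universe of detected metabolites,
adjusted by Holm (FWER) and Benjamini–Hochberg (FDR). Pathway impact follows
the MetPA convention: the sum of relative betweenness centralities of the hit
members divided by the sum over all members. Pathways with raw p below
``core_alpha`` (0.05 by default) are flagged as core pathways; the core flag
is what gates the downstream target-scoring stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PathwayDefinition",
    "EnrichmentResult",
    "ora_hypergeometric",
    "adjust_holm",
    "adjust_bh",
    "pathway_impact",
    "flag_core_pathways",
    "enrich_pathways",
    "load_pathway_db",
    "save_pathway_db",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayDefinition:
    """A metabolic pathway: member metabolites plus an undirected graph."""

    pathway_id: str
    name: str
    members: tuple
    edges: tuple  # tuple of (u, v) pairs over members

    def __post_init__(self):
        object.__setattr__(self, "members", tuple(self.members))
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))
        if len(self.members) < 2:
            raise ValueError(f"pathway {self.pathway_id} needs >= 2 members")
        mem = set(self.members)
        for u, v in self.edges:
            if u not in mem or v not in mem:
                raise ValueError(
                    f"pathway {self.pathway_id}: edge ({u}, {v}) references non-members"
                )

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.members)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    name: str
    n_members: int
    overlap: int
    raw_p: float
    holm_p: float = np.nan
    fdr_q: float = np.nan
    impact: float = np.nan
    is_core: bool = False


def ora_hypergeometric(hits, pathway: PathwayDefinition, universe) -> float:
    """P(X >= overlap) under Hypergeometric(N=|universe|, K=|pathway∩universe|,
    n=|hits|); the upper tail includes the observed overlap itself."""
    universe = set(universe)
    hits = set(hits)
    if not universe:
        raise ValueError("empty metabolite universe")
    if not hits <= universe:
        raise ValueError(f"hits outside universe: {sorted(hits - universe)}")
    members = set(pathway.members) & universe
    if not members:
        raise ValueError(f"pathway {pathway.pathway_id} shares no metabolites with universe")
    overlap = len(hits & members)
    return float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(hits)))


def _check_pvals(pvals) -> np.ndarray:
    p = np.asarray(list(pvals), dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p


def adjust_holm(pvals) -> list[float]:
    """Holm step-down adjusted p-values, in the input order, capped at 1."""
    p = _check_pvals(pvals)
    if p.size == 0:
        return []
    return multipletests(p, method="holm")[1].tolist()


def adjust_bh(pvals) -> list[float]:
    """Benjamini–Hochberg q-values, in the input order, capped at 1."""
    p = _check_pvals(pvals)
    if p.size == 0:
        return []
    return multipletests(p, method="fdr_bh")[1].tolist()


def pathway_impact(pathway: PathwayDefinition, hits) -> float:
    """Sum of relative betweenness centralities of hit members over the sum
    across all members; 0 when no member has positive centrality."""
    hits = set(hits)
    stray = hits - set(pathway.members)
    if stray:
        logger.info("pathway %s: ignoring %d hits outside pathway",
                    pathway.pathway_id, len(stray))
        hits &= set(pathway.members)
    bc = nx.betweenness_centrality(pathway.graph(), normalized=True)
    total = sum(bc.values())
    if total <= 0:
        return 0.0
    return float(sum(bc[m] for m in hits) / total)


def flag_core_pathways(results: list[EnrichmentResult],
                       core_alpha: float = 0.05) -> list[EnrichmentResult]:
    """Set is_core on each result: core iff raw p < core_alpha (strict)."""
    if not 0 < core_alpha <= 1:
        raise ValueError("core_alpha must be in (0, 1]")
    return [replace(r, is_core=bool(r.raw_p < core_alpha)) for r in results]


def enrich_pathways(hits, pathways: list[PathwayDefinition], universe,
                    core_alpha: float = 0.05) -> list[EnrichmentResult]:
    """Full over-representation analysis of ``hits`` against every pathway."""
    raw = [ora_hypergeometric(hits, pw, universe) for pw in pathways]
    holm = adjust_holm(raw)
    fdr = adjust_bh(raw)
    hit_set = set(hits)
    results = [
        EnrichmentResult(
            pathway_id=pw.pathway_id, name=pw.name, n_members=len(pw.members),
            overlap=len(hit_set & set(pw.members) & set(universe)),
            raw_p=raw[i], holm_p=holm[i], fdr_q=fdr[i],
            impact=pathway_impact(pw, hit_set),
        )
        for i, pw in enumerate(pathways)
    ]
    return flag_core_pathways(results, core_alpha)


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(pathway_id=r.pathway_id, name=r.name, n_members=r.n_members,
                 overlap=r.overlap, raw_p=r.raw_p, holm_p=r.holm_p,
                 fdr_q=r.fdr_q, impact=r.impact, is_core=r.is_core)
            for r in results
        ]
    )


def load_pathway_db(path) -> list[PathwayDefinition]:
    """Read the JSON pathway DB: [{id, name, members[], edges[][2]}]."""
    with open(path) as fh:
        raw = json.load(fh)
    return [
        PathwayDefinition(pathway_id=d["id"], name=d.get("name", d["id"]),
                          members=d["members"], edges=d.get("edges", []))
        for d in raw
    ]


def save_pathway_db(pathways: list[PathwayDefinition], path) -> None:
    data = [
        dict(id=p.pathway_id, name=p.name, members=list(p.members),
             edges=[list(e) for e in p.edges])
        for p in pathways
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
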