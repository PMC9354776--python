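"""Maximum activity contribution score (MACS): mutual-information target ranking.

The score asks how much each candidate drug target contributes to the activity
of the *core* metabolic pathways (those enriched in differential metabolites)
while avoiding redundancy with targets already selected — the classic
max-relevance / min-redundancy (mRMR) trade-off:

* relevance   D(g) = mean over core pathways y of I(g; y)
* redundancy  R(g | S) = (1/|S|) * sum over selected s of I(g; s)
* score       aleph(g | S) = D(g) − R(g | S)

Pathway activity (the random variable y) is operationalized per sample as the
standardized mean of the z-scored expression of the pathway's metabolic genes.
Greedy forward selection ranks every candidate; each target keeps the marginal
score it had when selected. Rankings from several expression cohorts are
aggregated (mean by default) and targets scoring strictly above the average
aggregated score are retained as core targets. All MI values are in nats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset
from .mi import MIEstimatorConfig, estimate_mi

__all__ = [
    "PathwayActivity",
    "MACSResult",
    "pathway_activity",
    "relevance",
    "greedy_mrmr_rank",
    "macs_scores",
    "results_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayActivity:
    """Per-sample activity of one core pathway in one cohort (zero mean,
    unit variance)."""

    pathway_id: str
    values: np.ndarray
    genes: tuple

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "genes", tuple(self.genes))


@dataclass(frozen=True)
class MACSResult:
    target: str
    rank: int                 # 1-based selection order
    relevance: float          # D, nats
    redundancy: float         # R at selection, nats
    score: float              # marginal aleph = D − R at selection
    retained: bool = False


def pathway_activity(dataset: ExpressionDataset, pathway_id: str, genes,
                     subset: str = "tumor") -> PathwayActivity:
    """Standardized mean of z-scored constituent-gene expression.

    Raises if no constituent gene is present or if the averaged signal is
    degenerate (variance below 1e-10, e.g. mutually cancelling genes).
    """
    X = dataset.subset(subset)
    present = [g for g in genes if g in X.columns]
    if not present:
        raise ValueError(
            f"pathway {pathway_id}: none of its genes are in dataset {dataset.dataset_id}"
        )
    if len(present) < len(list(genes)):
        logger.info("pathway %s: %d/%d genes present in %s", pathway_id,
                    len(present), len(list(genes)), dataset.dataset_id)
    M = X[present].to_numpy(dtype=float)
    sd = M.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    z = (M - M.mean(axis=0)) / sd
    act = z.mean(axis=1)
    v = act.std(ddof=1)
    if v**2 < 1e-10:
        raise ValueError(f"pathway {pathway_id}: degenerate activity (variance < 1e-10)")
    act = (act - act.mean()) / v
    return PathwayActivity(pathway_id=pathway_id, values=act, genes=present)


def relevance(x, activities: list[PathwayActivity],
              config: MIEstimatorConfig | None = None) -> float:
    """Mean mutual information between a target vector and the core-pathway
    activities (nats)."""
    if not activities:
        raise ValueError("no core pathways: relevance is undefined")
    return float(np.mean([estimate_mi(x, a.values, config) for a in activities]))


def greedy_mrmr_rank(candidates: dict, activities: list[PathwayActivity],
                     config: MIEstimatorConfig | None = None) -> list[MACSResult]:
    """Rank all candidate targets by greedy forward mRMR selection.

    ``candidates`` maps target id -> expression vector (same length as the
    activities). The first pick maximizes relevance; each later pick maximizes
    aleph(g) = D(g) − mean MI with already-selected targets. Ties are broken
    by lexicographically smallest target id.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate targets")
    ids = sorted(candidates)
    n = activities[0].values.size if activities else 0
    vectors = {}
    for g in ids:
        v = np.asarray(candidates[g], dtype=float).ravel()
        if v.size != n:
            raise ValueError(f"candidate {g}: length {v.size} != activity length {n}")
        vectors[g] = v
    D = {g: relevance(vectors[g], activities, config) for g in ids}
    red_sum = {g: 0.0 for g in ids}
    remaining = list(ids)
    results: list[MACSResult] = []
    while remaining:
        k = len(results)
        best, best_score, best_red = None, -np.inf, 0.0
        for g in remaining:  # lexicographic tie-break via sorted order + strict >
            r = red_sum[g] / k if k else 0.0
            s = D[g] - r
            if s > best_score:
                best, best_score, best_red = g, s, r
        results.append(MACSResult(target=best, rank=k + 1, relevance=D[best],
                                  redundancy=best_red, score=best_score))
        remaining.remove(best)
        for g in remaining:
            red_sum[g] += estimate_mi(vectors[g], vectors[best], config)
    return results


def macs_scores(per_dataset_rankings: list[list[MACSResult]],
                aggregation: str = "mean") -> list[MACSResult]:
    """Aggregate per-cohort marginal scores and flag retained targets.

    A target is retained iff its aggregated score is strictly greater than the
    mean aggregated score over the shared candidate set. Returned results are
    re-ranked by descending aggregated score (ties by id).
    """
    if aggregation not in ("mean", "median"):
        raise ValueError("aggregation must be mean or median")
    if not per_dataset_rankings:
        raise ValueError("no rankings supplied")
    sets = [set(r.target for r in ranking) for ranking in per_dataset_rankings]
    shared = set.intersection(*sets)
    if not shared:
        raise ValueError("empty intersection of candidate sets across datasets")
    if any(s != shared for s in sets):
        logger.warning("candidate sets differ across datasets; using %d shared targets",
                       len(shared))
    scores = {}
    rels = {}
    reds = {}
    for g in sorted(shared):
        vals = []
        rv, dv = [], []
        for ranking in per_dataset_rankings:
            rec = next(r for r in ranking if r.target == g)
            vals.append(rec.score)
            rv.append(rec.redundancy)
            dv.append(rec.relevance)
        agg = np.mean if aggregation == "mean" else np.median
        scores[g] = float(agg(vals))
        rels[g] = float(agg(dv))
        reds[g] = float(agg(rv))
    mean_score = float(np.mean(list(scores.values())))
    if all(abs(s - mean_score) < 1e-15 for s in scores.values()):
        logger.warning("all aggregated scores equal; nothing retained")
    order = sorted(scores, key=lambda g: (-scores[g], g))
    return [
        MACSResult(target=g, rank=i + 1, relevance=rels[g], redundancy=reds[g],
                   score=scores[g], retained=bool(scores[g] > mean_score))
        for i, g in enumerate(order)
    ]


def results_to_frame(results: list[MACSResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(target=r.target, rank=r.rank, relevance_nats=r.relevance,
              redundancy_nats=r.redundancy, score_nats=r.score, retained=r.retained)
         for r in results]
    )
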