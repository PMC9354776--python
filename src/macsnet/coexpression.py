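"""Coexpression of candidate drug targets with metabolic genes across cohorts.

For each expression cohort, a targets x metabolic-genes Pearson correlation
matrix is computed over a chosen sample subset (tumor by default — the disease
state is where target–metabolism coupling matters). Cohort matrices are then
aggregated element-wise (median by default, robust to one discordant cohort)
and candidates whose strongest absolute consensus correlation falls below
``r_min`` are dropped before target scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionDataset

__all__ = [
    "CoexpressionMatrix",
    "compute_coexpression",
    "aggregate_coexpression",
    "filter_candidate_targets",
]

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionMatrix:
    dataset_id: str
    r: pd.DataFrame        # rows = targets, columns = metabolic genes
    p: pd.DataFrame
    n_samples: int


def _pearson_block(A: np.ndarray, B: np.ndarray):
    """Pearson r and two-sided p between columns of A (targets) and B (genes)."""
    n = A.shape[0]
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    sa = Ac.std(axis=0, ddof=1)
    sb = Bc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ac.T @ Bc) / ((n - 1) * np.outer(sa, sb))
    r[~np.isfinite(r)] = np.nan
    rr = np.clip(r, -1.0, 1.0)
    ab = n / 2.0 - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 2.0 * stats.beta.sf(np.abs(rr), ab, ab, loc=-1, scale=2)
    p = np.where(np.isnan(r), np.nan, np.minimum(p, 1.0))
    return r, p


def compute_coexpression(dataset: ExpressionDataset, metabolic_genes, targets,
                         subset: str = "tumor") -> CoexpressionMatrix:
    """Targets x metabolic-genes Pearson correlation over the sample subset.

    Genes missing from the cohort are reported and skipped; constant genes
    yield missing cells. Requires >= 4 samples in the subset.
    """
    X = dataset.subset(subset)
    if X.shape[0] < 4:
        raise ValueError(
            f"dataset {dataset.dataset_id}: only {X.shape[0]} '{subset}' samples (< 4)"
        )
    mg = [g for g in metabolic_genes if g in X.columns]
    tg = [g for g in targets if g in X.columns]
    miss = sorted((set(metabolic_genes) | set(targets)) - set(X.columns))
    if miss:
        logger.warning("dataset %s: %d requested genes absent: %s",
                       dataset.dataset_id, len(miss), miss[:10])
    if not mg or not tg:
        raise ValueError(f"dataset {dataset.dataset_id}: no usable metabolic genes or targets")
    r, p = _pearson_block(X[tg].to_numpy(dtype=float), X[mg].to_numpy(dtype=float))
    return CoexpressionMatrix(
        dataset_id=dataset.dataset_id,
        r=pd.DataFrame(r, index=tg, columns=mg),
        p=pd.DataFrame(p, index=tg, columns=mg),
        n_samples=X.shape[0],
    )


def aggregate_coexpression(matrices: list[CoexpressionMatrix],
                           method: str = "median") -> CoexpressionMatrix:
    """Element-wise consensus over cohorts on the shared row/column ids."""
    if method not in ("median", "mean"):
        raise ValueError("method must be median or mean")
    if not matrices:
        raise ValueError("no matrices to aggregate")
    rows = sorted(set.intersection(*[set(m.r.index) for m in matrices]))
    cols = sorted(set.intersection(*[set(m.r.columns) for m in matrices]))
    if not rows or not cols:
        raise ValueError("empty row/column intersection across cohorts")
    stack = np.stack([m.r.loc[rows, cols].to_numpy(dtype=float) for m in matrices])
    agg = np.nanmedian(stack, axis=0) if method == "median" else np.nanmean(stack, axis=0)
    pstack = np.stack([m.p.loc[rows, cols].to_numpy(dtype=float) for m in matrices])
    pagg = np.nanmedian(pstack, axis=0) if method == "median" else np.nanmean(pstack, axis=0)
    return CoexpressionMatrix(
        dataset_id="consensus",
        r=pd.DataFrame(agg, index=rows, columns=cols),
        p=pd.DataFrame(pagg, index=rows, columns=cols),
        n_samples=int(min(m.n_samples for m in matrices)),
    )


def filter_candidate_targets(consensus: CoexpressionMatrix,
                             r_min: float = 0.3) -> list[str]:
    """Targets whose max |consensus r| over metabolic genes reaches r_min.

    Set ``r_min=0`` to disable the gate (every target passes).
    """
    if consensus.r.empty:
        raise ValueError("empty consensus matrix")
    best = consensus.r.abs().max(axis=1)
    kept = [t for t in consensus.r.index if best[t] >= r_min or r_min <= 0]
    logger.info("coexpression gate: %d/%d targets at r_min=%.3g",
                len(kept), consensus.r.shape[0], r_min)
    return kept
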