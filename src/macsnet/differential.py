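"""Differential-metabolite selection and metabolite correlation analysis.

Selection follows the two-criterion rule standard in metabolomics: a
metabolite is differential iff its multivariate VIP exceeds 1 *and* its
univariate two-sided Welch t-test p-value is below 0.05, both strictly.
No multiple-testing correction is applied at this stage; correction enters
only in pathway enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MetaboliteTable

__all__ = [
    "DifferentialMetabolite",
    "univariate_test",
    "select_differential",
    "metabolite_correlation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DifferentialMetabolite:
    metabolite_id: str
    vip: float
    p_value: float
    direction: str            # "up" | "down" in the treated group
    control_mean: float
    treated_mean: float


def univariate_test(table: MetaboliteTable) -> dict:
    """Two-sided Welch t-test per metabolite; returns id -> p-value.

    A metabolite constant within both groups (zero variance, equal means)
    has no evidence either way; its p is set to 1 by convention.
    """
    lo, hi = table.group_levels
    X = table.matrix()
    a = X[table.groups.to_numpy() == lo]
    b = X[table.groups.to_numpy() == hi]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, equal_var=False, axis=0)
    pvals = np.asarray(res.pvalue, dtype=float)
    nan_mask = ~np.isfinite(pvals)
    if nan_mask.any():
        logger.warning(
            "%d metabolite(s) with degenerate variance: p set to 1", int(nan_mask.sum())
        )
        pvals = np.where(nan_mask, 1.0, pvals)
    return dict(zip(table.metabolite_ids, pvals.tolist()))


def select_differential(vip: dict, pvals: dict, table: MetaboliteTable,
                        vip_threshold: float = 1.0,
                        p_threshold: float = 0.05) -> list[DifferentialMetabolite]:
    """Retain metabolites with VIP > vip_threshold and p < p_threshold (strict).

    Direction is 'up' when the treated-group mean exceeds the control mean.
    The control group is the alphabetically first label.
    """
    if set(vip) != set(pvals):
        diff = sorted(set(vip) ^ set(pvals))
        raise ValueError(f"VIP and p-value metabolite sets differ: {diff}")
    lo, hi = table.group_levels
    g = table.groups.to_numpy()
    means_lo = table.intensities[g == lo].mean(axis=0)
    means_hi = table.intensities[g == hi].mean(axis=0)
    out = []
    for m in table.metabolite_ids:
        if m not in vip:
            continue
        if vip[m] > vip_threshold and pvals[m] < p_threshold:
            c, t = float(means_lo[m]), float(means_hi[m])
            out.append(DifferentialMetabolite(
                metabolite_id=m, vip=float(vip[m]), p_value=float(pvals[m]),
                direction="up" if t > c else "down",
                control_mean=c, treated_mean=t,
            ))
    return out


def metabolite_correlation(table: MetaboliteTable, subset=None):
    """Pearson correlation matrix (with two-sided p-values) over metabolites.

    Returns (r_df, p_df). Constant metabolites yield NaN rows/columns.
    """
    ids = list(subset) if subset is not None else table.metabolite_ids
    if len(ids) < 2:
        raise ValueError("need at least two metabolites")
    missing = [m for m in ids if m not in table.intensities.columns]
    if missing:
        raise KeyError(f"metabolites not in table: {missing}")
    X = table.intensities[ids].to_numpy(dtype=float)
    n = X.shape[0]
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.asarray(r, dtype=float)
    const = sd == 0
    r[const, :] = np.nan
    r[:, const] = np.nan
    np.fill_diagonal(r, np.where(const, np.nan, 1.0))
    # two-sided p via the exact beta form used by scipy.stats.pearsonr
    rr = np.clip(r, -1.0, 1.0)
    ab = n / 2.0 - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 2.0 * stats.beta.sf(np.abs(rr), ab, ab, loc=-1, scale=2)
    p = np.minimum(p, 1.0)
    np.fill_diagonal(p, 0.0)
    p[np.isnan(r)] = np.nan
    return (pd.DataFrame(r, index=ids, columns=ids),
            pd.DataFrame(p, index=ids, columns=ids))
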