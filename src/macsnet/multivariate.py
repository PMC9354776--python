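"""Chemometric latent-variable models for two-group metabolite tables.

Implements the standard metabolomics workflow: PCA score inspection, PLS-DA
with label-permutation validation, OPLS-DA (Trygg–Wold O-PLS for a single
response) separating class-predictive from class-orthogonal variation, VIP
scores, and S-plot statistics.

Conventions
-----------
* Class coding: y = ±1, with the alphabetically first group label coded −1.
* Scaling: ``center`` (mean only), ``uv`` (unit variance, the default — the
  SIMCA convention for this workflow), or ``pareto`` (sqrt of SD).
* Component sign: each loading vector is flipped so its largest-magnitude
  entry is positive, making fits reproducible across backends.
* Q² is estimated by stratified k-fold cross-validation (7 folds by default,
  reduced with a warning when a group is smaller than the fold count); fold
  assignment is deterministic (round-robin over samples sorted within group).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import MetaboliteTable

__all__ = [
    "LatentModel",
    "PermutationReport",
    "fit_pca",
    "fit_plsda",
    "fit_oplsda",
    "compute_vip",
    "s_plot",
    "permutation_validate",
]

logger = logging.getLogger(__name__)

_SCALINGS = ("center", "uv", "pareto")
_NIPALS_TOL = 1e-12
_NIPALS_MAXITER = 2000


@dataclass
class LatentModel:
    """A fitted latent-variable model (PCA, PLS-DA or OPLS-DA)."""

    kind: str
    scores: np.ndarray          # n x A predictive (or PCA) scores
    loadings: np.ndarray        # p x A
    weights: np.ndarray | None  # p x A (None for PCA)
    ortho_scores: np.ndarray | None = None
    ortho_loadings: np.ndarray | None = None
    ortho_weights: np.ndarray | None = None
    y_loadings: np.ndarray | None = None     # per-component c_a
    ssy: np.ndarray | None = None            # y-variance explained per component
    r2x: float = np.nan
    r2y: float = np.nan
    q2: float = np.nan
    explained_variance: np.ndarray | None = None  # PCA, per component
    mean_: np.ndarray = field(default=None, repr=False)
    scale_: np.ndarray = field(default=None, repr=False)
    scaling: str = "uv"
    feature_ids: list = field(default_factory=list, repr=False)
    sample_ids: list = field(default_factory=list, repr=False)
    y: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _scale_matrix(X: np.ndarray, scaling: str, feature_ids=None):
    """Center/scale columns; returns (Xs, mean, scale). UV on a constant
    column is undefined and raises naming the column."""
    if scaling not in _SCALINGS:
        raise ValueError(f"scaling must be one of {_SCALINGS}, got {scaling!r}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if scaling == "center":
        scale = np.ones_like(sd)
    else:
        bad = np.flatnonzero(sd == 0)
        if bad.size and scaling == "uv":
            names = [feature_ids[i] for i in bad] if feature_ids is not None else list(bad)
            raise ValueError(
                f"constant column(s) {names} have undefined unit-variance scale"
            )
        scale = sd if scaling == "uv" else np.sqrt(sd)
        scale = np.where(scale == 0, 1.0, scale)
    return (X - mean) / scale, mean, scale


def _fix_sign(vec: np.ndarray) -> float:
    """Sign multiplier making the largest-|.| entry of ``vec`` positive."""
    idx = int(np.argmax(np.abs(vec)))
    return 1.0 if vec[idx] >= 0 else -1.0


def fit_pca(table: MetaboliteTable, n_components: int, scaling: str = "uv") -> LatentModel:
    """NIPALS principal component analysis of the scaled intensity matrix."""
    X0 = table.matrix()
    n, p = X0.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, p)}], got {n_components}"
        )
    X, mean, scale = _scale_matrix(X0, scaling, table.metabolite_ids)
    total_var = float(np.sum(X**2))
    scores = np.empty((n, n_components))
    loadings = np.empty((p, n_components))
    ev = np.empty(n_components)
    R = X.copy()
    for a in range(n_components):
        if np.sum(R**2) < _NIPALS_TOL * max(total_var, 1.0):
            raise ValueError(f"matrix rank exhausted before component {a + 1}")
        t = R[:, int(np.argmax(R.var(axis=0)))].copy()
        for _ in range(_NIPALS_MAXITER):
            pvec = R.T @ t / (t @ t)
            pvec /= np.linalg.norm(pvec)
            t_new = R @ pvec
            if np.linalg.norm(t_new - t) < _NIPALS_TOL * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        s = _fix_sign(pvec)
        pvec, t = s * pvec, s * t
        scores[:, a], loadings[:, a] = t, pvec
        ev[a] = float(t @ t) / max(total_var, np.finfo(float).tiny)
        R = R - np.outer(t, pvec)
    return LatentModel(
        kind="pca", scores=scores, loadings=loadings, weights=None,
        explained_variance=ev, r2x=float(ev.sum()),
        mean_=mean, scale_=scale, scaling=scaling,
        feature_ids=table.metabolite_ids, sample_ids=table.sample_ids,
    )


def _pls1_nipals(X: np.ndarray, y: np.ndarray, n_components: int):
    """Single-response NIPALS PLS on pre-scaled X, centered y.

    Returns (W, T, P, c, ssy_per_component, extracted)."""
    n, p = X.shape
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    c = np.zeros(n_components)
    ssy = np.zeros(n_components)
    R, yr = X.copy(), y.copy()
    extracted = 0
    for a in range(n_components):
        w = R.T @ yr
        nw = np.linalg.norm(w)
        if nw < 1e-12 or np.sum(R**2) < 1e-12:
            break  # y-orthogonal residual or rank exhausted
        w /= nw
        t = R @ w
        tt = float(t @ t)
        pvec = R.T @ t / tt
        ca = float(yr @ t) / tt
        s = _fix_sign(pvec)
        W[:, a], T[:, a], P[:, a], c[a] = s * w, s * t, s * pvec, s * ca
        ssy[a] = ca * ca * tt
        R = R - np.outer(t, pvec)
        yr = yr - ca * t
        extracted = a + 1
    return W, T, P, c, ssy, extracted


def fit_plsda(table: MetaboliteTable, n_components: int, scaling: str = "uv",
              cv_folds: int = 7) -> LatentModel:
    """PLS discriminant analysis with ±1 class coding (NIPALS)."""
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    X0 = table.matrix()
    X, mean, scale = _scale_matrix(X0, scaling, table.metabolite_ids)
    rank = np.linalg.matrix_rank(X)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    y = table.y()
    yc = y - y.mean()
    W, T, P, c, ssy, k = _pls1_nipals(X, yc, n_components)
    W, T, P, c, ssy = W[:, :max(k, 1)], T[:, :max(k, 1)], P[:, :max(k, 1)], c[:max(k, 1)], ssy[:max(k, 1)]
    tss = float(yc @ yc)
    r2y = float(ssy.sum() / tss) if tss > 0 else 0.0
    r2x = float(np.sum((T @ P.T) ** 2) / np.sum(X**2))
    q2 = _cv_q2(X0, y, table.groups.to_numpy(), scaling, n_components, None, cv_folds)
    lo, hi = table.group_levels
    logger.info("PLS-DA group coding: %s=-1, %s=+1", lo, hi)
    return LatentModel(
        kind="plsda", scores=T, loadings=P, weights=W, y_loadings=c, ssy=ssy,
        r2x=r2x, r2y=r2y, q2=q2, mean_=mean, scale_=scale, scaling=scaling,
        feature_ids=table.metabolite_ids, sample_ids=table.sample_ids, y=y,
    )


def _opls_core(X: np.ndarray, y: np.ndarray, n_orthogonal: int):
    """Trygg–Wold O-PLS for one response on pre-scaled X, centered y.

    Returns (w, t, p, c, To, Po, Wo, X_filtered)."""
    n, pdim = X.shape
    w = X.T @ y
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise ValueError("response is orthogonal to every column; no predictive direction")
    w /= nw
    To = np.zeros((n, n_orthogonal))
    Po = np.zeros((pdim, n_orthogonal))
    Wo = np.zeros((pdim, n_orthogonal))
    Xf = X.copy()
    for a in range(n_orthogonal):
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        w_o = p - float(w @ p) * w
        norm_o = np.linalg.norm(w_o)
        if norm_o < 1e-10:
            raise ValueError(
                f"no y-orthogonal variation left for orthogonal component {a + 1}"
            )
        w_o /= norm_o
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        s = _fix_sign(p_o)
        To[:, a], Po[:, a], Wo[:, a] = s * t_o, s * p_o, s * w_o
        Xf = Xf - np.outer(t_o, p_o)
    t = Xf @ w
    tt = float(t @ t)
    p = Xf.T @ t / tt
    cpred = float(y @ t) / tt
    s = _fix_sign(p)
    return s * w, s * t, s * p, s * cpred, To, Po, Wo, Xf


def fit_oplsda(table: MetaboliteTable, n_orthogonal: int = 1, scaling: str = "uv",
               cv_folds: int = 7) -> LatentModel:
    """OPLS-DA: one predictive component plus ``n_orthogonal`` orthogonal ones.

    Orthogonal score vectors have exactly zero covariance with the class
    vector by construction (their weights are orthogonal to X'y).
    """
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")
    X0 = table.matrix()
    X, mean, scale = _scale_matrix(X0, scaling, table.metabolite_ids)
    rank = np.linalg.matrix_rank(X)
    if n_orthogonal + 1 > rank:
        raise ValueError(f"1 predictive + {n_orthogonal} orthogonal exceeds rank {rank}")
    y = table.y()
    yc = y - y.mean()
    w, t, p, cpred, To, Po, Wo, Xf = _opls_core(X, yc, n_orthogonal)
    tss = float(yc @ yc)
    ssy = np.array([cpred * cpred * float(t @ t)])
    r2y = float(ssy[0] / tss) if tss > 0 else 0.0
    modelled = np.sum((np.outer(t, p)) ** 2) + (np.sum((To @ Po.T) ** 2) if n_orthogonal else 0.0)
    r2x = float(modelled / np.sum(X**2))
    q2 = _cv_q2(X0, y, table.groups.to_numpy(), scaling, 1, n_orthogonal, cv_folds)
    return LatentModel(
        kind="oplsda", scores=t[:, None], loadings=p[:, None], weights=w[:, None],
        ortho_scores=To if n_orthogonal else None,
        ortho_loadings=Po if n_orthogonal else None,
        ortho_weights=Wo if n_orthogonal else None,
        y_loadings=np.array([cpred]), ssy=ssy, r2x=r2x, r2y=r2y, q2=q2,
        mean_=mean, scale_=scale, scaling=scaling,
        feature_ids=table.metabolite_ids, sample_ids=table.sample_ids, y=y,
    )


def compute_vip(model: LatentModel) -> dict:
    """Variable importance in projection; sum of VIP² equals the number of
    features by construction. Defined for PLS-DA/OPLS-DA (predictive part)."""
    if model.kind == "pca":
        raise ValueError("VIP is undefined for PCA models")
    W, ssy = model.weights, model.ssy
    p = W.shape[0]
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    denom = float(ssy.sum())
    if denom <= 0:
        vip = np.zeros(p)
    else:
        vip = np.sqrt(p * (wn**2 @ ssy) / denom)
    return dict(zip(model.feature_ids, vip.tolist()))


def s_plot(model: LatentModel, table: MetaboliteTable) -> dict:
    """Per-metabolite (covariance, correlation) against the predictive scores.

    Zero-variance metabolites get a missing (NaN) correlation, not an error.
    """
    if model.kind == "pca" or model.scores.shape[1] < 1:
        raise ValueError("S-plot requires a model with a predictive component")
    X = (table.matrix() - model.mean_) / model.scale_
    t = model.scores[:, 0]
    n = len(t)
    tc = t - t.mean()
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ tc / (n - 1)
    sx = Xc.std(axis=0, ddof=1)
    st = tc.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(sx > 0, cov / (sx * st), np.nan)
    return {m: (float(cv), float(cr)) for m, cv, cr in zip(model.feature_ids, cov, corr)}


def _fold_assignment(groups: np.ndarray, folds: int) -> np.ndarray:
    """Deterministic stratified folds: round-robin within each group in
    stable order. Reduces folds (warning) if a group is smaller."""
    counts = {g: int(np.sum(groups == g)) for g in np.unique(groups)}
    k = min(folds, min(counts.values()))
    if k < folds:
        logger.warning(
            "reducing CV folds from %d to %d: smallest group has %d samples",
            folds, k, min(counts.values()),
        )
    assign = np.empty(len(groups), dtype=int)
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        assign[idx] = np.arange(len(idx)) % k
    return assign


def _cv_q2(X0: np.ndarray, y: np.ndarray, groups: np.ndarray, scaling: str,
           n_components: int, n_orthogonal: int | None, folds: int) -> float:
    """Q² = 1 − PRESS/SSY under stratified k-fold CV."""
    assign = _fold_assignment(groups, folds)
    press = 0.0
    yc_all = y - y.mean()
    for f in np.unique(assign):
        tr, te = assign != f, assign == f
        Xtr = X0[tr]
        sd = Xtr.std(axis=0, ddof=1)
        # constant-in-fold columns get unit scale rather than failing the fold
        mean = Xtr.mean(axis=0)
        if scaling == "center":
            scale = np.ones_like(sd)
        elif scaling == "uv":
            scale = np.where(sd == 0, 1.0, sd)
        else:
            scale = np.where(sd == 0, 1.0, np.sqrt(sd))
        Xs = (Xtr - mean) / scale
        ytr = y[tr]
        ytr_c = ytr - ytr.mean()
        Xte = (X0[te] - mean) / scale
        if n_orthogonal is None:
            W, T, P, c, ssy, k = _pls1_nipals(Xs, ytr_c, n_components)
            W, P, c = W[:, :max(k, 1)], P[:, :max(k, 1)], c[:max(k, 1)]
            # regression coefficients b = W (P'W)^-1 c
            try:
                b = W @ np.linalg.solve(P.T @ W, c)
            except np.linalg.LinAlgError:
                b = np.zeros(Xs.shape[1])
            yhat = Xte @ b + ytr.mean()
        else:
            w, t, p, cpred, To, Po, Wo, Xf = _opls_core(Xs, ytr_c, n_orthogonal)
            Xte_f = Xte.copy()
            for a in range(To.shape[1]):
                t_o = Xte_f @ Wo[:, a]
                Xte_f = Xte_f - np.outer(t_o, Po[:, a])
            yhat = (Xte_f @ w) * cpred + ytr.mean()
        press += float(np.sum((y[te] - yhat) ** 2))
    ssy_tot = float(yc_all @ yc_all)
    return 1.0 - press / ssy_tot if ssy_tot > 0 else np.nan


@dataclass
class PermutationReport:
    r2y: float
    q2: float
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    n_permutations: int
    valid: bool


def permutation_validate(table: MetaboliteTable, n_components: int = 1,
                         n_permutations: int = 100, cv_folds: int = 7,
                         seed: int = 0, scaling: str = "uv") -> PermutationReport:
    """Label-permutation validation of a PLS-DA model.

    The model is declared valid iff every permuted R²Y *and* Q² falls strictly
    below the original values. Permutations equal to the original label vector
    are redrawn, so the null distribution never contains the unpermuted model.
    """
    if n_permutations < 20:
        raise ValueError("need at least 20 permutations")
    rng = np.random.default_rng(seed)
    model = fit_plsda(table, n_components, scaling=scaling, cv_folds=cv_folds)
    labels = table.groups.to_numpy()
    X0 = table.matrix()
    perm_r2 = np.empty(n_permutations)
    perm_q2 = np.empty(n_permutations)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_permutations):
            while True:
                perm = rng.permutation(len(labels))
                if not np.array_equal(labels[perm], labels):
                    break
            ptab = MetaboliteTable(
                intensities=table.intensities,
                groups=table.groups.iloc[perm].set_axis(table.intensities.index),
            )
            pm = fit_plsda(ptab, n_components, scaling=scaling, cv_folds=cv_folds)
            perm_r2[i], perm_q2[i] = pm.r2y, pm.q2
    valid = bool(np.all(perm_r2 < model.r2y) and np.all(perm_q2 < model.q2))
    return PermutationReport(
        r2y=model.r2y, q2=model.q2, permuted_r2y=perm_r2, permuted_q2=perm_q2,
        n_permutations=n_permutations, valid=valid,
    )
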