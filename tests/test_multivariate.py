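"""Chemometric models: PCA/PLS/OPLS contracts, VIP, S-plot, permutation test."""

import numpy as np
import pytest

from macsnet.multivariate import (LatentModel, compute_vip, fit_oplsda, fit_pca,
                                  fit_plsda, permutation_validate, s_plot)
from macsnet.synthetic import generate_metabolite_table

from conftest import make_table


# ---------------------------------------------------------------- PCA

def test_pca_rank_one_recovers_direction(rng):
    direction = rng.standard_normal(20)
    direction /= np.linalg.norm(direction)
    coeff = np.array([-3.0, -2, -1, 1, 2, 3.0])
    X = 100 + np.outer(coeff, direction)
    table = make_table(X, 3)
    model = fit_pca(table, 1, scaling="center")
    got = model.loadings[:, 0]
    sign = np.sign(got @ direction)
    assert np.allclose(sign * got, direction, atol=1e-8)
    assert model.explained_variance[0] == pytest.approx(1.0, abs=1e-10)


def test_pca_explained_variance_bounded_and_ordered(small_table):
    model = fit_pca(small_table, 5)
    ev = model.explained_variance
    assert ev.sum() <= 1.0 + 1e-12
    assert np.all(np.diff(ev) <= 1e-10)


def test_pca_nipals_matches_svd(rng):
    X = rng.standard_normal((12, 18))
    table = make_table(X - X.min() + 1.0, 6)
    model = fit_pca(table, 4, scaling="uv")
    Xs = (table.matrix() - model.mean_) / model.scale_
    _, _, vt = np.linalg.svd(Xs, full_matrices=False)
    for a in range(4):
        ref = vt[a]
        ref = ref * np.sign(ref[np.argmax(np.abs(ref))])
        assert np.allclose(model.loadings[:, a], ref, atol=1e-6)


def test_pca_scores_orthogonal(small_table):
    model = fit_pca(small_table, 4)
    G = model.scores.T @ model.scores
    off = G - np.diag(np.diag(G))
    norm = np.sqrt(np.outer(np.diag(G), np.diag(G)))
    assert np.max(np.abs(off / norm)) < 1e-8


def test_pca_separates_planted_clusters(planted_table):
    table, _ = planted_table
    model = fit_pca(table, 2)
    y = table.y()
    s = model.scores[:, 0]
    # component-1 scores split the groups with no overlap
    assert max(s[y < 0]) < min(s[y > 0]) or max(s[y > 0]) < min(s[y < 0])


def test_pca_constant_column_uv_names_column(rng):
    X = np.exp(rng.normal(0, 1, (8, 5)))
    X[:, 2] = 7.0
    table = make_table(X, 4)
    with pytest.raises(ValueError, match="M002"):
        fit_pca(table, 2, scaling="uv")
    fit_pca(table, 2, scaling="center")  # centering-only is fine


def test_pca_component_limit(small_table):
    with pytest.raises(ValueError, match="n_components"):
        fit_pca(small_table, 12)


# ---------------------------------------------------------------- PLS-DA

def test_pls_one_component_weight_is_xty(rng):
    X = np.exp(rng.normal(3, 0.4, (10, 15)))
    table = make_table(X, 5)
    model = fit_plsda(table, 1, scaling="center")
    Xc = table.matrix() - table.matrix().mean(axis=0)
    y = table.y()
    w_ref = Xc.T @ (y - y.mean())
    w_ref /= np.linalg.norm(w_ref)
    w = model.weights[:, 0]
    w_ref *= np.sign(w_ref[np.argmax(np.abs(w_ref))])
    assert np.allclose(w, w_ref, atol=1e-8)


def test_pls_perfect_separator_dominates_weights(rng):
    n = 12
    X = np.exp(rng.normal(0, 1, (n, 20)))
    y = np.array([-1.0] * 6 + [1.0] * 6)
    X[:, 7] = 10 + y  # perfectly separating metabolite
    model = fit_plsda(make_table(X, 6), 1)
    assert np.argmax(np.abs(model.weights[:, 0])) == 7


def test_pls_r2y_invariant_under_column_duplication(small_table):
    base = fit_plsda(small_table, 1)
    dup = small_table.intensities.copy()
    for c in list(dup.columns):
        dup[c + "_copy"] = dup[c]
    table2 = make_table(dup.to_numpy(), 6)
    assert fit_plsda(table2, 1).r2y == pytest.approx(base.r2y, abs=1e-10)


def test_pls_orthogonal_response_gives_zero_r2y(rng):
    y = np.array([-1.0] * 5 + [1.0] * 5)
    yc = y - y.mean()
    X = rng.standard_normal((10, 8))
    X -= np.outer(yc, yc @ X) / (yc @ yc)  # project y out of every column
    model = fit_plsda(make_table(X + 10, 5), 1, scaling="center")
    assert model.r2y == pytest.approx(0.0, abs=1e-12)


def test_pls_rank_limit(rng):
    X = np.exp(rng.normal(0, 1, (8, 30)))
    with pytest.raises(ValueError, match="rank"):
        fit_plsda(make_table(X, 4), 10)


# ---------------------------------------------------------------- OPLS-DA

def test_opls_zero_orthogonal_equals_pls_one_component(small_table):
    pls = fit_plsda(small_table, 1)
    opls = fit_oplsda(small_table, 0)
    assert np.allclose(opls.scores[:, 0], pls.scores[:, 0], atol=1e-10)
    assert np.allclose(opls.loadings[:, 0], pls.loadings[:, 0], atol=1e-10)


def test_opls_orthogonal_scores_uncorrelated_with_y(planted_table):
    table, _ = planted_table
    model = fit_oplsda(table, 2)
    y = table.y()
    for a in range(model.ortho_scores.shape[1]):
        r = np.corrcoef(model.ortho_scores[:, a], y)[0, 1]
        assert abs(r) < 1e-8


def test_opls_removes_constructed_y_orthogonal_variation(rng):
    """Adding structured variation orthogonal to y (in a null-space direction)
    must leave predictive weights and loadings bit-for-bit comparable."""
    X = np.exp(rng.normal(2, 0.5, (12, 40)))
    table = make_table(X, 6)
    clean = fit_oplsda(table, 1, scaling="center")
    Xc = table.matrix() - table.matrix().mean(axis=0)
    y = table.y()
    yc = y - y.mean()
    t_init = Xc @ clean.weights[:, 0]
    t_o = clean.ortho_scores[:, 0]
    # t_add orthogonal to {1, y, t_init, t_o}
    t_add = rng.standard_normal(12)
    basis = np.column_stack([np.ones(12), yc, t_init, t_o])
    q, _ = np.linalg.qr(basis)
    t_add -= q @ (q.T @ t_add)
    # v in the right null space of the centered matrix
    _, s, vt = np.linalg.svd(Xc, full_matrices=True)
    v = vt[-1]
    assert np.max(np.abs(Xc @ v)) < 1e-8
    aug = make_table(X + 5.0 * np.outer(t_add, v), 6)
    model = fit_oplsda(aug, 1, scaling="center")
    assert np.allclose(model.weights[:, 0], clean.weights[:, 0], atol=1e-6)
    assert np.allclose(model.loadings[:, 0], clean.loadings[:, 0], atol=1e-6)


def test_opls_too_many_orthogonal_components(rng):
    X = np.exp(rng.normal(0, 1, (8, 30)))
    with pytest.raises(ValueError):
        fit_oplsda(make_table(X, 4), 10)


# ---------------------------------------------------------------- VIP / S-plot

def test_vip_closed_form_for_unit_weight():
    model = LatentModel(kind="plsda", scores=np.zeros((4, 1)),
                        loadings=np.zeros((2, 1)),
                        weights=np.array([[1.0], [0.0]]),
                        ssy=np.array([0.7]), feature_ids=["a", "b"])
    vip = compute_vip(model)
    assert vip["a"] == pytest.approx(np.sqrt(2), abs=1e-12)
    assert vip["b"] == pytest.approx(0.0, abs=1e-12)


def test_vip_single_metabolite_is_one(rng):
    X = np.exp(rng.normal(0, 1, (10, 1)) + np.r_[np.zeros(5), np.ones(5)][:, None])
    model = fit_plsda(make_table(X, 5), 1)
    assert compute_vip(model)["M000"] == pytest.approx(1.0, abs=1e-10)


def test_vip_mean_square_is_one(planted_table):
    table, _ = planted_table
    for model in (fit_plsda(table, 2), fit_oplsda(table, 1)):
        vip = np.array(list(compute_vip(model).values()))
        assert np.mean(vip**2) == pytest.approx(1.0, rel=1e-9)


def test_vip_undefined_for_pca(small_table):
    with pytest.raises(ValueError, match="PCA"):
        compute_vip(fit_pca(small_table, 2))


def test_s_plot_correlations(planted_table):
    table, truth = planted_table
    model = fit_oplsda(table, 1)
    pairs = s_plot(model, table)
    corrs = {m: c for m, (_, c) in pairs.items()}
    assert all(-1 - 1e-9 <= c <= 1 + 1e-9 for c in corrs.values() if np.isfinite(c))
    # planted metabolites occupy the extreme |corr| ranks
    ranked = sorted(corrs, key=lambda m: -abs(corrs[m]))
    assert set(truth.differential_metabolites) <= set(ranked[:12])


def test_s_plot_metabolite_equal_to_scores(rng):
    # single-column model: predictive scores are the (centered) column itself
    X = (10 + np.r_[np.zeros(5), np.ones(5)] + 0.1 * rng.standard_normal(10))[:, None]
    table = make_table(X, 5)
    model = fit_oplsda(table, 0, scaling="center")
    pairs = s_plot(model, table)
    assert pairs["M000"][1] == pytest.approx(1.0, abs=1e-8)


def test_s_plot_constant_metabolite_reported_missing(rng):
    X = np.exp(rng.normal(0, 0.5, (10, 6)))
    X[:, 3] = 2.5
    table = make_table(X, 5)
    model = fit_oplsda(table, 0, scaling="center")
    assert np.isnan(s_plot(model, table)["M003"][1])


# ---------------------------------------------------------------- permutation

def test_permutation_flags_strong_effect_valid():
    table, _ = generate_metabolite_table(6, 50, 10, 3.0, seed=42)
    report = permutation_validate(table, 1, n_permutations=100, seed=0)
    assert report.valid
    assert report.q2 > max(report.permuted_q2)


def test_permutation_requires_enough_permutations(small_table):
    with pytest.raises(ValueError, match="20"):
        permutation_validate(small_table, 1, n_permutations=5, seed=0)
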