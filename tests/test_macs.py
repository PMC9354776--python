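"""MACS model: pathway activity, MI relevance, greedy mRMR, retention rule."""

import numpy as np
import pandas as pd
import pytest

from macsnet.datatypes import ExpressionDataset
from macsnet.macs import (MACSResult, PathwayActivity, greedy_mrmr_rank,
                          macs_scores, pathway_activity, relevance)
from macsnet.mi import MIEstimatorConfig, estimate_mi
from macsnet.synthetic import generate_expression_dataset

CFG = MIEstimatorConfig()


def make_dataset(data: dict, n_tumor: int, n_normal: int = 0) -> ExpressionDataset:
    n = n_tumor + n_normal
    idx = [f"s{i}" for i in range(n)]
    cond = ["tumor"] * n_tumor + ["normal"] * n_normal
    return ExpressionDataset("test", pd.DataFrame(data, index=idx),
                             pd.Series(cond, index=idx))


def standardized(v):
    return (v - v.mean()) / v.std(ddof=1)


# ------------------------------------------------------------ pathway activity

def test_single_gene_activity_is_zscore(rng):
    g = rng.standard_normal(50)
    ds = make_dataset({"g1": g}, 50)
    act = pathway_activity(ds, "pw", ["g1"], subset="tumor")
    assert np.allclose(act.values, standardized(g), atol=1e-12)
    assert act.values.mean() == pytest.approx(0.0, abs=1e-12)
    assert act.values.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_cancelling_genes_raise_degenerate_activity(rng):
    g = rng.standard_normal(50)
    ds = make_dataset({"g1": g, "g2": 10 - g}, 50)
    with pytest.raises(ValueError, match="degenerate"):
        pathway_activity(ds, "pw", ["g1", "g2"])


def test_activity_requires_present_genes(rng):
    ds = make_dataset({"g1": rng.standard_normal(30)}, 30)
    with pytest.raises(ValueError, match="none of its genes"):
        pathway_activity(ds, "pw", ["absent"])


def test_activity_tracks_latent_factor():
    blocks = {"P0": [f"G{j}" for j in range(8)]}
    ds, _ = generate_expression_dataset(200, 4, blocks, ["t1"], 0, 0.0, seed=8)
    act = pathway_activity(ds, "P0", blocks["P0"], subset="tumor")
    # the factor is unobserved; the block mean is its best proxy, and the
    # activity must agree with the analytic loading-geometry prediction
    lam, m = 0.7, 8
    expected = lam * np.sqrt(m) / np.sqrt(m * lam**2 + 1 - lam**2)
    gene_corrs = [np.corrcoef(act.values, ds.subset("tumor")[g])[0, 1]
                  for g in blocks["P0"]]
    assert np.mean(gene_corrs) == pytest.approx(lam * expected, abs=0.1)


# ------------------------------------------------------------ relevance

def test_relevance_requires_core_pathways(rng):
    with pytest.raises(ValueError, match="no core pathways"):
        relevance(rng.standard_normal(30), [], CFG)


def test_relevance_averages_over_pathways(rng):
    x = rng.standard_normal(100)
    a1 = PathwayActivity("p1", standardized(0.9 * x + 0.44 * rng.standard_normal(100)), ())
    a2 = PathwayActivity("p2", standardized(rng.standard_normal(100)), ())
    expected = 0.5 * (estimate_mi(x, a1.values, CFG) + estimate_mi(x, a2.values, CFG))
    assert relevance(x, [a1, a2], CFG) == pytest.approx(expected, abs=1e-12)


def test_self_relevance_dominates(rng):
    act = PathwayActivity("p", standardized(rng.standard_normal(100)), ())
    others = {f"g{i}": rng.standard_normal(100) for i in range(5)}
    self_rel = relevance(act.values, [act], CFG)
    assert all(self_rel > relevance(v, [act], CFG) for v in others.values())


# ------------------------------------------------------------ greedy ranking

def test_duplicate_candidate_deferred_by_redundancy(rng):
    f = rng.standard_normal(150)
    act = PathwayActivity("p", standardized(f), ())
    g1 = 0.9 * f + 0.44 * rng.standard_normal(150)
    g3 = 0.4 * f + np.sqrt(1 - 0.16) * rng.standard_normal(150)
    candidates = {"g1": g1, "g2": g1.copy(), "g3": g3}
    order = [r.target for r in greedy_mrmr_rank(candidates, [act], CFG)]
    assert order == ["g1", "g3", "g2"]


def test_independent_candidates_ranked_by_relevance(rng):
    f = rng.standard_normal(300)
    act = PathwayActivity("p", standardized(f), ())
    couplings = {"a": 0.9, "b": 0.6, "c": 0.3, "d": 0.0}
    candidates = {
        g: c * f + np.sqrt(1 - c**2) * rng.standard_normal(300)
        for g, c in couplings.items()
    }
    results = greedy_mrmr_rank(candidates, [act], CFG)
    assert [r.target for r in results] == ["a", "b", "c", "d"]
    assert all(np.isclose(r.score, r.relevance - r.redundancy) for r in results)
    assert [r.rank for r in results] == [1, 2, 3, 4]


def test_greedy_matches_exhaustive_step_oracle():
    from macsnet.experiments import greedy_oracle_agreement
    out = greedy_oracle_agreement(n_instances=10, seed=123)
    assert out["agreement_rate"] == 1.0


def test_greedy_needs_two_candidates(rng):
    act = PathwayActivity("p", rng.standard_normal(30), ())
    with pytest.raises(ValueError, match="2 candidate"):
        greedy_mrmr_rank({"only": rng.standard_normal(30)}, [act], CFG)


def test_greedy_rejects_length_mismatch(rng):
    act = PathwayActivity("p", rng.standard_normal(30), ())
    with pytest.raises(ValueError, match="length"):
        greedy_mrmr_rank({"a": np.zeros(30), "b": np.zeros(29)}, [act], CFG)


# ------------------------------------------------------------ score aggregation

def _result(target, score):
    return MACSResult(target=target, rank=0, relevance=score, redundancy=0.0,
                      score=score)


def test_retention_strictly_above_mean():
    ranking = [[_result("a", 3.0), _result("b", 1.0), _result("c", 2.0)]]
    final = macs_scores(ranking)
    retained = {r.target for r in final if r.retained}
    assert retained == {"a"}  # mean is 2.0; only 3.0 is strictly above
    assert [r.target for r in final] == ["a", "c", "b"]


def test_equal_scores_retain_nothing():
    ranking = [[_result("a", 1.0), _result("b", 1.0)]]
    assert not any(r.retained for r in macs_scores(ranking))


def test_single_dataset_aggregation_is_identity():
    ranking = [[_result("a", 0.5), _result("b", 0.2)]]
    final = macs_scores(ranking)
    assert {r.target: r.score for r in final} == {"a": 0.5, "b": 0.2}


def test_aggregation_mean_vs_median():
    rankings = [
        [_result("a", 0.2), _result("b", 0.0)],
        [_result("a", 0.4), _result("b", 0.0)],
        [_result("a", 0.9), _result("b", 0.0)],
    ]
    by_mean = {r.target: r.score for r in macs_scores(rankings, "mean")}
    by_median = {r.target: r.score for r in macs_scores(rankings, "median")}
    assert by_mean["a"] == pytest.approx(0.5)
    assert by_median["a"] == pytest.approx(0.4)


def test_disjoint_candidate_sets_error():
    with pytest.raises(ValueError, match="intersection"):
        macs_scores([[_result("a", 1.0)], [_result("b", 1.0)]])


# ------------------------------------------------------------ planted recovery

def test_planted_targets_recovered_and_ranked_high():
    from macsnet.experiments import planted_target_recovery
    out = planted_target_recovery(n_replicates=10, seed=77)
    assert out["all_retained_rate"] == 1.0
    assert out["first3_informative_rate"] == 1.0
    assert out["all_in_top10_rate"] == 1.0
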