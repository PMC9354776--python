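"""Over-representation p-values, multiplicity adjustments, pathway impact."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from macsnet.enrichment import (EnrichmentResult, PathwayDefinition, adjust_bh,
                                adjust_holm, enrich_pathways,
                                flag_core_pathways, ora_hypergeometric,
                                pathway_impact)


def chain(members):
    return [(members[i], members[i + 1]) for i in range(len(members) - 1)]


def hypergeom_tail_oracle(overlap, N, K, n):
    """Exact upper-tail P(X >= overlap) by pmf enumeration with integer comb."""
    total = math.comb(N, n)
    acc = 0
    for k in range(overlap, min(K, n) + 1):
        acc += math.comb(K, k) * math.comb(N - K, n - k)
    return acc / total


def test_ora_worked_example_full_overlap():
    members = [f"m{i}" for i in range(5)]
    pw = PathwayDefinition("p1", "p1", members, chain(members))
    universe = [f"m{i}" for i in range(10)]
    p = ora_hypergeometric(set(members), pw, universe)
    assert p == pytest.approx(1 / 252, rel=1e-12)


def test_ora_zero_overlap_is_one():
    pw = PathwayDefinition("p1", "p1", ["a", "b"], [("a", "b")])
    universe = ["a", "b", "c", "d", "e"]
    assert ora_hypergeometric({"c", "d"}, pw, universe) == 1.0


def test_ora_partial_overlap_matches_enumeration():
    members = [f"m{i}" for i in range(5)]
    pw = PathwayDefinition("p1", "p1", members, chain(members))
    universe = [f"m{i}" for i in range(20)]
    hits = {"m0", "m1", "m10", "m11", "m12"}  # overlap 2
    expected = hypergeom_tail_oracle(2, 20, 5, 5)
    assert expected == pytest.approx(0.36609907120743035, rel=1e-12)
    assert ora_hypergeometric(hits, pw, universe) == pytest.approx(expected, abs=1e-12)


def test_ora_agrees_with_enumeration_over_small_grid():
    rng = np.random.default_rng(0)
    for _ in range(200):
        N = int(rng.integers(3, 31))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        universe = [f"u{i}" for i in range(N)]
        members = universe[:K] if K >= 2 else universe[:2]
        K_eff = len(members)
        pw = PathwayDefinition("p", "p", members, chain(members))
        hits = set(rng.choice(universe, size=n, replace=False).tolist())
        overlap = len(hits & set(members))
        got = ora_hypergeometric(hits, pw, universe)
        assert abs(got - hypergeom_tail_oracle(overlap, N, K_eff, n)) < 1e-12


def test_ora_validation_errors():
    pw = PathwayDefinition("p", "p", ["a", "b"], [])
    with pytest.raises(ValueError, match="universe"):
        ora_hypergeometric(set(), pw, set())
    with pytest.raises(ValueError, match="outside"):
        ora_hypergeometric({"z"}, pw, {"a", "b"})


def test_holm_hand_worked_example():
    assert adjust_holm([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])


def test_holm_trivial_cases():
    assert adjust_holm([0.2]) == [pytest.approx(0.2)]
    assert adjust_holm([0.3, 0.3, 0.3]) == pytest.approx([0.9, 0.9, 0.9])
    assert adjust_holm([0.6, 0.6]) == pytest.approx([1.0, 1.0])  # capped


def test_bh_hand_worked_example():
    assert adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert adjust_bh([0.5]) == [pytest.approx(0.5)]


def test_bh_monotone_on_sorted_input():
    q = adjust_bh([0.001, 0.01, 0.02, 0.2, 0.9])
    assert all(q[i] <= q[i + 1] + 1e-15 for i in range(len(q) - 1))


@given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=12),
       st.randoms(use_true_random=False))
def test_adjustments_permutation_equivariant(pvals, rnd):
    perm = list(range(len(pvals)))
    rnd.shuffle(perm)
    shuffled = [pvals[i] for i in perm]
    for adjust in (adjust_holm, adjust_bh):
        base = adjust(pvals)
        assert adjust(shuffled) == pytest.approx([base[i] for i in perm], abs=1e-12)


def test_adjustments_reject_bad_pvalues():
    for adjust in (adjust_holm, adjust_bh):
        with pytest.raises(ValueError):
            adjust([0.5, 1.2])


def test_impact_star_hub_is_one():
    members = ["hub", "a", "b", "c", "d"]
    pw = PathwayDefinition("p", "p", members, [("hub", m) for m in members[1:]])
    assert pathway_impact(pw, {"hub"}) == pytest.approx(1.0)
    assert pathway_impact(pw, {"a"}) == pytest.approx(0.0)


def test_impact_path_endpoints_are_zero():
    pw = PathwayDefinition("p", "p", ["a", "b", "c"], [("a", "b"), ("b", "c")])
    assert pathway_impact(pw, {"a", "c"}) == 0.0
    assert pathway_impact(pw, {"b"}) == pytest.approx(1.0)
    assert pathway_impact(pw, set()) == 0.0


def test_impact_full_hit_set_is_one_when_any_centrality():
    rng = np.random.default_rng(4)
    members = [f"m{i}" for i in range(7)]
    edges = chain(members) + [("m0", "m4")]
    pw = PathwayDefinition("p", "p", members, edges)
    assert pathway_impact(pw, set(members)) == pytest.approx(1.0)


def test_impact_in_unit_interval_and_hits_outside_ignored():
    pw = PathwayDefinition("p", "p", ["a", "b", "c"], [("a", "b"), ("b", "c")])
    v = pathway_impact(pw, {"b", "zzz"})
    assert 0.0 <= v <= 1.0


def test_core_flag_strict_boundary():
    results = [
        EnrichmentResult("p1", "p1", 5, 3, raw_p=0.049),
        EnrichmentResult("p2", "p2", 5, 3, raw_p=0.05),
        EnrichmentResult("p3", "p3", 5, 0, raw_p=0.9),
    ]
    flagged = flag_core_pathways(results)
    assert [r.is_core for r in flagged] == [True, False, False]


def test_enrich_pathways_invariants():
    rng = np.random.default_rng(11)
    universe = [f"m{i}" for i in range(40)]
    pathways = []
    for k in range(6):
        members = rng.choice(universe, size=6, replace=False).tolist()
        pathways.append(PathwayDefinition(f"pw{k}", f"pw{k}", members, chain(members)))
    hits = set(rng.choice(universe, size=8, replace=False).tolist())
    res = enrich_pathways(hits, pathways, universe)
    for r in res:
        assert r.raw_p <= r.holm_p + 1e-15
        assert r.raw_p <= r.fdr_q + 1e-15
        assert 0.0 <= r.impact <= 1.0
        assert r.is_core == (r.raw_p < 0.05)
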