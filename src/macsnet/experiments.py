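"""Calibration and recovery experiments over the synthetic study design.

Each function runs one simulation study end to end through the package and
returns plain numbers, so the same computations back the test suite, the
numbered analysis scripts and the acceptance report. Seeds derive from a
single experiment seed; all sizes are the study conditions documented in
docs/methods.md.
"""

from __future__ import annotations

import hashlib
import math
from pathlib import Path

import numpy as np

from .differential import select_differential, univariate_test
from .macs import (PathwayActivity, greedy_mrmr_rank, macs_scores,
                   pathway_activity, relevance)
from .mi import MIEstimatorConfig, estimate_mi
from .multivariate import compute_vip, fit_oplsda, fit_plsda, permutation_validate
from .synthetic import generate_expression_dataset, generate_metabolite_table

__all__ = [
    "mi_gaussian_recovery",
    "mi_independence_calibration",
    "greedy_oracle_agreement",
    "planted_target_recovery",
    "vip_normalization_fuzz",
    "null_selection_calibration",
    "null_permutation_flag_rate",
]


def _sub_seed(seed: int, tag: str) -> int:
    digest = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def mi_gaussian_recovery(rho: float, n: int = 2000, n_seeds: int = 20,
                         seed: int = 0, k: int = 3) -> dict:
    """Mean KSG estimate for bivariate Gaussians vs the closed form
    −½ln(1−ρ²)."""
    cfg = MIEstimatorConfig(method="knn", k=k)
    vals = []
    for i in range(n_seeds):
        rng = np.random.default_rng(_sub_seed(seed, f"gauss:{rho}:{i}"))
        x = rng.standard_normal(n)
        y = rho * x + math.sqrt(1 - rho**2) * rng.standard_normal(n)
        vals.append(estimate_mi(x, y, cfg))
    truth = -0.5 * math.log(1 - rho**2)
    return {"mean_estimate": float(np.mean(vals)), "closed_form": truth,
            "abs_error": float(abs(np.mean(vals) - truth)), "n": n}


def mi_independence_calibration(n: int = 2000, n_seeds: int = 100,
                                seed: int = 0, bound: float = 0.05) -> dict:
    """Fraction of independent-normal pairs whose estimate stays <= bound."""
    cfg = MIEstimatorConfig()
    vals = []
    for i in range(n_seeds):
        rng = np.random.default_rng(_sub_seed(seed, f"indep:{i}"))
        vals.append(estimate_mi(rng.standard_normal(n), rng.standard_normal(n), cfg))
    vals = np.asarray(vals)
    return {"fraction_within_bound": float(np.mean(vals <= bound)),
            "max_estimate": float(vals.max()), "n": n}


def _oracle_greedy(vectors: dict, activities, cfg) -> list:
    """Exhaustive per-step argmax of the incremental mRMR criterion."""
    ids = sorted(vectors)
    D = {g: relevance(vectors[g], activities, cfg) for g in ids}
    mi_cache = {}

    def pair_mi(a, b):
        key = (a, b) if a < b else (b, a)
        if key not in mi_cache:
            mi_cache[key] = estimate_mi(vectors[key[0]], vectors[key[1]], cfg)
        return mi_cache[key]

    selected = []
    remaining = list(ids)
    while remaining:
        best, best_val = None, -np.inf
        for g in remaining:
            red = (sum(pair_mi(g, s) for s in selected) / len(selected)
                   if selected else 0.0)
            val = D[g] - red
            if val > best_val or (val == best_val and g < best):
                best, best_val = g, val
        selected.append(best)
        remaining.remove(best)
    return selected


def greedy_oracle_agreement(n_instances: int = 50, seed: int = 0,
                            max_candidates: int = 8, n_samples: int = 120) -> dict:
    """Fraction of random small instances where every greedy pick equals the
    exhaustive argmax oracle."""
    cfg = MIEstimatorConfig()
    agree = 0
    for i in range(n_instances):
        rng = np.random.default_rng(_sub_seed(seed, f"oracle:{i}"))
        n_cand = int(rng.integers(3, max_candidates + 1))
        n_act = int(rng.integers(1, 4))
        factors = rng.standard_normal((n_act, n_samples))
        acts = [
            PathwayActivity(pathway_id=f"a{a}",
                            values=(factors[a] - factors[a].mean()) / factors[a].std(ddof=1),
                            genes=())
            for a in range(n_act)
        ]
        vectors = {}
        for c in range(n_cand):
            w = rng.uniform(0, 0.9)
            f = factors[int(rng.integers(0, n_act))]
            vectors[f"g{c:02d}"] = w * f + math.sqrt(1 - w**2) * rng.standard_normal(n_samples)
        ranking = greedy_mrmr_rank(vectors, acts, cfg)
        if [r.target for r in ranking] == _oracle_greedy(vectors, acts, cfg):
            agree += 1
    return {"agreement_rate": agree / n_instances, "n": n_instances}


def planted_target_recovery(n_replicates: int = 100, seed: int = 0,
                            n_samples: int = 200, n_targets: int = 40,
                            n_informative: int = 5, coupling: float = 0.8,
                            n_pathways: int = 3, genes_per_pathway: int = 8) -> dict:
    """Rate at which every planted informative target is retained by the
    strict above-average MACS rule (plus auxiliary rank statistics)."""
    blocks = {f"P{i}": [f"P{i}_G{j}" for j in range(genes_per_pathway)]
              for i in range(n_pathways)}
    targets = [f"T{i:02d}" for i in range(n_targets)]
    cfg = MIEstimatorConfig()
    all_retained = 0
    first3_informative = 0
    all_top10 = 0
    for rep in range(n_replicates):
        ds, truth = generate_expression_dataset(
            n_samples, 4, blocks, targets, n_informative, coupling,
            seed=_sub_seed(seed, f"recovery:{rep}"))
        acts = [pathway_activity(ds, p, g, subset="tumor")
                for p, g in sorted(blocks.items())]
        X = ds.subset("tumor")
        ranking = greedy_mrmr_rank({t: X[t].to_numpy(dtype=float) for t in targets},
                                   acts, cfg)
        final = macs_scores([ranking])
        informative = set(truth.informative_targets)
        retained = {r.target for r in final if r.retained}
        all_retained += informative <= retained
        first3_informative += {r.target for r in ranking[:3]} <= informative
        all_top10 += informative <= {r.target for r in ranking[:10]}
    return {"all_retained_rate": all_retained / n_replicates,
            "first3_informative_rate": first3_informative / n_replicates,
            "all_in_top10_rate": all_top10 / n_replicates,
            "n": n_replicates}


def vip_normalization_fuzz(n_tables: int = 100, seed: int = 0) -> dict:
    """Max relative error of sum(VIP²) − p over random fitted tables."""
    worst = 0.0
    for i in range(n_tables):
        rng = np.random.default_rng(_sub_seed(seed, f"vip:{i}"))
        n_per = int(rng.integers(3, 8))
        p = int(rng.integers(5, 60))
        tab, _ = generate_metabolite_table(
            n_per, p, int(rng.integers(0, p // 2 + 1)),
            float(rng.uniform(0, 3)), seed=_sub_seed(seed, f"vip_tab:{i}"))
        kind = fit_oplsda(tab, 1) if i % 2 else fit_plsda(tab, min(2, n_per - 1))
        vip = np.array(list(compute_vip(kind).values()))
        worst = max(worst, abs(float(np.sum(vip**2)) - p) / p)
    return {"max_relative_error": worst, "n": n_tables}


def null_selection_calibration(n_tables: int = 200, seed: int = 0,
                               n_per_group: int = 6, n_metabolites: int = 50) -> dict:
    """Mean fraction of metabolites selected under the null (no planted
    effect) with the VIP>1 & p<0.05 rule."""
    frac = []
    for i in range(n_tables):
        tab, _ = generate_metabolite_table(n_per_group, n_metabolites, 0,
                                           seed=_sub_seed(seed, f"null:{i}"))
        model = fit_oplsda(tab, 1)
        vip = compute_vip(model)
        pvals = univariate_test(tab)
        diff = select_differential(vip, pvals, tab)
        frac.append(len(diff) / n_metabolites)
    return {"mean_selection_fraction": float(np.mean(frac)), "n": n_tables}


def null_permutation_flag_rate(n_tables: int = 100, seed: int = 0,
                               n_per_group: int = 6, n_metabolites: int = 50,
                               n_permutations: int = 20) -> dict:
    """Rate at which permutation validation declares a pure-noise model valid."""
    import warnings
    flags = 0
    for i in range(n_tables):
        tab, _ = generate_metabolite_table(n_per_group, n_metabolites, 0,
                                           seed=_sub_seed(seed, f"permnull:{i}"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = permutation_validate(tab, n_components=1,
                                       n_permutations=n_permutations,
                                       seed=_sub_seed(seed, f"permseed:{i}"))
        flags += rep.valid
    return {"flag_true_rate": flags / n_tables, "n": n_tables}
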