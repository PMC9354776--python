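"""Synthetic inputs with planted ground truth for the whole pipeline.

Three generators emulate the study design end to end, so every downstream
stage is testable without LC-MS runs or expression cohorts:

* :func:`generate_metabolite_table` — two-group LC-MS-like intensities,
  log-normal with sigma = 0.3 on the log scale; a planted minority of
  metabolites is shifted by a chosen number of within-group SDs, with
  alternating sign so both up- and down-regulated metabolites occur.
* :func:`generate_pathway_db` — disjoint pathways with connected member
  graphs; a planted subset of "core" pathways absorbs the differential
  metabolites (round-robin, so every planted metabolite sits in a core
  pathway); each metabolite is annotated to one or more metabolic genes.
* :func:`generate_expression_dataset` — tumor/normal cohorts in which each
  pathway's metabolic genes share one latent activity factor (loading 0.7)
  and a planted subset of candidate targets couples to those factors at a
  chosen correlation; all remaining genes are independent noise.

All generators are deterministic given their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, MetaboliteTable
from .enrichment import PathwayDefinition

__all__ = [
    "SyntheticTruth",
    "generate_metabolite_table",
    "generate_pathway_db",
    "generate_expression_dataset",
    "generate_target_gene_links",
]

LOG_SIGMA = 0.3          # within-group SD of log intensities (LC-MS-like spread)
GENE_LOADING = 0.7       # metabolic-gene loading on its pathway factor
TUMOR_SHIFT_SD = 0.5     # SD of per-gene tumor/normal mean offsets


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded by the generators."""

    differential_metabolites: list = field(default_factory=list)
    informative_targets: list = field(default_factory=list)
    pathway_assignments: dict = field(default_factory=dict)
    seed: int = 0
    # extras useful for tests
    shift_directions: dict = field(default_factory=dict)    # metabolite -> +1/-1
    planted_core_pathways: list = field(default_factory=list)
    target_pathways: dict = field(default_factory=dict)     # target -> pathway id


def generate_metabolite_table(n_per_group: int, n_metabolites: int,
                              n_differential: int, effect_size: float = 2.0,
                              seed: int = 0):
    """Two-group metabolite table with ``n_differential`` planted shifts.

    Intensities are log-normal: log-intensity of metabolite j is
    N(mu_j, 0.3²) with mu_j ~ N(10, 1). In the treated group the planted
    metabolites' log-means shift by ±effect_size × 0.3, alternating sign.
    """
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    if n_metabolites < 1:
        raise ValueError("n_metabolites must be >= 1")
    if not 0 <= n_differential <= n_metabolites:
        raise ValueError("need 0 <= n_differential <= n_metabolites")
    rng = np.random.default_rng(seed)
    mets = [f"M{i + 1:04d}" for i in range(n_metabolites)]
    samples = [f"C{i + 1:02d}" for i in range(n_per_group)] + \
              [f"T{i + 1:02d}" for i in range(n_per_group)]
    groups = ["control"] * n_per_group + ["treated"] * n_per_group
    mu = rng.normal(10.0, 1.0, size=n_metabolites)
    logx = mu + LOG_SIGMA * rng.standard_normal((2 * n_per_group, n_metabolites))
    planted_idx = np.sort(rng.choice(n_metabolites, size=n_differential, replace=False))
    directions = {}
    for order, j in enumerate(planted_idx):
        sign = 1.0 if order % 2 == 0 else -1.0
        logx[n_per_group:, j] += sign * effect_size * LOG_SIGMA
        directions[mets[j]] = int(sign)
    table = MetaboliteTable(
        intensities=pd.DataFrame(np.exp(logx), index=samples, columns=mets),
        groups=pd.Series(groups, index=samples),
    )
    truth = SyntheticTruth(
        differential_metabolites=[mets[j] for j in planted_idx],
        shift_directions=directions, seed=seed,
    )
    return table, truth


def _connected_edges(members, rng) -> list:
    """Random spanning tree plus a few chords — always connected."""
    order = list(members)
    rng.shuffle(order)
    edges = {tuple(sorted((order[i], order[rng.integers(0, i)])))
             for i in range(1, len(order))}
    n_extra = int(rng.integers(0, max(1, len(order) // 2) + 1))
    for _ in range(n_extra):
        i, j = rng.choice(len(order), size=2, replace=False)
        edges.add(tuple(sorted((order[i], order[j]))))
    return sorted(edges)


def generate_pathway_db(n_pathways: int, size_range: tuple, n_core_planted: int,
                        metabolite_ids, differential_ids, seed: int = 0):
    """Disjoint pathway definitions plus a metabolite→gene annotation table.

    The planted differential metabolites are dealt round-robin into the first
    ``n_core_planted`` pathways, so those pathways are over-represented in
    any reasonable hit set; remaining slots and pathways draw from the
    non-differential metabolites. Every universe metabolite is annotated to
    1–3 metabolic genes (genes are pathway-local for members, singleton
    otherwise).

    Returns (pathways, annotation DataFrame, truth).
    """
    lo, hi = int(size_range[0]), int(size_range[1])
    if lo < 2:
        raise ValueError("size_range lower bound must be >= 2")
    if hi < lo:
        raise ValueError("size_range upper bound below lower bound")
    if n_core_planted > n_pathways:
        raise ValueError("n_core_planted cannot exceed n_pathways")
    metabolite_ids = list(metabolite_ids)
    differential_ids = [m for m in differential_ids]
    if not set(differential_ids) <= set(metabolite_ids):
        raise ValueError("differential ids must be a subset of the metabolite universe")
    rng = np.random.default_rng(seed)

    sizes = rng.integers(lo, hi + 1, size=n_pathways)
    pool = [m for m in metabolite_ids if m not in set(differential_ids)]
    rng.shuffle(pool)
    pool_iter = iter(pool)

    # round-robin the planted metabolites into the core pathways
    core_members: list[list] = [[] for _ in range(n_core_planted)]
    for i, m in enumerate(differential_ids):
        if n_core_planted:
            core_members[i % n_core_planted].append(m)

    pathways = []
    assignments = {}
    for k in range(n_pathways):
        pid = f"PW{k + 1:02d}"
        members = list(core_members[k]) if k < n_core_planted else []
        want = max(int(sizes[k]), len(members), 2)
        while len(members) < want:
            try:
                members.append(next(pool_iter))
            except StopIteration:
                raise ValueError(
                    "metabolite universe too small for the requested pathway sizes"
                ) from None
        pathways.append(PathwayDefinition(
            pathway_id=pid, name=f"synthetic pathway {k + 1}",
            members=members, edges=_connected_edges(members, rng),
        ))
        assignments[pid] = list(members)

    rows = []
    in_pathway = {m: pid for pid, mem in assignments.items() for m in mem}
    counter = 0
    for m in metabolite_ids:
        n_genes = int(rng.integers(1, 4))
        for g in range(n_genes):
            counter += 1
            prefix = in_pathway.get(m, "free")
            rows.append((m, f"MG_{prefix}_{counter:04d}"))
    annotation = pd.DataFrame(rows, columns=["metabolite_id", "gene_id"])
    truth = SyntheticTruth(
        differential_metabolites=list(differential_ids),
        pathway_assignments=assignments,
        planted_core_pathways=[p.pathway_id for p in pathways[:n_core_planted]],
        seed=seed,
    )
    return pathways, annotation, truth


def generate_expression_dataset(n_tumor: int, n_normal: int, metabolic_genes,
                                targets, n_informative_targets: int,
                                coupling: float, seed: int = 0,
                                dataset_id: str = "synthetic",
                                informative_ids=None):
    """Tumor/normal expression with pathway-block structure and planted targets.

    ``metabolic_genes`` is a mapping pathway id -> gene ids (a flat list is
    treated as a single block). Genes of one block load on a shared latent
    factor at 0.7; the ``n_informative_targets`` planted targets couple to
    the block factors (round-robin) at Pearson ``coupling``; other targets
    are independent noise. Tumor samples get small per-gene mean offsets.
    """
    if isinstance(metabolic_genes, dict):
        blocks = {str(k): list(v) for k, v in metabolic_genes.items()}
    else:
        blocks = {"block1": list(metabolic_genes)}
    targets = list(targets)
    if not targets or not any(blocks.values()):
        raise ValueError("metabolic gene and target lists must be non-empty")
    if n_informative_targets > len(targets):
        raise ValueError("n_informative_targets exceeds number of targets")
    if not 0 <= coupling < 1:
        raise ValueError("coupling must be in [0, 1)")
    if n_tumor < 4 or n_normal < 4:
        raise ValueError("need >= 4 tumor and >= 4 normal samples")
    rng = np.random.default_rng(seed)
    n = n_tumor + n_normal
    samples = [f"TU{i + 1:03d}" for i in range(n_tumor)] + \
              [f"NO{i + 1:03d}" for i in range(n_normal)]
    condition = ["tumor"] * n_tumor + ["normal"] * n_normal
    tumor_mask = np.array([c == "tumor" for c in condition], dtype=float)

    block_ids = sorted(blocks)
    factors = {b: rng.standard_normal(n) for b in block_ids}
    data = {}
    lam = GENE_LOADING
    for b in block_ids:
        f = factors[b]
        for gname in blocks[b]:
            noise = rng.standard_normal(n)
            shift = rng.normal(0.0, TUMOR_SHIFT_SD)
            data[gname] = lam * f + np.sqrt(1 - lam**2) * noise + shift * tumor_mask

    if informative_ids is None:
        informative = sorted(
            rng.choice(len(targets), size=n_informative_targets, replace=False).tolist()
        )
        informative_ids = [targets[i] for i in informative]
    else:
        informative_ids = list(informative_ids)
        if not set(informative_ids) <= set(targets):
            raise ValueError("informative_ids must be a subset of targets")
        if len(informative_ids) != n_informative_targets:
            raise ValueError("informative_ids length must equal n_informative_targets")
    target_pathways = {}
    for order, t in enumerate(informative_ids):
        b = block_ids[order % len(block_ids)]
        target_pathways[t] = b
    for t in targets:
        noise = rng.standard_normal(n)
        shift = rng.normal(0.0, TUMOR_SHIFT_SD)
        if t in target_pathways and coupling > 0:
            f = factors[target_pathways[t]]
            data[t] = coupling * f + np.sqrt(1 - coupling**2) * noise + shift * tumor_mask
        else:
            data[t] = noise + shift * tumor_mask

    cols = [g for b in block_ids for g in blocks[b]] + targets
    expr = pd.DataFrame({c: data[c] for c in cols}, index=samples)
    dataset = ExpressionDataset(dataset_id=dataset_id, expression=expr,
                                condition=pd.Series(condition, index=samples))
    truth = SyntheticTruth(informative_targets=informative_ids,
                           target_pathways=target_pathways, seed=seed)
    return dataset, truth


def generate_target_gene_links(targets, metabolic_genes, truth: SyntheticTruth,
                               pathway_genes: dict | None = None, seed: int = 0,
                               links_per_target: int = 2) -> pd.DataFrame:
    """Synthetic stand-in for a protein-association link table.

    Informative targets link preferentially to genes of their own pathway
    block; every target gets ``links_per_target`` links.
    """
    rng = np.random.default_rng(seed)
    metabolic_genes = sorted(metabolic_genes)
    rows = []
    for t in sorted(targets):
        pool = metabolic_genes
        if pathway_genes and t in truth.target_pathways:
            own = sorted(set(pathway_genes.get(truth.target_pathways[t], [])) &
                         set(metabolic_genes))
            if own:
                pool = own
        k = min(links_per_target, len(pool))
        for g in rng.choice(len(pool), size=k, replace=False):
            rows.append((t, pool[g]))
    return pd.DataFrame(rows, columns=["target_id", "gene_id"])
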