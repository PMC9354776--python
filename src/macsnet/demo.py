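"""Bundled synthetic demo: writes every pipeline input plus a ready config.

The demo emulates the study design at desk scale: a 8+8-sample two-group
metabolite table with 10 planted differential metabolites, ten pathways of
which three are planted core pathways, and three tumor/normal expression
cohorts sized like typical public HCC microarray series (39/30, 39/39,
240/193) with four of twenty candidate targets coupled to core-pathway
activity at r = 0.8.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .pipeline import stage_seed
from .enrichment import save_pathway_db
from .synthetic import (SyntheticTruth, generate_expression_dataset,
                        generate_metabolite_table, generate_pathway_db,
                        generate_target_gene_links)

__all__ = ["write_demo_bundle", "DEMO_SCALES"]

DEMO_SCALES = dict(
    n_per_group=10, n_metabolites=80, n_differential=12, effect_size=3.0,
    n_pathways=10, size_range=(4, 8), n_core_planted=3,
    cohorts=[("GSEsimA", 39, 30), ("GSEsimB", 39, 39), ("GSEsimC", 240, 193)],
    n_targets=20, n_informative=4, coupling=0.8,
)


def write_demo_bundle(outdir, seed: int = 0, scales: dict | None = None) -> dict:
    """Generate all pipeline inputs under ``outdir``; returns paths + truth."""
    sc = dict(DEMO_SCALES)
    if scales:
        sc.update(scales)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    table, met_truth = generate_metabolite_table(
        sc["n_per_group"], sc["n_metabolites"], sc["n_differential"],
        sc["effect_size"], seed=stage_seed(seed, "sim_metabolites"))
    table_path = outdir / "metabolite_table.tsv"
    table.to_tsv(table_path)

    pathways, annotation, pw_truth = generate_pathway_db(
        sc["n_pathways"], sc["size_range"], sc["n_core_planted"],
        table.metabolite_ids, met_truth.differential_metabolites,
        seed=stage_seed(seed, "sim_pathways"))
    db_path = outdir / "pathway_db.json"
    save_pathway_db(pathways, db_path)
    ann_path = outdir / "annotation.tsv"
    annotation.to_csv(ann_path, sep="\t", index=False)

    # metabolic-gene blocks per planted core pathway drive the expression model
    ann_by_met = annotation.groupby("metabolite_id")["gene_id"].agg(
        lambda s: sorted(set(s)))
    blocks = {
        pid: sorted({g for m in pw_truth.pathway_assignments[pid]
                     for g in ann_by_met.get(m, [])})
        for pid in pw_truth.planted_core_pathways
    }
    targets = [f"TGT{i + 1:03d}" for i in range(sc["n_targets"])]
    rng = np.random.default_rng(stage_seed(seed, "sim_informative"))
    informative = sorted(
        targets[i] for i in rng.choice(len(targets), size=sc["n_informative"],
                                       replace=False))
    expr_paths = []
    truth = SyntheticTruth(
        differential_metabolites=met_truth.differential_metabolites,
        informative_targets=informative,
        pathway_assignments=pw_truth.pathway_assignments,
        planted_core_pathways=pw_truth.planted_core_pathways,
        shift_directions=met_truth.shift_directions, seed=seed)
    for name, n_tumor, n_normal in sc["cohorts"]:
        ds, ds_truth = generate_expression_dataset(
            n_tumor, n_normal, blocks, targets, sc["n_informative"],
            sc["coupling"], seed=stage_seed(seed, f"sim_expr_{name}"),
            dataset_id=name, informative_ids=informative)
        p = outdir / f"expression_{name}.tsv"
        ds.to_tsv(p)
        expr_paths.append(p)
        truth.target_pathways = ds_truth.target_pathways

    targets_path = outdir / "targets.txt"
    targets_path.write_text("".join(f"{t}\n" for t in targets))
    metabolic_genes = sorted({g for gs in blocks.values() for g in gs})
    links = generate_target_gene_links(
        targets, metabolic_genes, truth, pathway_genes=blocks,
        seed=stage_seed(seed, "sim_links"))
    links_path = outdir / "target_gene_links.tsv"
    links.to_csv(links_path, sep="\t", index=False)

    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps({
        "differential_metabolites": truth.differential_metabolites,
        "informative_targets": truth.informative_targets,
        "planted_core_pathways": truth.planted_core_pathways,
        "target_pathways": truth.target_pathways,
        "seed": seed,
    }, indent=1, sort_keys=True))

    expr_lines = "".join(f"    - {p.name}\n" for p in expr_paths)
    config_text = f"""inputs:
  metabolite_table: {table_path.name}
  expression_datasets:
{expr_lines}  pathway_db: {db_path.name}
  annotation: {ann_path.name}
  targets: {targets_path.name}
  target_gene_links: {links_path.name}
# the candidate pool is small here, so selection is left entirely to the
# above-average MACS rule; raise r_min to pre-gate candidates by coexpression
thresholds:
  r_min: 0.0
output_dir: results
compound_id: DEMO_COMPOUND
seed: {seed}
"""
    config_path = outdir / "config.yaml"
    config_path.write_text(config_text)
    return {"config": config_path, "truth": truth, "table": table_path,
            "expression": expr_paths, "pathway_db": db_path,
            "annotation": ann_path, "targets": targets_path,
            "links": links_path}
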