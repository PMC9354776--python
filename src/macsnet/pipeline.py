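"""End-to-end orchestration: metabolite table -> retained targets -> network.

Stages run in a fixed order (multivariate, differential, enrichment,
core_flag, gene_mapping, coexpression, macs, network); each writes its
outputs under the configured output directory and the run manifest records
parameters, per-stage outputs and SHA-256 checksums. A fixed config + seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .coexpression import (aggregate_coexpression, compute_coexpression,
                           filter_candidate_targets)
from .datatypes import ExpressionDataset, MetaboliteTable
from .differential import select_differential, univariate_test
from .enrichment import load_pathway_db, enrich_pathways, results_to_frame
from .macs import greedy_mrmr_rank, macs_scores, pathway_activity
from .macs import results_to_frame as macs_frame
from .mi import MIEstimatorConfig
from .multivariate import compute_vip, fit_oplsda, fit_pca, permutation_validate
from .network import (build_multilevel_network, load_annotation,
                      map_metabolites_to_genes, write_graphml, write_sif)

__all__ = ["run_pipeline", "stage_seed", "PipelineError"]

logger = logging.getLogger(__name__)

STAGES = ("multivariate", "differential", "enrichment", "core_flag",
          "gene_mapping", "coexpression", "macs", "network")


class PipelineError(RuntimeError):
    """A stage failed; the manifest records what completed."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: SHA-256 of 'seed:stage', reduced below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "thresholds": config.thresholds,
            "multivariate": config.multivariate,
            "macs": dict(config.macs),
            "compound_id": config.compound_id,
        },
        "stages": [],
    }

    def record(stage: str, outputs: list[Path], **info):
        manifest["stages"].append({
            "name": stage,
            "outputs": {str(p.name): _sha256(p) for p in outputs},
            **info,
        })

    try:
        # ---- stage 1: multivariate chemometrics -------------------------
        table = MetaboliteTable.from_tsv(config.metabolite_table)
        mv = config.multivariate
        n_pca = min(mv["pca_components"], len(table.sample_ids) - 1,
                    len(table.metabolite_ids))
        pca = fit_pca(table, n_pca, scaling=mv["scaling"])
        opls = fit_oplsda(table, n_orthogonal=mv["n_orthogonal"],
                          scaling=mv["scaling"], cv_folds=mv["cv_folds"])
        vip = compute_vip(opls)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            perm = permutation_validate(
                table, n_components=1, n_permutations=mv["n_permutations"],
                cv_folds=mv["cv_folds"], seed=stage_seed(config.seed, "multivariate"),
                scaling=mv["scaling"])
        scores = pd.DataFrame(
            {"pca1": pca.scores[:, 0],
             "pca2": pca.scores[:, 1] if n_pca > 1 else np.nan,
             "opls_predictive": opls.scores[:, 0]},
            index=table.sample_ids)
        if opls.ortho_scores is not None:
            scores["opls_orthogonal1"] = opls.ortho_scores[:, 0]
        scores_path = out / "multivariate_scores.tsv"
        scores.to_csv(scores_path, sep="\t", index_label="sample_id",
                      float_format="%.10g")
        vip_path = out / "vip.tsv"
        pd.Series(vip, name="vip").sort_index().to_csv(
            vip_path, sep="\t", index_label="metabolite_id", float_format="%.10g")
        report_path = out / "fit_report.json"
        report_path.write_text(json.dumps({
            "pca_explained_variance": [round(float(v), 10) for v in pca.explained_variance],
            "oplsda": {"r2x": round(opls.r2x, 10), "r2y": round(opls.r2y, 10),
                       "q2": round(opls.q2, 10)},
            "permutation": {"n": perm.n_permutations, "valid": perm.valid,
                            "max_permuted_r2y": round(float(perm.permuted_r2y.max()), 10),
                            "max_permuted_q2": round(float(perm.permuted_q2.max()), 10)},
        }, indent=1, sort_keys=True))
        record("multivariate", [scores_path, vip_path, report_path],
               permutation_valid=perm.valid)

        # ---- stage 2: differential metabolites --------------------------
        pvals = univariate_test(table)
        diff = select_differential(vip, pvals, table,
                                   vip_threshold=config.thresholds["vip"],
                                   p_threshold=config.thresholds["p"])
        diff_path = out / "differential_metabolites.tsv"
        pd.DataFrame(
            [dict(metabolite_id=d.metabolite_id, vip=d.vip, p_value=d.p_value,
                  direction=d.direction, control_mean=d.control_mean,
                  treated_mean=d.treated_mean, provenance="table")
             for d in diff]
        ).to_csv(diff_path, sep="\t", index=False, float_format="%.10g")
        record("differential", [diff_path], n_differential=len(diff))

        # ---- stage 3: pathway enrichment --------------------------------
        pathways = load_pathway_db(config.pathway_db)
        universe = set(table.metabolite_ids)
        hits = {d.metabolite_id for d in diff}
        if config.extra_metabolites:
            extra = [ln.strip() for ln in
                     Path(config.extra_metabolites).read_text().splitlines()
                     if ln.strip() and not ln.startswith("#")]
            hits |= set(extra)
            universe |= set(extra)
            logger.info("merged %d externally measured metabolites into the hit set",
                        len(extra))
        testable = [p for p in pathways if set(p.members) & universe]
        enr = enrich_pathways(hits, testable, universe,
                              core_alpha=config.thresholds["core_alpha"])
        enr_path = out / "pathway_enrichment.tsv"
        results_to_frame(enr).to_csv(enr_path, sep="\t", index=False,
                                     float_format="%.10g")
        record("enrichment", [enr_path], n_pathways=len(enr))

        # ---- stage 4: core-pathway flag ----------------------------------
        core = [r for r in enr if r.is_core]
        core_path = out / "core_pathways.txt"
        core_path.write_text("".join(f"{r.pathway_id}\n" for r in core))
        record("core_flag", [core_path], n_core=len(core))
        core_defs = [p for p in pathways
                     if p.pathway_id in {r.pathway_id for r in core}]

        # ---- stage 5: metabolite -> gene mapping -------------------------
        annotation = load_annotation(config.annotation)
        bip, metabolic_genes = map_metabolites_to_genes(core_defs, diff, annotation)
        genes_path = out / "metabolic_genes.txt"
        genes_path.write_text("".join(f"{g}\n" for g in metabolic_genes))
        record("gene_mapping", [genes_path], n_genes=len(metabolic_genes))

        # ---- stage 6: coexpression ---------------------------------------
        targets = [ln.strip() for ln in Path(config.targets).read_text().splitlines()
                   if ln.strip() and not ln.startswith("#")]
        datasets = [ExpressionDataset.from_tsv(p, dataset_id=Path(p).stem)
                    for p in config.expression_datasets]
        subset = config.macs["subset"]
        matrices = [compute_coexpression(ds, metabolic_genes, targets, subset=subset)
                    for ds in datasets]
        consensus = aggregate_coexpression(matrices)
        cons_path = out / "coexpression_consensus.tsv"
        consensus.r.to_csv(cons_path, sep="\t", index_label="target",
                           float_format="%.10g")
        candidates = filter_candidate_targets(consensus,
                                              r_min=config.thresholds["r_min"])
        record("coexpression", [cons_path], n_candidates=len(candidates))
        if len(candidates) < 2:
            raise PipelineError(
                "fewer than 2 candidate targets survive the coexpression gate; "
                "lower thresholds.r_min")

        # ---- stage 7: MACS target ranking --------------------------------
        mi_cfg = MIEstimatorConfig(method=config.macs["estimator"],
                                   k=config.macs["k"], bins=config.macs["bins"])
        # a core pathway's metabolic genes = annotation genes of its members
        ann_by_met = annotation.groupby("metabolite_id")["gene_id"].agg(
            lambda s: sorted(set(s)))
        rankings = []
        for ds in datasets:
            activities = []
            for pw in core_defs:
                genes = sorted({g for m in pw.members for g in ann_by_met.get(m, [])})
                try:
                    activities.append(pathway_activity(ds, pw.pathway_id, genes,
                                                       subset=subset))
                except ValueError as exc:
                    logger.warning("skipping pathway %s in %s: %s",
                                   pw.pathway_id, ds.dataset_id, exc)
            if not activities:
                raise PipelineError(
                    f"no usable core-pathway activity in dataset {ds.dataset_id}")
            X = ds.subset(subset)
            cand = {t: X[t].to_numpy(dtype=float) for t in candidates
                    if t in X.columns}
            rankings.append(greedy_mrmr_rank(cand, activities, mi_cfg))
        final = macs_scores(rankings, aggregation=config.macs["aggregation"])
        macs_path = out / "macs_targets.tsv"
        macs_frame(final).to_csv(macs_path, sep="\t", index=False,
                                 float_format="%.10g")
        retained = [r.target for r in final if r.retained]
        record("macs", [macs_path], n_retained=len(retained))

        # ---- stage 8: multilevel network ---------------------------------
        if config.target_gene_links:
            links_df = pd.read_csv(config.target_gene_links, sep="\t", comment="#",
                                   dtype=str)
            links = [(t, g) for t, g in links_df.itertuples(index=False, name=None)
                     if g in set(metabolic_genes)]
            n_drop = len(links_df) - len(links)
            if n_drop:
                logger.info("dropped %d link(s) to genes outside the metabolic-gene "
                            "layer", n_drop)
        else:
            links = []
            logger.warning("no target-gene link table: network has no "
                           "target-metabolic_gene edges")
        memberships = {p.pathway_id: list(p.members) for p in core_defs}
        net = build_multilevel_network(config.compound_id, retained, links, bip,
                                       memberships)
        gml_path = out / "multilevel_network.graphml"
        sif_path = out / "multilevel_network.sif"
        write_graphml(net, gml_path)
        write_sif(net, sif_path)
        record("network", [gml_path, sif_path],
               n_nodes=net.number_of_nodes(), n_edges=net.number_of_edges())
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
        raise PipelineError(str(exc)) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
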