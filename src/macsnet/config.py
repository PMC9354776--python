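"""Pipeline configuration: YAML parsing, defaulting and validation.

Unknown keys are rejected (typo protection); every applied default is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "validate_config"]

logger = logging.getLogger(__name__)

_REQUIRED_INPUTS = ("metabolite_table", "expression_datasets", "pathway_db",
                    "annotation", "targets")
_OPTIONAL_INPUTS = ("target_gene_links", "extra_metabolites")

_DEFAULTS = {
    "thresholds": {"vip": 1.0, "p": 0.05, "core_alpha": 0.05, "r_min": 0.3},
    "multivariate": {"scaling": "uv", "n_orthogonal": 1, "n_permutations": 100,
                     "cv_folds": 7, "pca_components": 2},
    "macs": {"estimator": "knn", "k": 3, "bins": None, "aggregation": "mean",
             "subset": "tumor"},
    "compound_id": "COMPOUND",
    "seed": 0,
}


@dataclass
class PipelineConfig:
    metabolite_table: Path
    expression_datasets: list
    pathway_db: Path
    annotation: Path
    targets: Path
    output_dir: Path
    target_gene_links: Path | None = None
    extra_metabolites: Path | None = None
    thresholds: dict = field(default_factory=dict)
    multivariate: dict = field(default_factory=dict)
    macs: dict = field(default_factory=dict)
    compound_id: str = "COMPOUND"
    seed: int = 0


def _merge_defaults(section: str, given: dict) -> dict:
    merged = dict(_DEFAULTS[section])
    unknown = set(given) - set(merged)
    if unknown:
        raise ValueError(f"unknown keys in '{section}': {sorted(unknown)}")
    for k, v in given.items():
        merged[k] = v
    for k in set(merged) - set(given):
        logger.info("config default applied: %s.%s = %r", section, k, merged[k])
    return merged


def validate_config(raw: str, base_dir: str | Path = ".") -> PipelineConfig:
    """Parse and validate YAML config text; returns a fully-defaulted config.

    Relative paths resolve against ``base_dir``. Missing required inputs,
    unknown keys, and out-of-range thresholds all raise ``ValueError``.
    """
    data = yaml.safe_load(raw)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config must be a YAML mapping")
    base = Path(base_dir)
    known_top = {"inputs", "thresholds", "multivariate", "macs", "compound_id",
                 "output_dir", "seed"}
    unknown = set(data) - known_top
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")

    inputs = data.get("inputs", {}) or {}
    unknown_in = set(inputs) - set(_REQUIRED_INPUTS) - set(_OPTIONAL_INPUTS)
    if unknown_in:
        raise ValueError(f"unknown input keys: {sorted(unknown_in)}")
    missing = [k for k in _REQUIRED_INPUTS if k not in inputs]
    if missing or "output_dir" not in data:
        need = missing + (["output_dir"] if "output_dir" not in data else [])
        raise ValueError(f"missing required config keys: {need}")

    def respath(p):
        q = Path(p)
        return q if q.is_absolute() else base / q

    expr = inputs["expression_datasets"]
    if isinstance(expr, (str, Path)):
        expr = [expr]
    if not expr:
        raise ValueError("expression_datasets must list at least one file")
    paths = {
        "metabolite_table": respath(inputs["metabolite_table"]),
        "expression_datasets": [respath(p) for p in expr],
        "pathway_db": respath(inputs["pathway_db"]),
        "annotation": respath(inputs["annotation"]),
        "targets": respath(inputs["targets"]),
        "target_gene_links": respath(inputs["target_gene_links"])
        if inputs.get("target_gene_links") else None,
        "extra_metabolites": respath(inputs["extra_metabolites"])
        if inputs.get("extra_metabolites") else None,
    }
    flat = list(paths["expression_datasets"]) + [
        v for k, v in paths.items() if k != "expression_datasets" and v is not None
    ]
    absent = [str(p) for p in flat if not Path(p).exists()]
    if absent:
        raise ValueError(f"input paths do not exist: {absent}")

    thr = _merge_defaults("thresholds", data.get("thresholds", {}) or {})
    if thr["vip"] < 0:
        raise ValueError("vip threshold must be >= 0")
    if not 0 < thr["p"] < 1:
        raise ValueError("p threshold must be in (0, 1)")
    if not 0 < thr["core_alpha"] <= 1:
        raise ValueError("core_alpha must be in (0, 1]")
    if not 0 <= thr["r_min"] <= 1:
        raise ValueError("r_min must be in [0, 1]")

    mv = _merge_defaults("multivariate", data.get("multivariate", {}) or {})
    if mv["scaling"] not in ("center", "uv", "pareto"):
        raise ValueError("multivariate.scaling must be center|uv|pareto")
    if mv["n_orthogonal"] < 0 or mv["n_permutations"] < 20 or mv["cv_folds"] < 2:
        raise ValueError("invalid multivariate options")

    mc = _merge_defaults("macs", data.get("macs", {}) or {})
    if mc["estimator"] not in ("knn", "histogram"):
        raise ValueError("macs.estimator must be knn|histogram")
    if mc["k"] < 1 or (mc["bins"] is not None and mc["bins"] < 2):
        raise ValueError("invalid macs estimator options")
    if mc["aggregation"] not in ("mean", "median"):
        raise ValueError("macs.aggregation must be mean|median")
    if mc["subset"] not in ("tumor", "normal", "all"):
        raise ValueError("macs.subset must be tumor|normal|all")

    seed = int(data.get("seed", _DEFAULTS["seed"]))
    if seed < 0:
        raise ValueError("seed must be >= 0")

    return PipelineConfig(
        output_dir=respath(data["output_dir"]),
        thresholds=thr, multivariate=mv, macs=mc,
        compound_id=str(data.get("compound_id", _DEFAULTS["compound_id"])),
        seed=seed, **paths,
    )
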