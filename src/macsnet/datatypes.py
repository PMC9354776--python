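"""Core in-memory containers shared across pipeline stages.

Both containers wrap a samples x features :class:`pandas.DataFrame` plus a
per-sample label vector, with validation at construction so downstream stages
can assume a clean two-group design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MetaboliteTable", "ExpressionDataset"]


@dataclass
class MetaboliteTable:
    """Two-group metabolite intensity table (samples x metabolites).

    Parameters
    ----------
    intensities
        Positive intensities, indexed by sample id, one column per metabolite.
    groups
        Per-sample group label; exactly two levels, each with >= 3 samples.
    """

    intensities: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups, index=self.intensities.index).astype(str)
        if self.groups.isna().any():
            raise ValueError("missing group labels")
        levels = sorted(self.groups.unique())
        if len(levels) != 2:
            raise ValueError(f"expected exactly two group levels, got {levels}")
        counts = self.groups.value_counts()
        if (counts < 3).any():
            raise ValueError(f"each group needs >= 3 samples, got {counts.to_dict()}")
        if not self.intensities.columns.is_unique:
            raise ValueError("duplicate metabolite ids")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def group_levels(self) -> tuple[str, str]:
        """The two group labels in alphabetical order (control, treated)."""
        a, b = sorted(self.groups.unique())
        return a, b

    def matrix(self) -> np.ndarray:
        return self.intensities.to_numpy(dtype=float)

    def y(self) -> np.ndarray:
        """+/-1 class coding; alphabetically first label is -1."""
        _, hi = self.group_levels
        return np.where(self.groups.to_numpy() == hi, 1.0, -1.0)

    def to_tsv(self, path) -> None:
        out = self.intensities.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "MetaboliteTable":
        df = pd.read_csv(path, sep="\t", index_col="sample_id", comment="#")
        groups = df.pop("group")
        return cls(intensities=df.astype(float), groups=groups)


@dataclass
class ExpressionDataset:
    """Tumor/normal expression matrix (samples x genes) for one cohort."""

    dataset_id: str
    expression: pd.DataFrame
    condition: pd.Series = field(repr=False)

    CONDITIONS = ("tumor", "normal")

    def __post_init__(self) -> None:
        self.condition = pd.Series(self.condition, index=self.expression.index).astype(str)
        if self.condition.isna().any():
            raise ValueError("missing condition labels")
        bad = set(self.condition.unique()) - set(self.CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if not self.expression.columns.is_unique:
            raise ValueError("duplicate gene ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.columns)

    def subset(self, which: str = "tumor") -> pd.DataFrame:
        """Expression restricted to 'tumor', 'normal' or 'all' samples."""
        if which == "all":
            return self.expression
        if which not in self.CONDITIONS:
            raise ValueError(f"subset must be tumor|normal|all, got {which!r}")
        return self.expression.loc[self.condition == which]

    def to_tsv(self, path) -> None:
        out = self.expression.copy()
        out.insert(0, "condition", self.condition)
        out.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, dataset_id: str | None = None) -> "ExpressionDataset":
        df = pd.read_csv(path, sep="\t", index_col="sample_id", comment="#")
        condition = df.pop("condition")
        name = dataset_id if dataset_id is not None else str(path)
        return cls(dataset_id=name, expression=df.astype(float), condition=condition)
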