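"""Core containers shared by every pipeline stage.

The central object is :class:`ExpressionMatrix`, a labelled numeric matrix of
expression values. Internally all stages work with genes-by-samples
orientation (one row per gene, one column per sample); the samples-by-genes
orientation exists because the ICA model is conventionally written on the
transposed matrix, where each row is one sample's profile over all genes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Orientation",
    "ExpressionMatrix",
    "PhenotypeLabels",
    "GeneFactorError",
    "FormatError",
    "ParameterError",
    "DegenerateInputError",
    "ConvergenceError",
]


class GeneFactorError(Exception):
    """Base class for all package errors."""


class FormatError(GeneFactorError):
    """Malformed input file: duplicates, non-numeric cells, missing values."""


class ParameterError(GeneFactorError):
    """A parameter violates its documented domain."""


class DegenerateInputError(GeneFactorError):
    """Numerically degenerate input (constant sample, zero vector, ...)."""


class ConvergenceError(GeneFactorError):
    """An iterative routine failed to produce any usable result."""


class Orientation(str, enum.Enum):
    GENES_BY_SAMPLES = "genes_by_samples"
    SAMPLES_BY_GENES = "samples_by_genes"


@dataclass(frozen=True)
class ExpressionMatrix:
    """A labelled expression matrix.

    Parameters
    ----------
    values
        Numeric matrix. Shape is ``(n_genes, n_samples)`` under
        ``genes_by_samples`` orientation and the transpose otherwise.
    gene_ids, sample_ids
        Unique identifiers for rows/columns (in the genes-by-samples sense).
    orientation
        Which axis holds genes; all public accessors are orientation-safe.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    orientation: Orientation = Orientation.GENES_BY_SAMPLES

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise FormatError(f"expression matrix must be 2-D, got {values.ndim}-D")
        n, m = len(self.gene_ids), len(self.sample_ids)
        expected = (n, m) if self.orientation is Orientation.GENES_BY_SAMPLES else (m, n)
        if values.shape != expected:
            raise FormatError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples "
                f"under {self.orientation.value} orientation"
            )
        if len(set(self.gene_ids)) != n:
            raise FormatError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != m:
            raise FormatError("duplicate sample identifiers")
        if not np.all(np.isfinite(values)):
            raise FormatError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def as_genes_by_samples(self) -> "ExpressionMatrix":
        if self.orientation is Orientation.GENES_BY_SAMPLES:
            return self
        return replace(
            self, values=self.values.T, orientation=Orientation.GENES_BY_SAMPLES
        )

    def as_samples_by_genes(self) -> "ExpressionMatrix":
        if self.orientation is Orientation.SAMPLES_BY_GENES:
            return self
        return replace(
            self, values=self.values.T, orientation=Orientation.SAMPLES_BY_GENES
        )

    def genes_by_samples_values(self) -> np.ndarray:
        """The raw matrix in (n_genes, n_samples) layout."""
        return self.as_genes_by_samples().values

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class PhenotypeLabels:
    """Sample-to-group mapping over exactly two phenotype groups.

    ``groups`` is ordered; downstream stages treat ``groups[0]`` as the
    phenotype of interest (e.g. the disease group) when orienting
    up/down-regulation calls.
    """

    assignments: Mapping[str, str]
    groups: tuple[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", dict(self.assignments))
        object.__setattr__(self, "groups", tuple(self.groups))
        if len(self.groups) != 2 or self.groups[0] == self.groups[1]:
            raise ParameterError("exactly two distinct group labels required")
        seen = set(self.assignments.values())
        if seen != set(self.groups):
            raise ParameterError(
                f"assignment groups {sorted(seen)} do not match declared "
                f"groups {list(self.groups)}"
            )
        for g in self.groups:
            n = sum(1 for v in self.assignments.values() if v == g)
            if n < 2:
                raise ParameterError(f"group {g!r} has {n} samples; need >= 2")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.assignments)

    def group_of(self, sample_id: str) -> str:
        return self.assignments[sample_id]

    def mask(self, sample_ids: Sequence[str], group: str) -> np.ndarray:
        """Boolean mask selecting ``sample_ids`` that belong to ``group``."""
        if group not in self.groups:
            raise ParameterError(f"unknown group {group!r}")
        return np.array([self.assignments[s] == group for s in sample_ids])

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]]) -> "PhenotypeLabels":
        """Build labels from (sample, group) pairs; group order is first appearance."""
        assignments: dict[str, str] = {}
        order: list[str] = []
        for sample, group in pairs:
            if sample in assignments:
                raise FormatError(f"sample {sample!r} listed twice")
            assignments[sample] = group
            if group not in order:
                order.append(group)
        if len(order) != 2:
            raise FormatError(f"expected exactly 2 groups, found {len(order)}")
        return cls(assignments=assignments, groups=(order[0], order[1]))
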