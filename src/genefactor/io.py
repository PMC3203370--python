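"""Tab-delimited readers/writers and run configuration.

File conventions
----------------
Expression TSV
    Header ``gene_id<TAB>sample1<TAB>...``, one row per gene. Values must be
    numeric and complete; missing cells are rejected rather than imputed.
Phenotype TSV
    ``sample_id<TAB>group`` with no header; group order is first appearance.
Config YAML
    Flat mapping mirroring :class:`RunConfig` field names; every field has a
    default, so a partial (or absent) file is valid.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ExpressionMatrix,
    FormatError,
    Orientation,
    ParameterError,
    PhenotypeLabels,
)

__all__ = [
    "RunConfig",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "write_table",
    "read_table",
    "get_logger",
]

logger = logging.getLogger("genefactor")


def get_logger() -> logging.Logger:
    """Package logger with a timestamp/stage formatter attached once."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s\t%(name)s\t%(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of a pipeline run.

    ICA settings: ``a1`` is the slope of the tanh contrast nonlinearity,
    ``ica_n_restarts`` the number of random restarts pooled into the
    consensus, ``loading_threshold`` the |z| cutoff for gene calls.
    nsNMF settings: ``k`` is the factorization rank, ``theta`` the smoothing
    strength in [0, 1], ``nsnmf_n_iter`` the fixed multiplicative-update
    budget, ``epsilon_floor`` the positivity floor on the factors.
    """

    seed: int = 17
    # FastICA
    a1: float = 1.0
    ica_n_restarts: int = 100
    ica_tol: float = 1e-6
    ica_max_iter: int = 1000
    loading_threshold: float = 2.5
    # nsNMF
    k: int = 2
    theta: float = 0.5
    nsnmf_n_restarts: int = 40
    nsnmf_n_iter: int = 2000
    epsilon_floor: float = 1e-9
    # gene selection
    nmf_gene_z_threshold: float = 2.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ParameterError(f"theta must be in [0, 1], got {self.theta}")
        if self.k < 1:
            raise ParameterError(f"k must be >= 1, got {self.k}")
        for name in (
            "ica_n_restarts",
            "ica_max_iter",
            "nsnmf_n_restarts",
            "nsnmf_n_iter",
        ):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")
        for name in ("a1", "ica_tol", "loading_threshold", "epsilon_floor",
                     "nmf_gene_z_threshold"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: Mapping[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    def restart_seed(self, restart: int) -> int:
        """Derived seed for restart ``restart``; reproducible in isolation.

        Kept below 2**31 so every downstream RNG accepts it.
        """
        return int((self.seed + 1_000_003 * (restart + 1)) % (2**31 - 1))


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes-by-samples expression TSV.

    Rejects duplicate identifiers and any non-numeric or missing cell,
    naming the offending row and column.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: no sample columns found")
    sample_ids = header[1:]  # pandas mangles duplicate names, so check raw
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicate sample identifier in header")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    if len(set(gene_ids)) != len(gene_ids):
        raise FormatError(f"{path}: duplicate gene identifier")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.where(~np.isfinite(converted.to_numpy(dtype=float)))[0]
        if bad.size:
            raise FormatError(
                f"{path}: non-numeric or missing value at gene "
                f"{gene_ids[bad[0]]!r}, sample {sample_ids[j]!r}"
            )
        values[:, j] = converted.to_numpy(dtype=float)
    return ExpressionMatrix(
        values=values,
        gene_ids=tuple(gene_ids),
        sample_ids=tuple(sample_ids),
        orientation=Orientation.GENES_BY_SAMPLES,
    )


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a genes-by-samples expression TSV with full float precision."""
    m = matrix.as_genes_by_samples()
    df = pd.DataFrame(m.values, index=list(m.gene_ids), columns=list(m.sample_ids))
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_phenotypes(path: str | Path, matrix: ExpressionMatrix) -> PhenotypeLabels:
    """Read a two-column (sample, group) TSV and align it to ``matrix``.

    Every sample of the matrix must be labelled exactly once, no extra
    samples may appear, and exactly two groups must be present.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise FormatError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        pairs.append((fields[0], fields[1]))
    labels = PhenotypeLabels.from_pairs(pairs)
    matrix_samples = set(matrix.sample_ids)
    labelled = set(labels.sample_ids)
    missing = matrix_samples - labelled
    extra = labelled - matrix_samples
    if missing:
        raise FormatError(f"{path}: samples missing from phenotype file: {sorted(missing)}")
    if extra:
        raise FormatError(f"{path}: unknown samples in phenotype file: {sorted(extra)}")
    return labels


def write_phenotypes(labels: PhenotypeLabels, path: str | Path) -> None:
    lines = [f"{s}\t{g}" for s, g in labels.assignments.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_table(rows: pd.DataFrame | Iterable[Mapping[str, Any]],
                path: str | Path) -> None:
    """Write a header-bearing TSV; floats carry >= 10 significant digits."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=0)
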