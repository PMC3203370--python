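"""Normalization into the two forms the factorizations require.

The ICA track consumes a sample-standardized matrix (each sample profile has
zero mean and unit standard deviation over genes). The NMF track consumes a
nonnegative matrix built from the raw input — standardization would destroy
nonnegativity, so the two tracks branch from the same loaded matrix.
"""

from __future__ import annotations

import numpy as np

from .datatypes import DegenerateInputError, ExpressionMatrix

__all__ = ["standardize_samples", "make_nonnegative"]


def standardize_samples(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale every sample to mean 0, SD 1 (n-1 denominator).

    Raises :class:`DegenerateInputError` naming the first constant sample,
    since a zero-variance profile cannot be scaled.
    """
    m = matrix.as_genes_by_samples()
    values = m.values
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    zero = np.where(sds == 0)[0]
    if zero.size:
        raise DegenerateInputError(
            f"sample {m.sample_ids[zero[0]]!r} is constant; cannot standardize"
        )
    out = (values - means) / sds
    return m.with_values(out)


def make_nonnegative(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Shift each gene row containing a negative up by -min(row).

    An already-nonnegative matrix is returned unchanged (same values,
    bitwise). The per-gene shift preserves within-gene differences exactly,
    which is what metagene loadings summarize.
    """
    m = matrix.as_genes_by_samples()
    mins = m.values.min(axis=1, keepdims=True)
    if (mins >= 0).all():
        return m
    shift = np.maximum(0.0, -mins)
    return m.with_values(m.values + shift)
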