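import numpy as np
import pytest

from genefactor import (
    ExpressionMatrix,
    PhenotypeLabels,
    default_labels,
)


@pytest.fixture
def labels13() -> PhenotypeLabels:
    """The default 5-disease / 8-control two-group design."""
    return default_labels()


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    return ExpressionMatrix(
        values=rng.normal(size=(20, 6)),
        gene_ids=tuple(f"g{i}" for i in range(20)),
        sample_ids=tuple(f"s{j}" for j in range(6)),
    )


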