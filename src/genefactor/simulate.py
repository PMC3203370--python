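"""Synthetic expression matrices with planted latent structure.

Two generators mirror the two factorization tracks:

``simulate_ica_dataset``
    Plants statistically independent, heavy-tailed expression modes: each
    mode is a standard-normal background over genes with a sparse subset of
    genes spiked to ``|signal_z|`` (the planted "significant genes"). Samples
    are linear mixtures of the modes plus Gaussian noise. One designated
    mode's mixing weights have constant magnitude and opposite signs in the
    two phenotype groups, so that mode is phenotype-discriminating by
    construction.

``simulate_nmf_dataset``
    Plants nonnegative metagenes: disjoint gene modules with high loadings
    against a low background, and an encoding matrix giving each phenotype
    group elevated weight on its own metagene. Noise is zero-truncated
    Gaussian so the output stays nonnegative.

The default study shape follows the motivating microarray design: 6398 genes
over 13 samples split 5 disease / 8 control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    ExpressionMatrix,
    Orientation,
    ParameterError,
    PhenotypeLabels,
)

__all__ = ["PlantedTruth", "default_labels", "simulate_ica_dataset",
           "simulate_nmf_dataset"]

DEFAULT_N_GENES = 6398


def default_labels(n_disease: int = 5, n_control: int = 8,
                   disease: str = "AD", control: str = "control") -> PhenotypeLabels:
    """Phenotype labels for the default 5 + 8 two-group design.

    The disease group comes first so downstream up/down orientation treats
    it as the group of interest.
    """
    assignments = {f"{disease}_{i + 1}": disease for i in range(n_disease)}
    assignments.update({f"{control}_{i + 1}": control for i in range(n_control)})
    return PhenotypeLabels(assignments=assignments, groups=(disease, control))


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth record emitted alongside a simulated matrix.

    ``mode_matrix`` (n_modes x n_genes) and ``mixing_matrix``
    (m_samples x n_modes) hold the planted linear model for the ICA track;
    ``metagene_modules`` holds the planted module gene sets for the NMF
    track (empty for ICA simulations, and vice versa).
    """

    mode_matrix: np.ndarray
    mixing_matrix: np.ndarray
    significant_gene_sets: tuple[dict[str, str], ...]  # per mode: gene_id -> up/down
    phenotype_mode_index: int
    metagene_modules: tuple[frozenset[str], ...] = ()
    encoding_matrix: np.ndarray | None = None

    def significant_ids(self, mode: int) -> frozenset[str]:
        return frozenset(self.significant_gene_sets[mode])


def _ordered_samples(labels: PhenotypeLabels) -> list[str]:
    return list(labels.sample_ids)


def simulate_ica_dataset(
    n_genes: int,
    labels: PhenotypeLabels,
    n_modes: int,
    frac_significant: float = 0.02,
    signal_z: float = 4.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Simulate an expression matrix with planted independent modes.

    Each mode's significant genes are disjoint from those of every other
    mode, which keeps sensitivity/false-positive bookkeeping unambiguous.
    Generation is a pure function of the arguments and ``seed``.
    """
    samples = _ordered_samples(labels)
    m = len(samples)
    if n_modes > m:
        raise ParameterError(f"n_modes={n_modes} exceeds sample count {m}")
    if not 0.0 < frac_significant < 1.0:
        raise ParameterError("frac_significant must be in (0, 1)")
    n_sig = max(1, int(round(frac_significant * n_genes)))
    if n_modes * n_sig > n_genes:
        raise ParameterError(
            f"cannot plant {n_modes} disjoint sets of {n_sig} significant genes "
            f"in {n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    gene_ids = tuple(f"g{i + 1}" for i in range(n_genes))

    # Sparse super-Gaussian modes: normal background plus +/- signal_z spikes.
    modes = rng.standard_normal((n_modes, n_genes))
    sig_pool = rng.permutation(n_genes)[: n_modes * n_sig]
    significant_sets: list[dict[str, str]] = []
    for r in range(n_modes):
        idx = sig_pool[r * n_sig : (r + 1) * n_sig]
        signs = rng.choice([-1.0, 1.0], size=n_sig)
        modes[r, idx] = signs * signal_z
        significant_sets.append(
            {gene_ids[i]: ("up" if s > 0 else "down") for i, s in zip(idx, signs)}
        )

    mixing = rng.standard_normal((m, n_modes))
    phenotype_mode = 0
    group0 = labels.mask(samples, labels.groups[0])
    mixing[:, phenotype_mode] = np.where(group0, 1.0, -1.0)

    data_t = mixing @ modes  # samples x genes
    if noise_sd > 0:
        data_t = data_t + rng.normal(0.0, noise_sd, size=data_t.shape)

    matrix = ExpressionMatrix(
        values=data_t.T,
        gene_ids=gene_ids,
        sample_ids=tuple(samples),
        orientation=Orientation.GENES_BY_SAMPLES,
    )
    truth = PlantedTruth(
        mode_matrix=modes,
        mixing_matrix=mixing,
        significant_gene_sets=tuple(significant_sets),
        phenotype_mode_index=phenotype_mode,
    )
    return matrix, truth


def simulate_nmf_dataset(
    n_genes: int,
    labels: PhenotypeLabels,
    k: int = 2,
    module_size: int = 50,
    load_high: float = 1.0,
    load_low: float = 0.05,
    noise_sd: float = 0.5,
    seed: int = 0,
    encoding_high: float = 10.0,
    encoding_low: float = 2.0,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Simulate a nonnegative matrix with planted metagene modules.

    The planted model is ``V = W_true H_true + max(0, noise)``: ``W_true``
    holds ``k`` disjoint modules of ``module_size`` genes at loading
    ``load_high`` over a ``load_low`` background; each phenotype group gets
    encoding weight ``encoding_high`` on its own metagene (groups are
    assigned to metagenes cyclically when ``k > 2``).
    """
    samples = _ordered_samples(labels)
    m = len(samples)
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k * module_size > n_genes:
        raise ParameterError(
            f"k*module_size = {k * module_size} exceeds n_genes = {n_genes}; "
            "disjoint modules are impossible"
        )
    if load_low < 0 or load_high <= 0:
        raise ParameterError("loadings must be nonnegative with load_high > 0")
    rng = np.random.default_rng(seed)
    gene_ids = tuple(f"g{i + 1}" for i in range(n_genes))

    module_pool = rng.permutation(n_genes)[: k * module_size]
    w_true = np.full((n_genes, k), load_low, dtype=float)
    modules: list[frozenset[str]] = []
    for j in range(k):
        idx = module_pool[j * module_size : (j + 1) * module_size]
        w_true[idx, j] = load_high
        modules.append(frozenset(gene_ids[i] for i in idx))

    group_index = {g: i for i, g in enumerate(labels.groups)}
    h_true = np.full((k, m), encoding_low, dtype=float)
    for s, sample in enumerate(samples):
        h_true[group_index[labels.group_of(sample)] % k, s] = encoding_high

    data = w_true @ h_true
    if noise_sd > 0:
        data = data + np.maximum(0.0, rng.normal(0.0, noise_sd, size=data.shape))

    matrix = ExpressionMatrix(
        values=data,
        gene_ids=gene_ids,
        sample_ids=tuple(samples),
        orientation=Orientation.GENES_BY_SAMPLES,
    )
    truth = PlantedTruth(
        mode_matrix=w_true.T,
        mixing_matrix=h_true.T,
        significant_gene_sets=tuple({} for _ in range(k)),
        phenotype_mode_index=0,
        metagene_modules=tuple(modules),
        encoding_matrix=h_true,
    )
    return matrix, truth
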