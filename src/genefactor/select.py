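"""Turning factorizations into gene lists, sample classes and biclusters.

This stage formalizes how a discriminating latent component is picked and
how its significant genes are read off:

* a mixing-matrix column discriminates the two phenotype groups when its
  entries differ in sign and magnitude between groups — scored here by a
  Welch two-sample t statistic plus a sign-separation fraction;
* genes load a component significantly when their standardized loading
  exceeds a |z| threshold (default 2.5), with sign giving up/down
  regulation once the component is oriented toward the phenotype group of
  interest;
* nsNMF metagenes are nonnegative, so selection there is one-sided on the
  standardized loading and up/down is resolved from raw group means;
* sorting genes by a metagene and samples by its encoding vector collects
  the co-regulated block at the matrix extremes (factor biclustering).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, ParameterError, PhenotypeLabels
from .ica import ICAResult
from .nsnmf import NsNMFResult

__all__ = [
    "ComponentScore",
    "GENE_TABLE_COLUMNS",
    "empty_gene_table",
    "score_components",
    "select_discriminating_components",
    "select_genes_ica",
    "select_genes_nmf",
    "classify_samples",
    "bicluster_sort",
    "integrate_gene_sets",
]

GENE_TABLE_COLUMNS = ("gene_id", "method", "component", "loading", "zscore",
                      "direction")


def empty_gene_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        GENE_TABLE_COLUMNS, (str, str, int, float, float, str))})


@dataclass(frozen=True)
class ComponentScore:
    """Discrimination score of one mixing-matrix column.

    ``sign_separation`` is the best achievable fraction of samples whose
    entry sign matches a single sign assigned to their group (1.0 means the
    column sign-separates the groups perfectly); ``t_statistic`` is the
    Welch two-sample statistic between the group entries. ``rank`` 1 is the
    most discriminating component.
    """

    component: int
    sign_separation: float
    t_statistic: float
    rank: int = 0


def _group_masks(
    sample_ids: tuple[str, ...], labels: PhenotypeLabels
) -> tuple[np.ndarray, np.ndarray]:
    m0 = labels.mask(sample_ids, labels.groups[0])
    m1 = labels.mask(sample_ids, labels.groups[1])
    for g, mk in zip(labels.groups, (m0, m1)):
        if mk.sum() < 2:
            raise ParameterError(f"group {g!r} has < 2 samples among the data")
    return m0, m1


def score_components(
    mixing: np.ndarray,
    labels: PhenotypeLabels,
    sample_ids: tuple[str, ...] | None = None,
) -> list[ComponentScore]:
    """Score every mixing column for phenotype discrimination.

    Components are ranked by |t| (descending); ties break by higher
    sign-separation, then by lower component index. Rows of ``mixing``
    must align with ``sample_ids`` (defaults to the labels' own order).
    """
    mixing = np.asarray(mixing, dtype=float)
    if sample_ids is None:
        sample_ids = labels.sample_ids
    if mixing.shape[0] != len(sample_ids):
        raise ParameterError(
            f"mixing has {mixing.shape[0]} rows but {len(sample_ids)} samples"
        )
    m0, m1 = _group_masks(tuple(sample_ids), labels)
    scores: list[ComponentScore] = []
    for j in range(mixing.shape[1]):
        col = mixing[:, j]
        a, b = col[m0], col[m1]
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = stats.ttest_ind(a, b, equal_var=False).statistic
        if np.isnan(t_stat):
            t_stat = 0.0  # identical zero-variance groups carry no signal
        # +/-inf (zero within-group variance, different means) is kept:
        # perfect separation is maximal discrimination and must rank first.
        # Best over the two ways of assigning +/- to the groups; zero
        # entries match neither sign.
        match_a = (np.sign(a) == 1).sum() + (np.sign(b) == -1).sum()
        match_b = (np.sign(a) == -1).sum() + (np.sign(b) == 1).sum()
        sep = max(match_a, match_b) / col.size
        scores.append(
            ComponentScore(component=j, sign_separation=float(sep),
                           t_statistic=float(t_stat))
        )
    order = sorted(
        range(len(scores)),
        key=lambda j: (-abs(scores[j].t_statistic),
                       -scores[j].sign_separation, j),
    )
    ranked = [None] * len(scores)
    for rank_pos, j in enumerate(order, start=1):
        s = scores[j]
        ranked[j] = ComponentScore(
            component=s.component,
            sign_separation=s.sign_separation,
            t_statistic=s.t_statistic,
            rank=rank_pos,
        )
    return ranked  # type: ignore[return-value]


def select_discriminating_components(scores: list[ComponentScore]) -> list[int]:
    """All components with perfect sign-separation, else the top-ranked one."""
    perfect = [s.component for s in scores if s.sign_separation == 1.0]
    if perfect:
        return sorted(perfect)
    return [next(s.component for s in scores if s.rank == 1)]


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def select_genes_ica(
    result: ICAResult,
    components: list[int],
    threshold: float,
    labels: PhenotypeLabels | None = None,
) -> pd.DataFrame:
    """Significant genes of the chosen expression modes at a |z| threshold.

    Each mode's loadings are standardized across genes; genes with
    ``|z| >= threshold`` (inclusive) are emitted. When labels are given the
    mode is first oriented so the group of interest (``labels.groups[0]``)
    has positive mean mixing weight, making ``z > 0`` mean up-regulated in
    that group regardless of ICA's sign indeterminacy.
    """
    if not components:
        raise ParameterError("component list is empty")
    n_comp = result.n_components
    rows = []
    for comp in components:
        if not 0 <= comp < n_comp:
            raise ParameterError(f"component {comp} out of range [0, {n_comp})")
        orient = 1.0
        if labels is not None:
            m0 = labels.mask(result.sample_ids, labels.groups[0])
            mean_w = result.mixing[m0, comp].mean()
            orient = -1.0 if mean_w < 0 else 1.0
        loadings = orient * result.sources[comp]
        z = _zscore(loadings)
        for idx in np.where(np.abs(z) >= threshold)[0]:
            rows.append(
                {
                    "gene_id": result.gene_ids[idx] if result.gene_ids else str(idx),
                    "method": "ica",
                    "component": comp,
                    "loading": float(loadings[idx]),
                    "zscore": float(z[idx]),
                    "direction": "up" if z[idx] > 0 else "down",
                }
            )
    if not rows:
        return empty_gene_table()
    return pd.DataFrame(rows, columns=list(GENE_TABLE_COLUMNS))


def select_genes_nmf(
    result: NsNMFResult,
    z_threshold: float,
    data: ExpressionMatrix,
    labels: PhenotypeLabels,
) -> pd.DataFrame:
    """Significant genes of each metagene at a one-sided z threshold.

    W is nonnegative, so only unusually large loadings are informative:
    genes with standardized loading ``z >= z_threshold`` are selected.
    Direction comes from the raw data: up if the gene's mean expression in
    the group of interest (``labels.groups[0]``) strictly exceeds the other
    group's, down otherwise (ties resolve to down).
    """
    em = data.as_genes_by_samples()
    if result.gene_ids and tuple(result.gene_ids) != tuple(em.gene_ids):
        raise ParameterError("metagene gene order does not match the data")
    m0, m1 = _group_masks(em.sample_ids, labels)
    mean0 = em.values[:, m0].mean(axis=1)
    mean1 = em.values[:, m1].mean(axis=1)
    rows = []
    for j in range(result.k):
        w = result.metagenes[:, j]
        z = _zscore(w)
        for idx in np.where(z >= z_threshold)[0]:
            rows.append(
                {
                    "gene_id": em.gene_ids[idx],
                    "method": "nmf",
                    "component": j,
                    "loading": float(w[idx]),
                    "zscore": float(z[idx]),
                    "direction": "up" if mean0[idx] > mean1[idx] else "down",
                }
            )
    if not rows:
        return empty_gene_table()
    return pd.DataFrame(rows, columns=list(GENE_TABLE_COLUMNS))


def classify_samples(h: np.ndarray) -> list[int]:
    """Assign each sample to its most highly expressed metagene.

    Ties go to the lowest metagene index (argmax convention).
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ParameterError("encoding matrix must be nonnegative")
    return [int(j) for j in np.argmax(h, axis=0)]


def bicluster_sort(
    data: ExpressionMatrix, result: NsNMFResult, factor: int
) -> tuple[np.ndarray, np.ndarray]:
    """Gene and sample orders sorting ``data`` by one nsNMF factor.

    Genes are ordered by descending metagene loading ``W[:, factor]`` and
    samples by descending encoding weight ``H[factor, :]``; ties keep the
    original index order. Pure reordering — apply the returned index arrays
    to view the bicluster, no values are changed.
    """
    if not 0 <= factor < result.k:
        raise ParameterError(f"factor {factor} out of range [0, {result.k})")
    em = data.as_genes_by_samples()
    if result.metagenes.shape[0] != em.n_genes:
        raise ParameterError("metagene rows do not match the data's genes")
    row_order = np.argsort(-result.metagenes[:, factor], kind="stable")
    col_order = np.argsort(-result.encodings[factor, :], kind="stable")
    return row_order, col_order


def integrate_gene_sets(
    ica_table: pd.DataFrame, nmf_table: pd.DataFrame
) -> dict:
    """Overlap report between the ICA and NMF significant-gene lists.

    Returns per-method gene sets, their intersection/union, the Jaccard
    index, and per-gene provenance with any up/down conflicts flagged
    (a gene called up by one method and down by the other, in any of its
    component-level calls).
    """
    def _directions(table: pd.DataFrame) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for _, row in table.iterrows():
            out.setdefault(str(row["gene_id"]), set()).add(str(row["direction"]))
        return out

    ica_dirs = _directions(ica_table)
    nmf_dirs = _directions(nmf_table)
    ica_genes = set(ica_dirs)
    nmf_genes = set(nmf_dirs)
    union = ica_genes | nmf_genes
    inter = ica_genes & nmf_genes
    genes = []
    for g in sorted(union):
        dirs = ica_dirs.get(g, set()) | nmf_dirs.get(g, set())
        genes.append(
            {
                "gene_id": g,
                "provenance": (
                    "both" if g in inter else ("ica-only" if g in ica_genes
                                               else "nmf-only")
                ),
                "directions": sorted(dirs),
                "direction_conflict": len(dirs) > 1,
            }
        )
    return {
        "ica_genes": sorted(ica_genes),
        "nmf_genes": sorted(nmf_genes),
        "intersection": sorted(inter),
        "union": sorted(union),
        "jaccard": (len(inter) / len(union)) if union else 0.0,
        "genes": genes,
    }
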