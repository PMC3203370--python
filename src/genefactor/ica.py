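"""From-scratch FastICA with multi-restart consensus.

The model is ``X^T = A S``: the samples-by-genes matrix is a linear mixture
of statistically independent expression modes (rows of ``S``, one profile
over all genes each), with the mixing matrix ``A`` holding the weight of
each mode in each sample profile. Estimation is the classic fixed-point
scheme: whiten the sample profiles, then iterate the tanh-contrast update
with symmetric decorrelation so all components are estimated in parallel.

FastICA converges to local optima that depend on the random start, so
:func:`fastica_consensus` pools many restarts: components are matched
across runs by absolute correlation and each component gets a stability
score (mean |r| to its matched partners), in the spirit of Icasso.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import (
    ConvergenceError,
    DegenerateInputError,
    ExpressionMatrix,
)
from .io import RunConfig

__all__ = [
    "WhiteningRecord",
    "FastICARun",
    "ICAResult",
    "whiten",
    "fastica_once",
    "fastica_consensus",
    "greedy_match",
]

_RANK_RTOL = 1e-10  # singular values below this fraction of the max are dropped


@dataclass(frozen=True)
class WhiteningRecord:
    """Everything needed to undo the whitening transform.

    ``whitener`` maps centered data to whitened space (c x m);
    ``dewhitener`` (m x c) maps back; ``row_means`` restores centering.
    """

    row_means: np.ndarray
    whitener: np.ndarray
    dewhitener: np.ndarray
    rank: int


@dataclass(frozen=True)
class FastICARun:
    unmixing: np.ndarray  # c x c, orthonormal in whitened space
    sources: np.ndarray  # c x n
    converged: bool
    n_iter: int
    seed: int


@dataclass(frozen=True)
class ICAResult:
    """Consensus decomposition of a samples-by-genes matrix.

    ``mixing @ sources`` reconstructs the row-centered input up to rank
    truncation. Source rows have unit sample variance and nonnegative
    skewness (the sign convention fixing ICA's up/down indeterminacy).
    """

    mixing: np.ndarray  # m x c
    sources: np.ndarray  # c x n
    whitening: WhiteningRecord | None
    stability: np.ndarray  # per component, in [0, 1]
    restart_count: int
    converged_count: int
    objective: np.ndarray  # negentropy proxy per component
    gene_ids: tuple[str, ...] = ()
    sample_ids: tuple[str, ...] = ()

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]


def whiten(data: np.ndarray) -> tuple[np.ndarray, WhiteningRecord]:
    """Whiten sample profiles (rows) to zero mean and identity covariance.

    Uses the eigendecomposition of the (n-1)-denominator row covariance.
    Rank-deficient input is reduced to its numerical rank with a warning;
    a zero-variance row is rejected outright.
    """
    data = np.asarray(data, dtype=float)
    m, n = data.shape
    if m < 1 or n < 2:
        raise DegenerateInputError("need at least 1 row and 2 columns to whiten")
    row_means = data.mean(axis=1)
    centered = data - row_means[:, None]
    row_sds = centered.std(axis=1, ddof=1)
    if np.any(row_sds == 0):
        bad = int(np.where(row_sds == 0)[0][0])
        raise DegenerateInputError(f"sample row {bad} has zero variance")
    cov = centered @ centered.T / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    sv = np.sqrt(np.maximum(eigvals, 0.0))
    keep = sv > _RANK_RTOL * sv[0]
    rank = int(keep.sum())
    if rank < m:
        warnings.warn(
            f"rank-deficient covariance: retaining {rank} of {m} components",
            stacklevel=2,
        )
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    whitener = (eigvecs / np.sqrt(eigvals)).T  # c x m
    dewhitener = eigvecs * np.sqrt(eigvals)  # m x c
    whitened = whitener @ centered
    record = WhiteningRecord(
        row_means=row_means, whitener=whitener, dewhitener=dewhitener, rank=rank
    )
    return whitened, record


def _sym_decorrelate(w: np.ndarray) -> np.ndarray:
    """W <- (W W^T)^{-1/2} W, the symmetric orthogonalization step."""
    s, u = np.linalg.eigh(w @ w.T)
    s = np.maximum(s, np.finfo(float).eps)
    return (u / np.sqrt(s)) @ u.T @ w


def fastica_once(
    whitened: np.ndarray,
    a1: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
    stall_patience: int = 100,
) -> FastICARun:
    """One symmetric fixed-point FastICA run on whitened data.

    The contrast derivative is ``g(u) = tanh(a1 * u)``. Convergence is
    declared when every component direction is unchanged up to sign:
    ``max_i |1 - |<w_i_new, w_i_old>|| < tol``. Hitting ``max_iter`` returns
    the best approximate fixed point seen, flagged as non-converged; the
    loop also stops early once the fixed-point residual has not improved by
    at least 5% for ``stall_patience`` consecutive iterations, since
    near-Gaussian dimensions cycle indefinitely without approaching tol.
    """
    z = np.asarray(whitened, dtype=float)
    c, n = z.shape
    rng = np.random.default_rng(seed)
    w = _sym_decorrelate(rng.standard_normal((c, c)))
    converged = False
    it = 0
    best_w, best_delta = w, np.inf
    stall = 0
    for it in range(1, max_iter + 1):
        u = w @ z
        gu = np.tanh(a1 * u)
        g_prime_mean = a1 * (1.0 - gu**2).mean(axis=1)
        w_new = (gu @ z.T) / n - g_prime_mean[:, None] * w
        w_new = _sym_decorrelate(w_new)
        delta = np.max(np.abs(1.0 - np.abs(np.sum(w_new * w, axis=1))))
        w = w_new
        if delta < 0.95 * best_delta:
            stall = 0
        else:
            stall += 1
        if delta < best_delta:
            # Near-Gaussian dimensions can cycle without ever meeting tol;
            # keep the best approximate fixed point encountered.
            best_w, best_delta = w, delta
        if delta < tol:
            converged = True
            break
        if stall >= stall_patience:
            break
    w = best_w
    return FastICARun(
        unmixing=w, sources=w @ z, converged=converged, n_iter=it, seed=seed
    )


def greedy_match(corr_abs: np.ndarray) -> list[tuple[int, int, float]]:
    """Greedy one-to-one pairing maximizing absolute correlation.

    Repeatedly takes the largest remaining entry of ``corr_abs`` and
    assigns that (row, column) pair. Returns (row, col, |r|) triples.
    """
    c = np.array(corr_abs, dtype=float, copy=True)
    pairs: list[tuple[int, int, float]] = []
    for _ in range(min(c.shape)):
        i, j = np.unravel_index(np.argmax(c), c.shape)
        pairs.append((int(i), int(j), float(c[i, j])))
        c[i, :] = -np.inf
        c[:, j] = -np.inf
    return pairs


def _row_corr_abs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|Pearson r| between every row of ``a`` and every row of ``b``."""
    az = (a - a.mean(axis=1, keepdims=True))
    bz = (b - b.mean(axis=1, keepdims=True))
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    bz /= np.linalg.norm(bz, axis=1, keepdims=True)
    return np.abs(az @ bz.T)


def _negentropy_proxy(sources: np.ndarray, a1: float) -> np.ndarray:
    """Squared deviation of E[log cosh(a1 u)]/a1 from its Gaussian value."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    gauss = float(
        (np.log(np.cosh(a1 * nodes)) @ weights) / (a1 * np.sqrt(2 * np.pi))
    )
    per_comp = np.log(np.cosh(a1 * sources)).mean(axis=1) / a1
    return (per_comp - gauss) ** 2


def fastica_consensus(
    data: ExpressionMatrix | np.ndarray, config: RunConfig
) -> ICAResult:
    """Multi-restart FastICA with stability scoring.

    Runs ``config.ica_n_restarts`` seeded restarts, keeps the converged
    ones, and scores every component of every converged run by its mean
    absolute correlation to greedy-matched partners in the other runs. The
    run whose components are most stable on average is returned, with the
    mixing matrix mapped back through the whitening record, source rows
    scaled to unit variance, and signs fixed to nonnegative skewness.
    """
    if isinstance(data, ExpressionMatrix):
        em = data.as_samples_by_genes()
        x = em.values
        gene_ids, sample_ids = em.gene_ids, em.sample_ids
    else:
        x = np.asarray(data, dtype=float)
        gene_ids, sample_ids = (), ()

    whitened, record = whiten(x)
    runs = [
        fastica_once(
            whitened,
            a1=config.a1,
            tol=config.ica_tol,
            max_iter=config.ica_max_iter,
            seed=config.restart_seed(r),
        )
        for r in range(config.ica_n_restarts)
    ]
    converged = [r for r in runs if r.converged]
    if not converged:
        # Strict fixed-point convergence is unattainable whenever some
        # retained dimensions are near-Gaussian (the expected regime when
        # the sample count exceeds the number of truly non-Gaussian modes).
        # The restart consensus exists to stabilize exactly this case, so
        # pool the best approximate fixed points of all restarts instead.
        warnings.warn(
            f"no FastICA restart met tol={config.ica_tol} within "
            f"{config.ica_max_iter} iterations; pooling all "
            f"{len(runs)} non-converged restarts into the consensus",
            RuntimeWarning,
            stacklevel=2,
        )
        converged = runs
    if not converged:
        raise ConvergenceError("no FastICA restarts were run")

    n_runs = len(converged)
    c = converged[0].sources.shape[0]
    if n_runs == 1:
        best_idx = 0
        stability = np.ones(c)
    else:
        # Pairwise component matching across all converged runs.
        stacked = np.vstack([r.sources for r in converged])
        corr = _row_corr_abs(stacked, stacked)
        per_comp = np.zeros((n_runs, c))
        for a in range(n_runs):
            for b in range(a + 1, n_runs):
                block = corr[a * c : (a + 1) * c, b * c : (b + 1) * c]
                for i, j, r_abs in greedy_match(block):
                    per_comp[a, i] += r_abs
                    per_comp[b, j] += r_abs
        per_comp /= n_runs - 1
        best_idx = int(np.argmax(per_comp.mean(axis=1)))
        stability = per_comp[best_idx]

    best = converged[best_idx]
    sources = best.sources.copy()
    mixing = record.dewhitener @ best.unmixing.T  # m x c

    # Unit-variance source rows; scale absorbed into the mixing columns.
    sds = sources.std(axis=1, ddof=1)
    sources /= sds[:, None]
    mixing *= sds[None, :]

    # Sign convention: every mode has nonnegative skewness.
    skews = stats.skew(sources, axis=1, bias=False)
    flip = np.where(skews < 0, -1.0, 1.0)
    sources *= flip[:, None]
    mixing *= flip[None, :]

    return ICAResult(
        mixing=mixing,
        sources=sources,
        whitening=record,
        stability=stability,
        restart_count=config.ica_n_restarts,
        converged_count=n_runs,
        objective=_negentropy_proxy(sources, config.a1),
        gene_ids=gene_ids,
        sample_ids=sample_ids,
    )
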