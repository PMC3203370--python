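"""From-scratch non-smooth NMF (nsNMF) with multiplicative KL updates.

Classical NMF approximates a nonnegative genes-by-samples matrix as
``V ~ W H`` with ``W`` (n x k) holding nonnegative metagenes and ``H``
(k x m) the encoding vectors that weight each metagene in each sample.
nsNMF interposes a smoothing matrix: ``V ~ W S_theta H`` with

    S_theta = (1 - theta) I + (theta / k) 11^T,   0 <= theta <= 1.

At theta = 0 this is classical NMF; as theta -> 1, ``S_theta x`` tends to
the constant mean vector of ``x``. Because the smoothing soaks up the
non-sparse part of the representation, the multiplicative updates push
sparseness onto both ``W`` and ``H`` — the mechanism that makes metagenes
concentrate on small gene modules.

Updates are the Lee–Seung divergence-form multiplicative rules, applied
with the smoothed partner: ``W`` is replaced by ``W S`` when updating ``H``
and ``H`` by ``S H`` when updating ``W``, so each half-step monotonically
decreases the generalized Kullback–Leibler divergence D(V || W S H).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import ExpressionMatrix, ParameterError
from .io import RunConfig

__all__ = [
    "SmoothingMatrix",
    "NsNMFResult",
    "smoothing_matrix",
    "nsnmf_once",
    "nsnmf_multistart",
    "hoyer_sparseness",
    "kl_divergence",
]


@dataclass(frozen=True)
class SmoothingMatrix:
    theta: float
    k: int
    values: np.ndarray  # k x k

    def __matmul__(self, other: np.ndarray) -> np.ndarray:
        return self.values @ other


@dataclass(frozen=True)
class NsNMFResult:
    """One nsNMF fit: ``metagenes @ smoothing @ encodings`` approximates V.

    ``objective_trace[i]`` is D(V || W S H) after iteration ``i``;
    ``sparseness`` holds the Hoyer sparseness of each W column and each H
    row (W entries first).
    """

    metagenes: np.ndarray  # W, n x k
    encodings: np.ndarray  # H, k x m
    theta: float
    objective_trace: np.ndarray
    restart_id: int
    seed: int
    converged: bool
    sparseness: np.ndarray
    restart_objectives: np.ndarray | None = None
    gene_ids: tuple[str, ...] = ()
    sample_ids: tuple[str, ...] = ()

    @property
    def k(self) -> int:
        return self.metagenes.shape[1]

    @property
    def final_objective(self) -> float:
        return float(self.objective_trace[-1])

    def smoothing(self) -> SmoothingMatrix:
        return smoothing_matrix(self.k, self.theta)


def smoothing_matrix(k: int, theta: float) -> SmoothingMatrix:
    """Build S_theta = (1 - theta) I + (theta / k) 11^T, elementwise exact."""
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if not 0.0 <= theta <= 1.0:
        raise ParameterError(f"theta must be in [0, 1], got {theta}")
    values = (1.0 - theta) * np.eye(k) + (theta / k) * np.ones((k, k))
    return SmoothingMatrix(theta=float(theta), k=int(k), values=values)


def kl_divergence(v: np.ndarray, approx: np.ndarray) -> float:
    """Generalized KL divergence D(v || approx), with 0 log 0 = 0."""
    approx = np.maximum(approx, np.finfo(float).tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.where(v > 0, v * np.log(np.where(v > 0, v, 1.0) / approx), 0.0)
    return float(np.sum(log_term - v + approx))


def nsnmf_once(
    v: np.ndarray | ExpressionMatrix,
    k: int,
    theta: float = 0.5,
    n_iter: int = 2000,
    epsilon_floor: float = 1e-9,
    seed: int = 0,
    rel_tol: float | None = None,
    restart_id: int = 0,
) -> NsNMFResult:
    """One seeded nsNMF fit with a fixed multiplicative-update budget.

    ``W`` and ``H`` are initialized from a uniform(epsilon_floor, 1] draw.
    Every update floors the factors at ``epsilon_floor`` so the
    multiplicative rules cannot absorb exact zeros. The KL objective is
    recorded after every full iteration; when ``rel_tol`` is given, the loop
    stops early once the relative objective decrease falls below it.

    Columns of ``W`` are rescaled to unit l1 norm at the end of the fit
    (scale absorbed into ``H``) so loadings are comparable across
    metagenes; rescaling mid-fit would alter ``W S H`` for theta > 0 and
    break the monotone objective guarantee.
    """
    if isinstance(v, ExpressionMatrix):
        em = v.as_genes_by_samples()
        gene_ids, sample_ids = em.gene_ids, em.sample_ids
        v = em.values
    else:
        v = np.asarray(v, dtype=float)
        gene_ids, sample_ids = (), ()
    n, m = v.shape
    if np.any(v < 0):
        raise ParameterError("V must be nonnegative")
    if not 1 <= k <= min(n, m):
        raise ParameterError(f"k must be in [1, min(n, m)] = [1, {min(n, m)}]")
    zero_rows = ~v.any(axis=1)
    zero_cols = ~v.any(axis=0)
    if zero_rows.any() or zero_cols.any():
        warnings.warn(
            f"{int(zero_rows.sum())} all-zero rows and {int(zero_cols.sum())} "
            "all-zero columns in V; their factor entries stay at the floor",
            stacklevel=2,
        )

    s = smoothing_matrix(k, theta).values
    rng = np.random.default_rng(seed)
    w = epsilon_floor + (1.0 - epsilon_floor) * rng.random((n, k))
    h = epsilon_floor + (1.0 - epsilon_floor) * rng.random((k, m))

    tiny = np.finfo(float).tiny
    trace = np.empty(n_iter)
    converged = rel_tol is None
    last = np.inf
    used = 0
    for it in range(n_iter):
        # H-step with the smoothed basis W S fixed.
        ws = w @ s
        ratio = v / np.maximum(ws @ h, tiny)
        h *= (ws.T @ ratio) / np.maximum(ws.sum(axis=0)[:, None], tiny)
        h = np.maximum(h, epsilon_floor)
        # W-step with the smoothed encoding S H fixed.
        sh = s @ h
        ratio = v / np.maximum(w @ sh, tiny)
        w *= (ratio @ sh.T) / np.maximum(sh.sum(axis=1)[None, :], tiny)
        w = np.maximum(w, epsilon_floor)

        obj = kl_divergence(v, w @ s @ h)
        trace[it] = obj
        used = it + 1
        if rel_tol is not None and last < np.inf:
            if abs(last - obj) <= rel_tol * max(abs(last), 1.0):
                converged = True
                break
        last = obj
    trace = trace[:used]

    # Final normalization: unit-l1 metagene columns, scale pushed into H.
    scale = w.sum(axis=0)
    w = w / scale[None, :]
    h = h * scale[:, None]

    spars = np.concatenate(
        [
            [hoyer_sparseness(w[:, j]) for j in range(k)],
            [hoyer_sparseness(h[j, :]) for j in range(k)],
        ]
    )
    return NsNMFResult(
        metagenes=w,
        encodings=h,
        theta=float(theta),
        objective_trace=trace,
        restart_id=restart_id,
        seed=seed,
        converged=converged,
        sparseness=spars,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
    )


def nsnmf_multistart(
    v: np.ndarray | ExpressionMatrix, config: RunConfig
) -> NsNMFResult:
    """Best-of-``config.nsnmf_n_restarts`` nsNMF by final KL objective.

    Restart seeds are derived from ``config.seed`` by fixed increments, so
    any single restart is reproducible in isolation and extending the
    restart count can only improve (never worsen) the returned objective.
    """
    results = [
        nsnmf_once(
            v,
            k=config.k,
            theta=config.theta,
            n_iter=config.nsnmf_n_iter,
            epsilon_floor=config.epsilon_floor,
            seed=config.restart_seed(r),
            restart_id=r,
        )
        for r in range(config.nsnmf_n_restarts)
    ]
    finals = np.array([r.final_objective for r in results])
    best = results[int(np.argmin(finals))]
    return NsNMFResult(
        metagenes=best.metagenes,
        encodings=best.encodings,
        theta=best.theta,
        objective_trace=best.objective_trace,
        restart_id=best.restart_id,
        seed=best.seed,
        converged=best.converged,
        sparseness=best.sparseness,
        restart_objectives=finals,
        gene_ids=best.gene_ids,
        sample_ids=best.sample_ids,
    )


def hoyer_sparseness(v: np.ndarray) -> float:
    """Hoyer's scale-free sparseness of a nonnegative vector, in [0, 1].

    ``(sqrt(d) - ||v||_1 / ||v||_2) / (sqrt(d) - 1)`` for length ``d``:
    0 for a constant vector, 1 for a one-hot vector.
    """
    v = np.asarray(v, dtype=float).ravel()
    l2 = np.linalg.norm(v)
    if l2 == 0:
        raise ParameterError("sparseness of the zero vector is undefined")
    d = v.size
    if d == 1:
        return 1.0
    sqrt_d = np.sqrt(d)
    return float((sqrt_d - np.abs(v).sum() / l2) / (sqrt_d - 1.0))
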