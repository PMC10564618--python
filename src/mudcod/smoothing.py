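"""Cross-subject, cross-time eigenvector smoothing — the method core.

For each subject s and time t let ``U_{s,t}`` be the projection onto the
K leading eigenvectors of the degree-normalized Laplacian.  The smoothed
projections minimize

    sum_{s,t} ||U_{s,t} - Ubar_{s,t}||_F^2
        + beta  * sum_{s,t} ||Ubar_{s,t} - mu_s(Ubar_{:,t})||_F^2
        + alpha * sum_{s,t<T} ||Ubar_{s,t} - Ubar_{s,t+1}||_F^2

over rank-K projection matrices, where ``mu_s`` is the mean projection
of the other subjects at time t.  The fixed-point iteration applies the
spectral truncation ``Pi_K`` to the weighted sum of the data projection,
the temporal neighbors and the subject mean:

    Ubar^{l+1}_{s,t} = Pi_K( alpha*Ubar^l_{s,t-1} + U_{s,t}
                             + alpha*Ubar^l_{s,t+1} + beta*mu_s(Ubar^l_{:,t}) )

with one-sided forms at t=1 and t=T, synchronously over all (s, t).
``beta = 0`` recovers per-subject time-only smoothing (PisCES);
``alpha = beta = 0`` recovers static spectral clustering.

All arithmetic runs on factored bases: each slice is stored as an
orthonormal ``V`` (G x k) with ``U = V V^T``, and ``Pi`` of a positive
combination ``sum_i w_i V_i V_i^T = W W^T`` is obtained from the
eigendecomposition of the small Gram matrix ``W^T W``.  This is exact
(not an approximation) and avoids any G x G intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from ._rng import subseed
from .containers import CommunityGrid, NetworkGrid
from .spectral import (
    eigengap_from_spectrum,
    leading_eigenbasis,
    normalized_laplacian,
)

__all__ = [
    "SmoothingConfig",
    "ProjectionGrid",
    "ConvergenceReport",
    "initialize_projections",
    "mean_other_subjects",
    "iterate_once",
    "smooth",
    "labels_from_projection",
    "run",
]

_RANK_EPS = 1e-10


@dataclass(frozen=True)
class SmoothingConfig:
    """Smoothing weights, iteration controls and model-order mode.

    Parameters
    ----------
    alpha : float
        Weight coupling temporally adjacent projections (>= 0).
    beta : float
        Weight pulling each subject toward the other subjects' mean
        projection at the same time point (>= 0).  Ignored when S = 1.
    n_communities : int or None
        Fixed K for every slice; None selects K per slice from the
        largest eigengap within [k_min, k_max).
    k_min, k_max : int
        Eigengap search range for adaptive model order.  ``k_min``
        defaults to 2 because the leading eigenvalue of a connected
        normalized Laplacian is always 1, which would otherwise make the
        trivial one-community gap dominate.
    tol : float
        Convergence threshold on the maximum Frobenius change of any
        slice between successive iterations.
    max_iter : int
        Iteration cap; non-convergence is reported, never raised.
    """

    alpha: float = 0.05
    beta: float = 0.05
    n_communities: int | None = None
    k_min: int = 2
    k_max: int = 20
    tol: float = 1e-6
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_communities is None and not (1 <= self.k_min < self.k_max):
            raise ValueError("adaptive mode needs 1 <= k_min < k_max")
        if self.n_communities is not None and self.n_communities < 1:
            raise ValueError("n_communities must be >= 1")

    @property
    def adaptive(self) -> bool:
        return self.n_communities is None


@dataclass
class ProjectionGrid:
    """S x T grid of rank-k projections in factored form.

    ``bases[s][t]`` is an orthonormal G x k_{s,t} matrix V; the
    projection itself is ``V V^T`` and is materialized only on demand.
    """

    bases: list[list[np.ndarray]]
    k_grid: np.ndarray  # (S, T) ints

    @property
    def shape(self) -> tuple[int, int, int]:
        S = len(self.bases)
        T = len(self.bases[0])
        G = self.bases[0][0].shape[0]
        return S, T, G

    def projection(self, s: int, t: int) -> np.ndarray:
        V = self.bases[s][t]
        return V @ V.T

    def to_dense(self) -> np.ndarray:
        """(S, T, G, G) stack of dense projection matrices."""
        S, T, G = self.shape
        U = np.empty((S, T, G, G))
        for s in range(S):
            for t in range(T):
                U[s, t] = self.projection(s, t)
        return U

    @classmethod
    def from_dense(cls, U: np.ndarray, k_grid: np.ndarray) -> "ProjectionGrid":
        """Factor a dense stack of (near-)projections back into bases."""
        U = np.asarray(U, dtype=float)
        S, T = U.shape[:2]
        k_grid = np.asarray(k_grid, dtype=int)
        bases = [
            [leading_eigenbasis(U[s, t], int(k_grid[s, t])).V for t in range(T)]
            for s in range(S)
        ]
        return cls(bases, k_grid.copy())

    def copy(self) -> "ProjectionGrid":
        return ProjectionGrid(
            [[V.copy() for V in row] for row in self.bases], self.k_grid.copy()
        )


def _frobenius_distance(V1: np.ndarray, V2: np.ndarray) -> float:
    # ||V1 V1^T - V2 V2^T||_F via the cross-Gram, no G x G intermediate
    cross = V1.T @ V2
    d2 = V1.shape[1] + V2.shape[1] - 2.0 * float(np.sum(cross * cross))
    return float(np.sqrt(max(d2, 0.0)))


@dataclass
class ConvergenceReport:
    """Per-iteration diagnostics of the fixed-point loop."""

    n_iter: int
    deltas: np.ndarray
    converged: bool
    tol: float
    degenerate_slices: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.deltas = np.asarray(self.deltas, dtype=float)
        if self.deltas.shape[0] != self.n_iter:
            raise ValueError("deltas length must equal n_iter")


def _slice_rank(cfg: SmoothingConfig, eigvals_desc: np.ndarray) -> int:
    if not cfg.adaptive:
        return cfg.n_communities
    vals = np.asarray(eigvals_desc, dtype=float)
    if vals.shape[0] < cfg.k_max:  # rank-deficient input: pad spectrum with zeros
        vals = np.concatenate([vals, np.zeros(cfg.k_max - vals.shape[0])])
    return eigengap_from_spectrum(vals, cfg.k_min, cfg.k_max)


def initialize_projections(
    networks: NetworkGrid, config: SmoothingConfig
) -> tuple[ProjectionGrid, list[tuple[int, int]]]:
    """Per-slice projections of the degree-normalized Laplacians.

    Returns the grid plus the list of degenerate (s, t) slices (graphs
    whose Laplacian spectrum cannot support the requested rank, e.g.
    empty graphs); those slices fall back to the smallest admissible
    rank and should be interpreted with care.
    """
    S, T, G = networks.shape
    n_eval = min(G, (config.k_max if config.adaptive else config.n_communities + 1))
    bases: list[list[np.ndarray]] = [[None] * T for _ in range(S)]
    k_grid = np.zeros((S, T), dtype=int)
    degenerate: list[tuple[int, int]] = []
    for s in range(S):
        for t in range(T):
            L = normalized_laplacian(networks[s, t])
            basis = leading_eigenbasis(L, min(n_eval, G), n_eval=n_eval)
            if np.all(np.abs(basis.eigvals) < _RANK_EPS):
                degenerate.append((s, t))
                k = config.n_communities if not config.adaptive else config.k_min
            else:
                k = _slice_rank(config, basis.eigvals)
            k = min(k, basis.V.shape[1])
            bases[s][t] = np.ascontiguousarray(basis.V[:, :k])
            k_grid[s, t] = k
    return ProjectionGrid(bases, k_grid), degenerate


def mean_other_subjects(grid: ProjectionGrid, s: int, t: int) -> np.ndarray:
    """mu_s: arithmetic mean of the other subjects' projections at time t."""
    S, _, G = grid.shape
    if S < 2:
        raise ValueError("mean over other subjects needs S >= 2")
    out = np.zeros((G, G))
    for s2 in range(S):
        if s2 != s:
            out += grid.projection(s2, t)
    return out / (S - 1)


def _smoothed_basis(
    terms: list[tuple[float, np.ndarray]], cfg: SmoothingConfig
) -> np.ndarray:
    """Leading eigenbasis of sum_i w_i V_i V_i^T = W W^T via the Gram matrix."""
    W = np.hstack([np.sqrt(w) * V for w, V in terms if w > 0])
    gram = W.T @ W
    vals, Q = scipy.linalg.eigh(gram)
    vals, Q = vals[::-1], Q[:, ::-1]
    vals = np.maximum(vals, 0.0)
    rank = int(np.sum(vals > _RANK_EPS))
    if rank == 0:  # all-zero combination (degenerate slices only)
        V = np.zeros((W.shape[0], 1))
        V[0, 0] = 1.0
        return V
    k = min(_slice_rank(cfg, vals), rank)
    V = (W @ Q[:, :k]) / np.sqrt(vals[:k])
    return V


def iterate_once(
    current: ProjectionGrid, U0: ProjectionGrid, config: SmoothingConfig
) -> ProjectionGrid:
    """One synchronous sweep of the fixed-point update over all (s, t).

    Every output slice is computed from the *current* iterate only
    (Jacobi update), so the result is independent of slice ordering.
    """
    S, T, G = current.shape
    beta_eff = config.beta if S > 1 else 0.0
    new_bases: list[list[np.ndarray]] = [[None] * T for _ in range(S)]
    k_grid = np.zeros((S, T), dtype=int)
    for s in range(S):
        for t in range(T):
            terms: list[tuple[float, np.ndarray]] = [(1.0, U0.bases[s][t])]
            if config.alpha > 0:
                if t > 0:
                    terms.append((config.alpha, current.bases[s][t - 1]))
                if t < T - 1:
                    terms.append((config.alpha, current.bases[s][t + 1]))
            if beta_eff > 0:
                w = beta_eff / (S - 1)
                terms.extend((w, current.bases[s2][t]) for s2 in range(S) if s2 != s)
            V = _smoothed_basis(terms, config)
            new_bases[s][t] = V
            k_grid[s, t] = V.shape[1]
    return ProjectionGrid(new_bases, k_grid)


def smooth(
    networks: NetworkGrid,
    config: SmoothingConfig,
    U0: ProjectionGrid | None = None,
) -> tuple[ProjectionGrid, ConvergenceReport]:
    """Run the fixed-point iteration to convergence (or ``max_iter``).

    Convergence is declared when the largest Frobenius change of any
    slice between successive iterates drops below ``config.tol``.
    ``U0`` may carry precomputed initial projections (they depend only on
    the model-order mode, so callers sweeping alpha/beta can share them).
    """
    if U0 is None:
        U0, degenerate = initialize_projections(networks, config)
    else:
        degenerate = []
    current = U0
    deltas: list[float] = []
    converged = False
    if config.alpha == 0 and (config.beta == 0 or networks.n_subjects == 1):
        # static reduction: projections are fixed points of Pi, one no-op sweep
        report = ConvergenceReport(1, np.zeros(1), True, config.tol, degenerate)
        return current, report
    for _ in range(config.max_iter):
        nxt = iterate_once(current, U0, config)
        delta = max(
            _frobenius_distance(current.bases[s][t], nxt.bases[s][t])
            for s in range(current.shape[0])
            for t in range(current.shape[1])
        )
        deltas.append(delta)
        current = nxt
        if delta < config.tol:
            converged = True
            break
    report = ConvergenceReport(len(deltas), np.asarray(deltas), converged, config.tol, degenerate)
    return current, report


def _labels_from_basis(V: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Row-normalized k-means on an eigenbasis; zero rows stay at the origin."""
    G = V.shape[0]
    if k == 1:
        return np.zeros(G, dtype=np.int64)
    X = V[:, :k] if V.shape[1] >= k else np.hstack([V, np.zeros((G, k - V.shape[1]))])
    norms = np.linalg.norm(X, axis=1)
    X = np.where(norms[:, None] > 1e-12, X / np.maximum(norms, 1e-300)[:, None], 0.0)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2**31 - 1))
    return km.fit_predict(X).astype(np.int64)


def labels_from_projection(U_bar: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Spectral-clustering label extraction from a smoothed projection.

    Takes the k leading eigenvectors of ``U_bar``, normalizes each row to
    unit length and clusters rows with k-means (deterministic given
    ``seed``).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    basis = leading_eigenbasis(np.asarray(U_bar, dtype=float), min(k, U_bar.shape[0]))
    return _labels_from_basis(basis.V, k, seed)


def run(
    networks: NetworkGrid,
    config: SmoothingConfig,
    seed: int = 0,
    U0: ProjectionGrid | None = None,
) -> tuple[CommunityGrid, ConvergenceReport, ProjectionGrid]:
    """Smooth, then extract one label vector per (subject, time) slice.

    The per-slice K used for labeling is the rank of the smoothed slice
    at convergence.
    """
    grid, report = smooth(networks, config, U0=U0)
    S, T, G = grid.shape
    z = np.empty((S, T, G), dtype=np.int64)
    for s in range(S):
        for t in range(T):
            z[s, t] = _labels_from_basis(
                grid.bases[s][t], int(grid.k_grid[s, t]), subseed(seed, "kmeans", s, t)
            )
    return CommunityGrid(z), report, grid
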