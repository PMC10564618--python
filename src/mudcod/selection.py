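"""Hyperparameter selection by node-pair network cross-validation.

The smoothing weights (alpha, beta) are tuned with a resampling-based
network cross-validation: unordered node *pairs* (not edges) are split
into folds, the training matrix for each fold keeps the observed pairs
(rescaled by the inverse observed fraction) and fills the held-out pairs
with a low-rank spectral reconstruction, the smoothing pipeline is run
on the completed matrices, and the resulting communities are scored on
the held-out pairs of the original matrices under a degree-corrected
block model (DCBM) Poisson log-likelihood.  The grid point with the
highest summed held-out log-likelihood wins; ties break toward smaller
(alpha, beta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from ._rng import stream, subseed
from .containers import NetworkGrid
from .smoothing import SmoothingConfig, run as _run_smoothing
from .spectral import eigengap_from_spectrum, normalized_laplacian
import scipy.sparse as sp

__all__ = [
    "CVConfig",
    "PairFolds",
    "DCBMFit",
    "pair_folds",
    "complete_heldout",
    "dcbm_fit",
    "dcbm_loglik",
    "select_hyperparams",
]

DEFAULT_GRID = (0.0125, 0.025, 0.05, 0.1, 0.25, 0.5, 0.75)

# stands in for log(0) when a held-out edge gets zero predicted rate
_LOG_ZERO_SENTINEL = -1e6


@dataclass(frozen=True)
class CVConfig:
    """Grid-search and fold configuration for (alpha, beta) tuning."""

    alpha_grid: tuple[float, ...] = DEFAULT_GRID
    beta_grid: tuple[float, ...] = DEFAULT_GRID
    n_folds: int = 5
    n_reps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_grid", "beta_grid"):
            g = tuple(getattr(self, name))
            object.__setattr__(self, name, g)
            if len(g) == 0 or any(v < 0 for v in g):
                raise ValueError(f"{name} must be non-empty with non-negative values")
            if list(g) != sorted(g):
                raise ValueError(f"{name} must be ascending")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class PairFolds:
    """Balanced random partition of all unordered node pairs into folds.

    ``fold[p]`` is the fold of the p-th pair in row-major upper-triangle
    order; ``rows``/``cols`` give the pair endpoints in that order.
    """

    n_nodes: int
    n_folds: int
    fold: np.ndarray
    rows: np.ndarray
    cols: np.ndarray

    def pairs_in_fold(self, f: int) -> np.ndarray:
        """(n, 2) array of the pairs assigned to fold ``f``."""
        mask = self.fold == f
        return np.column_stack([self.rows[mask], self.cols[mask]])

    def mask_for_fold(self, f: int) -> np.ndarray:
        """Symmetric boolean G x G mask of the held-out pairs of fold ``f``."""
        G = self.n_nodes
        m = np.zeros((G, G), dtype=bool)
        sel = self.fold == f
        m[self.rows[sel], self.cols[sel]] = True
        return m | m.T


def pair_folds(G: int, n_folds: int, rng) -> PairFolds:
    """Assign every unordered pair (i < j) to one of ``n_folds`` folds.

    Fold sizes differ by at most one; the assignment is a uniformly
    random balanced partition.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rows, cols = np.triu_indices(G, k=1)
    n_pairs = rows.shape[0]
    if n_folds > n_pairs:
        raise ValueError(f"n_folds={n_folds} exceeds the {n_pairs} node pairs")
    fold = np.tile(np.arange(n_folds), n_pairs // n_folds + 1)[:n_pairs]
    rng.shuffle(fold)
    return PairFolds(G, n_folds, fold, rows, cols)


def _as_mask(A_shape, heldout) -> np.ndarray:
    G = A_shape[0]
    heldout = np.asarray(heldout)
    if heldout.dtype == bool:
        return heldout | heldout.T
    m = np.zeros((G, G), dtype=bool)
    if heldout.size:
        m[heldout[:, 0], heldout[:, 1]] = True
    return m | m.T


def _rank_k_reconstruction(M: np.ndarray, K: int) -> np.ndarray:
    """Best rank-K approximation by the K largest-|eigenvalue| eigenpairs."""
    G = M.shape[0]
    Ms = 0.5 * (M + M.T)
    if K < G // 4:
        # the K largest-magnitude eigenpairs live among the K algebraically
        # largest and K smallest; two subset solves beat a full solve
        lo = scipy.linalg.eigh(Ms, subset_by_index=[0, K - 1])
        hi = scipy.linalg.eigh(Ms, subset_by_index=[G - K, G - 1])
        vals = np.concatenate([lo[0], hi[0]])
        vecs = np.concatenate([lo[1], hi[1]], axis=1)
    else:
        vals, vecs = scipy.linalg.eigh(Ms)
    top = np.argsort(np.abs(vals))[::-1][:K]
    return (vecs[:, top] * vals[top]) @ vecs[:, top].T


def complete_heldout(A: np.ndarray, heldout, K: int, n_refine: int = 0) -> np.ndarray:
    """Training matrix: rescaled observed entries + rank-K filled held-out ones.

    Observed off-diagonal entries are divided by the observed fraction so
    the expected entry value is unbiased; held-out entries are replaced
    by the rank-K eigen-reconstruction (K largest-magnitude eigenpairs)
    of the zero-filled rescaled matrix.  The result is symmetrized,
    clipped to [0, 1] and keeps a zero diagonal.

    ``n_refine > 0`` additionally iterates the hard-impute fixed point
    (observed entries kept unrescaled, held-out and diagonal positions
    refreshed from the rank-K reconstruction), which recovers exactly
    low-rank matrices to numerical precision.  The default single-shot
    form is used for cross-validation, where the cheaper unbiased fill
    is sufficient.
    """
    A = np.asarray(A, dtype=float)
    G = A.shape[0]
    mask = _as_mask(A.shape, heldout)
    np.fill_diagonal(mask, False)
    n_pairs = G * (G - 1) // 2
    n_held = int(np.triu(mask, 1).sum())
    if n_held == 0:
        return A.copy()
    if n_held >= n_pairs:
        raise ValueError("cannot hold out every node pair")
    obs_frac = 1.0 - n_held / n_pairs
    M0 = np.where(mask, 0.0, A / obs_frac)
    np.fill_diagonal(M0, 0.0)
    recon = _rank_k_reconstruction(M0, K)
    out = np.where(mask, recon, M0)
    if n_refine > 0:
        free = mask | np.eye(G, dtype=bool)  # impute diagonal too
        cur = np.where(free, recon, A)
        for _ in range(n_refine):
            recon = _rank_k_reconstruction(cur, K)
            nxt = np.where(free, recon, A)
            if np.max(np.abs(nxt - cur)) < 1e-9:
                cur = nxt
                break
            cur = nxt
        out = cur
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 0.0)
    return np.clip(out, 0.0, 1.0)


@dataclass
class DCBMFit:
    """Plug-in DCBM estimates from one network and one label vector.

    ``theta_hat[i]`` is node i's share of its block's total degree (sums
    to 1 within each block); ``B_hat[q, l]`` is the total edge weight
    between blocks q and l (diagonal doubled, i.e. ``Z^T A Z``).
    """

    theta_hat: np.ndarray
    B_hat: np.ndarray


def dcbm_fit(A: np.ndarray, z: np.ndarray) -> DCBMFit:
    """Standard DCBM maximum-likelihood plug-in estimators."""
    A = np.asarray(A, dtype=float)
    z = np.asarray(z, dtype=np.int64)
    if A.shape[0] != z.shape[0]:
        raise ValueError("adjacency order and label length differ")
    K = int(z.max()) + 1 if z.size else 0
    Z = np.zeros((z.shape[0], K))
    Z[np.arange(z.shape[0]), z] = 1.0
    B_hat = Z.T @ A @ Z
    deg = A.sum(axis=1)
    block_deg = Z.T @ deg
    theta = np.empty_like(deg)
    for q in range(K):
        members = z == q
        if block_deg[q] > 0:
            theta[members] = deg[members] / block_deg[q]
        else:  # empty-degree block: uniform share
            theta[members] = 1.0 / max(int(members.sum()), 1)
    return DCBMFit(theta, B_hat)


def dcbm_loglik(A: np.ndarray, fit: DCBMFit, z: np.ndarray, pairs) -> float:
    """Poisson DCBM log-likelihood over the given unordered pairs.

    sum over pairs of ``A_ij * log(lam_ij) - lam_ij`` with
    ``lam_ij = theta_i * theta_j * B_hat[z_i, z_j]``; ``0*log 0`` is 0
    and ``log 0`` against a present edge contributes a large negative
    sentinel instead of ``-inf``.
    """
    A = np.asarray(A, dtype=float)
    z = np.asarray(z, dtype=np.int64)
    pairs = np.asarray(pairs)
    if pairs.dtype == bool:
        r, c = np.nonzero(np.triu(pairs | pairs.T, k=1))
    else:
        pairs = pairs.reshape(-1, 2)
        r, c = pairs[:, 0], pairs[:, 1]
    lam = fit.theta_hat[r] * fit.theta_hat[c] * fit.B_hat[z[r], z[c]]
    a = A[r, c]
    with np.errstate(divide="ignore"):
        log_lam = np.where(lam > 0, np.log(np.maximum(lam, 1e-300)), _LOG_ZERO_SENTINEL)
    terms = np.where(a > 0, a * log_lam, 0.0) - lam
    return float(terms.sum())


def _slice_rank_for_completion(A_obs: np.ndarray, defaults: SmoothingConfig) -> int:
    """K for the spectral completion of one slice, from the defaults' k-mode."""
    if not defaults.adaptive:
        return defaults.n_communities
    L = normalized_laplacian(A_obs)
    Ld = L.toarray() if sp.issparse(L) else L
    n_eval = min(defaults.k_max, Ld.shape[0])
    vals = scipy.linalg.eigh(Ld, eigvals_only=True,
                             subset_by_index=[Ld.shape[0] - n_eval, Ld.shape[0] - 1])[::-1]
    if np.all(np.abs(vals) < 1e-10):
        return defaults.k_min
    return eigengap_from_spectrum(vals, defaults.k_min, min(defaults.k_max, n_eval))


def select_hyperparams(
    networks: NetworkGrid,
    cv: CVConfig,
    smoothing_defaults: SmoothingConfig | None = None,
    folds: tuple[int, ...] | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Grid-search (alpha, beta) by node-pair cross-validation.

    Returns ``(alpha_star, beta_star, table)`` where ``table`` has one
    row per (alpha, beta, rep, fold) with the summed held-out DCBM
    log-likelihood over all (subject, time) slices.  ``folds`` restricts
    scoring to a subset of the fold indices (e.g. ``(0,)`` turns 2-fold
    CV into a single 50% holdout split for quick tuning).
    """
    if smoothing_defaults is None:
        smoothing_defaults = SmoothingConfig()
    S, T, G = networks.shape
    fold_ids = tuple(range(cv.n_folds)) if folds is None else tuple(folds)
    if any(f < 0 or f >= cv.n_folds for f in fold_ids) or not fold_ids:
        raise ValueError("folds must be a non-empty subset of range(n_folds)")
    rows = []
    for rep in range(cv.n_reps):
        folds_obj = pair_folds(G, cv.n_folds, stream(cv.seed, "folds", rep))
        for f in fold_ids:
            mask = folds_obj.mask_for_fold(f)
            held_pairs = folds_obj.pairs_in_fold(f)
            # completed training grid, shared by every (alpha, beta) cell
            A_train = np.empty_like(networks.A)
            for s in range(S):
                for t in range(T):
                    k_c = _slice_rank_for_completion(
                        np.where(mask, 0.0, networks[s, t]), smoothing_defaults
                    )
                    A_train[s, t] = complete_heldout(networks[s, t], held_pairs, k_c)
            train_grid = NetworkGrid(A_train)
            for alpha in cv.alpha_grid:
                for beta in cv.beta_grid:
                    config = SmoothingConfig(
                        alpha=alpha,
                        beta=beta,
                        n_communities=smoothing_defaults.n_communities,
                        k_min=smoothing_defaults.k_min,
                        k_max=smoothing_defaults.k_max,
                        tol=smoothing_defaults.tol,
                        max_iter=smoothing_defaults.max_iter,
                    )
                    labels, report, _ = _run_smoothing(
                        train_grid, config, seed=subseed(cv.seed, "cv", rep, f)
                    )
                    if not report.converged:
                        warnings.warn(
                            f"smoothing did not converge for alpha={alpha}, "
                            f"beta={beta} (fold {f}); scoring anyway",
                            stacklevel=2,
                        )
                    total = 0.0
                    for s in range(S):
                        for t in range(T):
                            fit = dcbm_fit(A_train[s, t], labels[s, t])
                            total += dcbm_loglik(
                                networks[s, t], fit, labels[s, t], held_pairs
                            )
                    rows.append(
                        {"alpha": alpha, "beta": beta, "rep": rep, "fold": f,
                         "loglik": total}
                    )
    table = pd.DataFrame(rows)
    sums = table.groupby(["alpha", "beta"], sort=True)["loglik"].sum()
    best_alpha, best_beta = None, None
    best = -np.inf
    for alpha in cv.alpha_grid:  # ascending: ties stay at the smaller pair
        for beta in cv.beta_grid:
            score = sums.loc[(alpha, beta)]
            if score > best:
                best, best_alpha, best_beta = score, alpha, beta
    return float(best_alpha), float(best_beta), table
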