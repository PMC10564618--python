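"""Degree-normalized Laplacians, leading eigenspaces and rank-K projections.

The smoothing algorithm never consumes raw eigenvectors: every quantity
downstream is a projection matrix ``U = V V^T`` onto a leading
eigenspace, which is invariant to eigenvector sign flips and rotations
within degenerate eigenvalue blocks.  The number of communities can be
chosen per matrix from the largest eigengap of its spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "EigenBasis",
    "normalized_laplacian",
    "leading_eigenbasis",
    "pi_fixed",
    "eigengap_select_k",
    "eigengap_from_spectrum",
    "pi_adaptive",
]

# above this order, leading eigenpairs of sparse Laplacians go through
# Lanczos (with a fixed start vector) instead of the dense solver
DENSE_EIG_MAX_ORDER = 400


@dataclass(frozen=True)
class EigenBasis:
    """Orthonormal basis V (G x K) of a leading invariant subspace.

    ``eigvals`` holds the K algebraically largest eigenvalues, sorted
    descending and aligned with the columns of V.
    """

    V: np.ndarray
    eigvals: np.ndarray

    @property
    def k(self) -> int:
        return self.V.shape[1]

    def projection(self) -> np.ndarray:
        """Dense projection matrix V V^T."""
        return self.V @ self.V.T


def normalized_laplacian(A) -> np.ndarray:
    """L = D^{-1/2} A D^{-1/2} with zero rows/columns for isolated nodes.

    Accepts dense or scipy.sparse symmetric input with zero diagonal and
    returns the same container type.  Eigenvalues of the result lie in
    [-1, 1].
    """
    sparse_in = sp.issparse(A)
    if sparse_in:
        if (abs(A - A.T) > 1e-12).nnz:
            raise ValueError("adjacency must be symmetric")
        deg = np.asarray(A.sum(axis=1)).ravel()
    else:
        A = np.asarray(A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-12):
            raise ValueError("adjacency must be square and symmetric")
        deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        d_isqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    if sparse_in:
        D = sp.diags(d_isqrt)
        return (D @ A @ D).tocsr()
    return d_isqrt[:, None] * A * d_isqrt[None, :]


def _sym(M: np.ndarray) -> np.ndarray:
    # suppress floating-point asymmetry drift before eigendecomposition
    return 0.5 * (M + M.T)


def leading_eigenbasis(M, k: int, *, n_eval: int | None = None) -> EigenBasis:
    """Eigenpairs of the ``k`` algebraically largest eigenvalues of symmetric M.

    ``n_eval`` asks for additional trailing eigenvalues (still sorted
    descending, basis columns only for the first ``k``) so callers can
    inspect eigengaps past k without a second factorization.
    """
    G = M.shape[0]
    if not (1 <= k <= G):
        raise ValueError(f"need 1 <= k <= {G}, got {k}")
    n_eval = k if n_eval is None else min(max(n_eval, k), G)
    if sp.issparse(M) and G > DENSE_EIG_MAX_ORDER and n_eval < G - 1:
        # deterministic start vector: Lanczos output is then reproducible
        v0 = np.full(G, 1.0 / np.sqrt(G))
        vals, vecs = spla.eigsh(M, k=n_eval, which="LA", v0=v0)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    else:
        Md = M.toarray() if sp.issparse(M) else np.asarray(M, dtype=float)
        vals, vecs = scipy.linalg.eigh(_sym(Md), subset_by_index=[G - n_eval, G - 1])
        vals, vecs = vals[::-1], vecs[:, ::-1]
    return EigenBasis(np.ascontiguousarray(vecs[:, :k]), vals)


def pi_fixed(M, k: int) -> np.ndarray:
    """Rank-k spectral projection Pi_K(M) = sum of the k leading v v^T."""
    return leading_eigenbasis(M, k).projection()


def eigengap_from_spectrum(eigvals_desc: np.ndarray, k_min: int, k_max: int) -> int:
    """argmax over k in [k_min, k_max) of eigvals[k-1] - eigvals[k].

    ``eigvals_desc`` must be sorted descending and reach index k_max - 1
    at least.  Ties break toward the smaller k.
    """
    if k_min < 1 or k_max <= k_min:
        raise ValueError("need 1 <= k_min < k_max")
    vals = np.asarray(eigvals_desc, dtype=float)
    if vals.shape[0] < k_max:
        raise ValueError("not enough eigenvalues for the requested range")
    gaps = vals[k_min - 1 : k_max - 1] - vals[k_min:k_max]
    return int(k_min + np.argmax(gaps))


def eigengap_select_k(M, k_min: int, k_max: int) -> int:
    """Model-order selection: the k in [k_min, k_max) with the largest eigengap."""
    if k_max > M.shape[0]:
        raise ValueError("k_max cannot exceed the matrix order")
    basis = leading_eigenbasis(M, 1, n_eval=k_max)
    return eigengap_from_spectrum(basis.eigvals, k_min, k_max)


def pi_adaptive(M, k_min: int, k_max: int) -> tuple[np.ndarray, int]:
    """Projection onto the eigengap-selected leading eigenspace; returns (U, k)."""
    if k_max > M.shape[0]:
        raise ValueError("k_max cannot exceed the matrix order")
    basis = leading_eigenbasis(M, k_max - 1 if k_max > 1 else 1, n_eval=k_max)
    k = eigengap_from_spectrum(basis.eigvals, k_min, k_max)
    V = basis.V[:, :k]
    return V @ V.T, k
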