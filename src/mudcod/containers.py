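"""Grid containers shared across the package.

Everything operates on a common node set of size G observed for S
subjects at T time points.  ``NetworkGrid`` stacks the S*T adjacency
matrices, ``CommunityGrid`` the corresponding label vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NetworkGrid", "CommunityGrid", "validate_adjacency"]


def validate_adjacency(A: np.ndarray, *, binary: bool = False) -> np.ndarray:
    """Check that ``A`` is a square symmetric hollow matrix; return it as float."""
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency matrix must be symmetric")
    if np.any(np.diagonal(A) != 0):
        raise ValueError("adjacency matrix must have a zero diagonal")
    if np.any(A < 0):
        raise ValueError("adjacency entries must be non-negative")
    if binary and not np.isin(A, (0, 1)).all():
        raise ValueError("adjacency entries must be 0/1")
    return np.asarray(A, dtype=float)


@dataclass
class NetworkGrid:
    """S x T stack of G x G symmetric adjacency matrices over one node set.

    Parameters
    ----------
    A : ndarray, shape (S, T, G, G)
        Per-subject, per-time adjacency matrices.  Binary 0/1 for
        thresholded co-expression networks; weighted matrices (entries in
        [0, 1]) are accepted so that completed cross-validation training
        matrices can flow through the same code path.
    node_names : list of str, optional
        Shared node identifiers; positional indices are used when absent.
    """

    A: np.ndarray
    node_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 4 or self.A.shape[2] != self.A.shape[3]:
            raise ValueError(
                f"NetworkGrid expects shape (S, T, G, G), got {self.A.shape}"
            )
        S, T, G, _ = self.A.shape
        for s in range(S):
            for t in range(T):
                validate_adjacency(self.A[s, t])
        if self.node_names is not None and len(self.node_names) != G:
            raise ValueError("node_names length must equal G")

    @property
    def shape(self) -> tuple[int, int, int]:
        """(S, T, G)."""
        S, T, G, _ = self.A.shape
        return S, T, G

    @property
    def n_subjects(self) -> int:
        return self.A.shape[0]

    @property
    def n_times(self) -> int:
        return self.A.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.A.shape[2]

    def __getitem__(self, st: tuple[int, int]) -> np.ndarray:
        s, t = st
        return self.A[s, t]

    @classmethod
    def from_matrices(cls, matrices, node_names=None) -> "NetworkGrid":
        """Build from a nested [subject][time] list of matrices."""
        A = np.asarray([[np.asarray(m, dtype=float) for m in row] for row in matrices])
        return cls(A, node_names=node_names)


@dataclass
class CommunityGrid:
    """S x T stack of length-G integer community label vectors."""

    z: np.ndarray
    n_communities: int | None = field(default=None)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.int64)
        if self.z.ndim != 3:
            raise ValueError(f"CommunityGrid expects shape (S, T, G), got {self.z.shape}")
        if self.z.size and self.z.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.n_communities is None:
            self.n_communities = int(self.z.max()) + 1 if self.z.size else 0
        elif self.z.size and self.z.max() >= self.n_communities:
            raise ValueError("labels must be < n_communities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.z.shape

    def __getitem__(self, st: tuple[int, int]) -> np.ndarray:
        s, t = st
        return self.z[s, t]
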