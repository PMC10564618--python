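"""Multi-subject dynamic degree-corrected block model (MuS-Dynamic-DCBM).

Generates per-subject, per-time networks with ground-truth communities.
Edges are Bernoulli with probability ``psi_i * psi_j * B[z_i, z_j]``: a
degree-corrected block model whose label vectors are resampled node-wise
across time (rate ``r_time``) and across subjects (rate ``r_subject``).

Two label-sharing settings are supported:

* ``"SSoS"`` (signal sharing over subjects): an ancestor label chain
  evolves over time, and every subject at every time point is an
  independent perturbation of the ancestor at that time point.
* ``"SSoT"`` (signal sharing over time): subjects diverge from a common
  ancestor once at t=0, then each evolves independently over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import stream
from .containers import CommunityGrid, NetworkGrid

__all__ = [
    "SimulationConfig",
    "ConnectivityMatrix",
    "DegreeParams",
    "MuSDynamicDCBM",
    "sample_connectivity",
    "sample_degree_params",
    "init_labels",
    "evolve_labels",
    "generate_membership_series",
    "sample_adjacency",
    "generate",
]

SETTINGS = ("SSoS", "SSoT")


@dataclass(frozen=True)
class SimulationConfig:
    """All MuS-Dynamic-DCBM parameters.

    Defaults reproduce the simulation benchmark conditions: 500 genes in
    10 communities, in-cluster edge rates Uniform(0.2, 0.4), between-
    cluster rates fixed at 0.1, 8 subjects, degree propensities
    ``0.5 + perm(1..G)/G`` in (0.5, 1.5].
    """

    n_nodes: int = 500
    n_communities: int = 10
    n_subjects: int = 8
    n_times: int = 2
    p_in: tuple[float, float] = (0.2, 0.4)
    p_out: tuple[float, float] = (0.1, 0.1)
    gamma0: float = 0.5
    gamma1: float = 1.0
    r_time: float = 0.0
    r_subject: float = 0.0
    setting: str = "SSoS"
    seed: int = 0
    # when False, subject 1 is itself perturbed from a latent ancestor
    # (SSoS only); the default follows the generative equations, where the
    # ancestor chain IS subject 1.
    ancestor_is_subject: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.n_communities <= self.n_nodes):
            raise ValueError("need 1 <= K <= G")
        if self.n_subjects < 1 or self.n_times < 1:
            raise ValueError("need S >= 1 and T >= 1")
        _check_density_bounds(self.p_in, self.p_out)
        for name in ("r_time", "r_subject"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}, got {self.setting!r}")

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def _check_density_bounds(p_in, p_out) -> None:
    lo_in, hi_in = p_in
    lo_out, hi_out = p_out
    if not (0.0 <= lo_out <= hi_out <= lo_in <= hi_in <= 1.0):
        raise ValueError(
            "density bounds must satisfy 0 <= p_out(0) <= p_out(1) "
            f"<= p_in(0) <= p_in(1) <= 1, got p_in={p_in}, p_out={p_out}"
        )


@dataclass(frozen=True)
class ConnectivityMatrix:
    """K x K symmetric block edge-rate matrix B."""

    B: np.ndarray

    def __post_init__(self) -> None:
        B = np.asarray(self.B, dtype=float)
        if B.ndim != 2 or B.shape[0] != B.shape[1]:
            raise ValueError("B must be square")
        if not np.allclose(B, B.T):
            raise ValueError("B must be symmetric")
        if B.min() < 0 or B.max() > 1:
            raise ValueError("B entries must be in [0, 1]")
        object.__setattr__(self, "B", B)


@dataclass(frozen=True)
class DegreeParams:
    """Length-G vector of per-node degree propensities psi."""

    psi: np.ndarray

    def __post_init__(self) -> None:
        psi = np.asarray(self.psi, dtype=float)
        if psi.ndim != 1:
            raise ValueError("psi must be a vector")
        if psi.min() < 0:
            raise ValueError("psi must be non-negative")
        object.__setattr__(self, "psi", psi)


def sample_connectivity(K, p_in, p_out, rng) -> ConnectivityMatrix:
    """Draw B with Uniform(p_in) diagonal and Uniform(p_out) off-diagonal.

    Only the upper triangle is drawn, then mirrored, so B is exactly
    symmetric.
    """
    _check_density_bounds(p_in, p_out)
    B = np.zeros((K, K))
    iu = np.triu_indices(K, k=1)
    B[iu] = rng.uniform(p_out[0], p_out[1], size=len(iu[0]))
    B = B + B.T
    np.fill_diagonal(B, rng.uniform(p_in[0], p_in[1], size=K))
    return ConnectivityMatrix(B)


def sample_degree_params(G, gamma0, gamma1, rng) -> DegreeParams:
    """psi = gamma0 + gamma1 * perm(1..G) / G, a random permutation per draw."""
    if G < 1:
        raise ValueError("G must be >= 1")
    perm = rng.permutation(G) + 1  # values 1..G
    return DegreeParams(gamma0 + gamma1 * perm / G)


def init_labels(G, K, rng) -> np.ndarray:
    """Initial labels, i.i.d. uniform over {0, ..., K-1}."""
    if K > G:
        raise ValueError("K cannot exceed G")
    return rng.integers(0, K, size=G)


def evolve_labels(z_prev, r, K, rng) -> np.ndarray:
    """Node-wise label churn: keep with probability 1-r, else redraw uniformly.

    The uniform redraw ranges over all K labels and may coincide with the
    previous one, so the effective change probability is r*(K-1)/K.
    """
    z_prev = np.asarray(z_prev)
    if not (0.0 <= r <= 1.0):
        raise ValueError("r must be in [0, 1]")
    resample = rng.random(z_prev.shape[0]) < r
    z = z_prev.copy()
    z[resample] = rng.integers(0, K, size=int(resample.sum()))
    return z


def generate_membership_series(config: SimulationConfig, seed: int | None = None) -> CommunityGrid:
    """Ground-truth label grid under the configured sharing setting.

    SSoS: the ancestor chain evolves with ``r_time``; subjects s >= 2 at
    every t are redrawn from the ancestor with ``r_subject`` (subject 1
    is the ancestor itself unless ``ancestor_is_subject`` is False).
    SSoT: subjects are derived from the ancestor's t=0 labels with
    ``r_subject`` once, then each evolves independently with ``r_time``.
    """
    if seed is None:
        seed = config.seed
    G, K = config.n_nodes, config.n_communities
    S, T = config.n_subjects, config.n_times
    z = np.empty((S, T, G), dtype=np.int64)

    root = init_labels(G, K, stream(seed, "labels", 0, 0))
    if config.setting == "SSoS":
        ancestor = np.empty((T, G), dtype=np.int64)
        ancestor[0] = root
        for t in range(1, T):
            ancestor[t] = evolve_labels(
                ancestor[t - 1], config.r_time, K, stream(seed, "labels", 0, t)
            )
        first = 0 if config.ancestor_is_subject else -1
        for s in range(S):
            for t in range(T):
                if s == 0 and first == 0:
                    z[s, t] = ancestor[t]
                else:
                    z[s, t] = evolve_labels(
                        ancestor[t], config.r_subject, K, stream(seed, "labels", s + 1, t)
                    )
    else:  # SSoT
        for s in range(S):
            if s == 0:
                z[s, 0] = root
            else:
                z[s, 0] = evolve_labels(
                    root, config.r_subject, K, stream(seed, "labels", s + 1, 0)
                )
            for t in range(1, T):
                z[s, t] = evolve_labels(
                    z[s, t - 1], config.r_time, K, stream(seed, "labels", s + 1, t)
                )
    return CommunityGrid(z, n_communities=K)


def sample_adjacency(z, B: ConnectivityMatrix, psi: DegreeParams, rng) -> np.ndarray:
    """One symmetric hollow Bernoulli adjacency matrix.

    Edge probability psi_i * psi_j * B[z_i, z_j], clipped into [0, 1]
    (a safety net: with default gamma and B <= 0.4 the product stays
    below 0.9).  Only the upper triangle is drawn.
    """
    z = np.asarray(z)
    psi_v = psi.psi
    if z.shape[0] != psi_v.shape[0]:
        raise ValueError("labels and degree parameters disagree on G")
    if z.max() >= B.B.shape[0]:
        raise ValueError("labels exceed the connectivity matrix order")
    P = np.clip(np.outer(psi_v, psi_v) * B.B[np.ix_(z, z)], 0.0, 1.0)
    G = z.shape[0]
    A = np.zeros((G, G))
    iu = np.triu_indices(G, k=1)
    A[iu] = (rng.random(len(iu[0])) < P[iu]).astype(float)
    return A + A.T


def generate(config: SimulationConfig) -> tuple[NetworkGrid, CommunityGrid]:
    """Networks plus ground truth; fresh (psi, B) drawn per (subject, time)."""
    labels = generate_membership_series(config)
    S, T, G = labels.shape
    A = np.empty((S, T, G, G))
    for s in range(S):
        for t in range(T):
            B = sample_connectivity(
                config.n_communities, config.p_in, config.p_out,
                stream(config.seed, "connectivity", s, t),
            )
            psi = sample_degree_params(
                G, config.gamma0, config.gamma1, stream(config.seed, "degree", s, t)
            )
            A[s, t] = sample_adjacency(labels[s, t], B, psi, stream(config.seed, "adjacency", s, t))
    return NetworkGrid(A), labels


@dataclass
class MuSDynamicDCBM:
    """Object-style front end over the sampling functions.

    >>> sim = MuSDynamicDCBM(SimulationConfig(n_nodes=60, n_communities=3,
    ...                                       n_subjects=2, n_times=2, seed=1))
    >>> networks, truth = sim.generate()
    """

    config: SimulationConfig = field(default_factory=SimulationConfig)

    def generate(self, seed: int | None = None) -> tuple[NetworkGrid, CommunityGrid]:
        cfg = self.config if seed is None else self.config.replace(seed=seed)
        return generate(cfg)

    def membership_series(self, seed: int | None = None) -> CommunityGrid:
        return generate_membership_series(self.config, seed=seed)
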