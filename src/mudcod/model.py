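"""Model/Results front end for multi-subject dynamic community detection.

``MuDCoD`` is constructed from a :class:`~mudcod.containers.NetworkGrid`
(or loaded from a manifest on disk) with smoothing hyperparameters, and
``fit()`` returns a :class:`MuDCoDResults` carrying the inferred
communities, the smoothed projections, convergence diagnostics and
summary tables.  Setting ``beta=0`` yields time-only smoothing (PisCES);
``alpha=beta=0`` yields static per-network spectral clustering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import metrics as _metrics
from . import smoothing as _smoothing
from .containers import CommunityGrid, NetworkGrid
from .smoothing import ConvergenceReport, ProjectionGrid, SmoothingConfig

__all__ = ["MuDCoD", "MuDCoDResults"]


class MuDCoD:
    """Community detection on multi-subject dynamic networks.

    Parameters
    ----------
    networks : NetworkGrid
        S x T stack of symmetric adjacency matrices over a common node set.
    alpha : float
        Smoothing weight across adjacent time points.
    beta : float
        Smoothing weight across subjects (toward the leave-one-out mean
        projection at each time point).
    n_communities : int, optional
        Fix the number of communities K for every slice.  Default is
        adaptive: K is selected per slice from the largest eigengap in
        ``[k_min, k_max)``.
    k_min, k_max, tol, max_iter :
        See :class:`~mudcod.smoothing.SmoothingConfig`.

    Examples
    --------
    >>> from mudcod import MuSDynamicDCBM, SimulationConfig, MuDCoD
    >>> sim = MuSDynamicDCBM(SimulationConfig(n_nodes=120, n_communities=3,
    ...                                       n_subjects=4, n_times=2, seed=7))
    >>> networks, truth = sim.generate()
    >>> res = MuDCoD(networks, alpha=0.1, beta=0.2, n_communities=3).fit(seed=0)
    >>> res.communities.shape
    (4, 2, 120)
    """

    def __init__(
        self,
        networks: NetworkGrid,
        *,
        alpha: float = 0.05,
        beta: float = 0.05,
        n_communities: int | None = None,
        k_min: int = 2,
        k_max: int = 20,
        tol: float = 1e-6,
        max_iter: int = 100,
    ) -> None:
        if not isinstance(networks, NetworkGrid):
            networks = NetworkGrid(np.asarray(networks))
        k_max = min(k_max, networks.n_nodes)
        self.networks = networks
        self.config = SmoothingConfig(
            alpha=alpha,
            beta=beta,
            n_communities=n_communities,
            k_min=k_min,
            k_max=k_max,
            tol=tol,
            max_iter=max_iter,
        )

    @classmethod
    def from_manifest(cls, path, **kwargs) -> "MuDCoD":
        """Build the model from an on-disk network-grid manifest (YAML)."""
        from .io import read_network_grid

        return cls(read_network_grid(path), **kwargs)

    @classmethod
    def pisces(cls, networks, *, alpha: float = 0.05, **kwargs) -> "MuDCoD":
        """Time-only smoothing (the beta = 0 special case)."""
        return cls(networks, alpha=alpha, beta=0.0, **kwargs)

    @classmethod
    def static(cls, networks, **kwargs) -> "MuDCoD":
        """Per-network static spectral clustering (alpha = beta = 0)."""
        return cls(networks, alpha=0.0, beta=0.0, **kwargs)

    def fit(self, seed: int = 0) -> "MuDCoDResults":
        """Run the smoothing fixed point and extract per-slice communities."""
        communities, report, projections = _smoothing.run(
            self.networks, self.config, seed=seed
        )
        return MuDCoDResults(self, communities, projections, report, seed)

    def select_hyperparams(self, cv_config=None, seed: int = 0):
        """Tune (alpha, beta) by node-pair network cross-validation.

        Thin wrapper over :func:`mudcod.selection.select_hyperparams`
        using this model's network grid and smoothing defaults.
        """
        from .selection import CVConfig, select_hyperparams

        if cv_config is None:
            cv_config = CVConfig(seed=seed)
        return select_hyperparams(self.networks, cv_config, self.config)


class MuDCoDResults:
    """Fitted communities, projections and diagnostics.

    Attributes
    ----------
    communities : CommunityGrid
        Inferred label vectors, one per (subject, time).
    projections : ProjectionGrid
        Smoothed projection matrices in factored form.
    convergence : ConvergenceReport
        Iteration count, per-iteration Frobenius deltas, converged flag.
    k_grid : ndarray (S, T)
        Number of communities used for each slice.
    """

    def __init__(
        self,
        model: MuDCoD,
        communities: CommunityGrid,
        projections: ProjectionGrid,
        convergence: ConvergenceReport,
        seed: int,
    ) -> None:
        self.model = model
        self.communities = communities
        self.projections = projections
        self.convergence = convergence
        self.seed = seed

    @property
    def k_grid(self) -> np.ndarray:
        return self.projections.k_grid

    def to_frame(self) -> pd.DataFrame:
        """Tidy labels table with columns subject, time, node, community."""
        S, T, G = self.communities.shape
        names = self.model.networks.node_names
        s_idx, t_idx, n_idx = np.meshgrid(
            np.arange(S), np.arange(T), np.arange(G), indexing="ij"
        )
        df = pd.DataFrame(
            {
                "subject": s_idx.ravel(),
                "time": t_idx.ravel(),
                "node": [names[i] for i in n_idx.ravel()] if names else n_idx.ravel(),
                "community": self.communities.z.ravel(),
            }
        )
        return df

    def score(self, truth: CommunityGrid, metric="ari") -> dict:
        """Per-slice and mean agreement with ground-truth labels."""
        return _metrics.summarize_grid(self.communities, truth, metric=metric)

    def subject_similarity(self, metric="nmi") -> pd.DataFrame:
        """Pairwise between-subject partition agreement per time point."""
        return _metrics.pairwise_subject_scores(self.communities, metric=metric)

    def summary(self) -> str:
        """Human-readable fit report."""
        S, T, G = self.communities.shape
        cfg = self.model.config
        k_mode = (
            f"fixed K={cfg.n_communities}"
            if cfg.n_communities is not None
            else f"adaptive (eigengap, K in [{cfg.k_min}, {cfg.k_max}))"
        )
        sim = self.subject_similarity() if S > 1 else None
        lines = [
            "MuDCoD fit",
            "=" * 46,
            f"subjects: {S}   time points: {T}   nodes: {G}",
            f"alpha (time): {cfg.alpha:g}   beta (subject): {cfg.beta:g}",
            f"model order: {k_mode}",
            f"iterations: {self.convergence.n_iter}"
            f"   converged: {self.convergence.converged}"
            f"   final delta: "
            f"{self.convergence.deltas[-1] if self.convergence.n_iter else 0.0:.3e}",
            f"communities per slice (K): min {int(self.k_grid.min())}, "
            f"median {int(np.median(self.k_grid))}, max {int(self.k_grid.max())}",
        ]
        if sim is not None and not sim.empty:
            lines.append(
                f"mean between-subject NMI: {sim['score'].mean():.3f}"
            )
        if self.convergence.degenerate_slices:
            lines.append(
                f"degenerate slices (empty/disconnected spectra): "
                f"{self.convergence.degenerate_slices}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        S, T, G = self.communities.shape
        return (
            f"<MuDCoDResults S={S} T={T} G={G} "
            f"converged={self.convergence.converged}>"
        )
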