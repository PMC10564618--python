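"""Partition agreement metrics: adjusted Rand index and normalized mutual
information, plus grid-level summaries.

Both metrics are computed from the label contingency table and are
invariant to relabeling.  They are implemented directly (a dozen lines
each) so the package carries no estimator dependency for its evaluation
arithmetic; the test suite cross-checks them against scikit-learn.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import comb

from .containers import CommunityGrid

__all__ = ["contingency", "ari", "nmi", "summarize_grid", "pairwise_subject_scores"]


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"label vectors differ in length: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] == 0:
        raise ValueError("label vectors must be non-empty")
    return a, b


def contingency(a, b) -> np.ndarray:
    """Cross-tabulation of two label vectors (rows: labels of ``a``)."""
    a, b = _check_pair(a, b)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def ari(a, b) -> float:
    """Adjusted Rand index (Hubert–Arabie): (Index - E[Index]) / (Max - E[Index]).

    1 for identical partitions, about 0 for independent ones.  The
    degenerate case where the expectation equals the maximum (e.g. both
    partitions constant, or all singletons) returns 1.
    """
    table = contingency(a, b)
    n = table.sum()
    if n < 2:
        raise ValueError("ARI needs at least 2 elements")
    sum_cells = comb(table, 2).sum()
    sum_rows = comb(table.sum(axis=1), 2).sum()
    sum_cols = comb(table.sum(axis=0), 2).sum()
    n_pairs = comb(n, 2)
    expected = sum_rows * sum_cols / n_pairs
    maximum = 0.5 * (sum_rows + sum_cols)
    if maximum == expected:
        return 1.0
    return float((sum_cells - expected) / (maximum - expected))


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log(p)))


def nmi(a, b, average: str = "arithmetic") -> float:
    """Normalized mutual information in [0, 1].

    ``average`` selects the normalization of I(a;b): ``"arithmetic"``
    (default, robust near zero-entropy partitions) divides by the mean
    of the two entropies, ``"geometric"`` by their geometric mean.  If
    either partition has zero entropy the score is 0, except when both
    are constant and identical as partitions, which scores 1.
    """
    if average not in ("arithmetic", "geometric"):
        raise ValueError("average must be 'arithmetic' or 'geometric'")
    table = contingency(a, b)
    n = table.sum()
    h_a = _entropy(table.sum(axis=1), n)
    h_b = _entropy(table.sum(axis=0), n)
    if h_a == 0.0 and h_b == 0.0:
        return 1.0  # both constant: identical as partitions
    if h_a == 0.0 or h_b == 0.0:
        return 0.0
    nz = table > 0
    p = table[nz] / n
    pa = (table.sum(axis=1) / n)[:, None]
    pb = (table.sum(axis=0) / n)[None, :]
    outer = np.broadcast_to(pa * pb, table.shape)[nz]
    mi = float(np.sum(p * np.log(p / outer)))
    denom = 0.5 * (h_a + h_b) if average == "arithmetic" else np.sqrt(h_a * h_b)
    return float(np.clip(mi / denom, 0.0, 1.0))


_METRICS = {"ari": ari, "nmi": nmi}


def _resolve_metric(metric):
    if callable(metric):
        return metric
    try:
        return _METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; use 'ari', 'nmi' or a callable")


def summarize_grid(pred: CommunityGrid, truth: CommunityGrid, metric="ari") -> dict:
    """Score every (subject, time) slice of ``pred`` against ``truth``.

    Returns a dict with a tidy per-slice table and marginal means:
    ``{"scores": DataFrame(subject, time, score), "by_subject": ...,
    "by_time": ..., "mean": float}``.
    """
    if pred.shape != truth.shape:
        raise ValueError(f"grid shapes differ: {pred.shape} vs {truth.shape}")
    fn = _resolve_metric(metric)
    S, T, _ = pred.shape
    rows = [
        {"subject": s, "time": t, "score": fn(pred[s, t], truth[s, t])}
        for s in range(S)
        for t in range(T)
    ]
    scores = pd.DataFrame(rows)
    return {
        "scores": scores,
        "by_subject": scores.groupby("subject")["score"].mean(),
        "by_time": scores.groupby("time")["score"].mean(),
        "mean": float(scores["score"].mean()),
    }


def pairwise_subject_scores(grid: CommunityGrid, metric="nmi") -> pd.DataFrame:
    """All subject-pair agreement scores per time point (no ground truth).

    Used to summarize how similar inferred modules are across subjects,
    e.g. donor-to-donor NMI at each time point.
    """
    fn = _resolve_metric(metric)
    S, T, _ = grid.shape
    rows = [
        {"time": t, "subject_a": s1, "subject_b": s2,
         "score": fn(grid[s1, t], grid[s2, t])}
        for t in range(T)
        for s1, s2 in combinations(range(S), 2)
    ]
    return pd.DataFrame(rows)
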