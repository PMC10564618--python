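"""On-disk formats: network-grid manifests, Matrix Market / TSV slices,
label tables, and correlation-matrix binarization.

A network grid is stored as one file per (subject, time) slice —
``A_s{σ}_t{τ}.mtx`` (sparse Matrix Market) or ``.tsv`` (dense) — plus a
YAML manifest recording the grid shape, the per-slice paths, optional
node names and provenance.  Label grids travel as tidy TSV with columns
``subject, time, node, community``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .containers import CommunityGrid, NetworkGrid, validate_adjacency

__all__ = [
    "binarize_top_quantile",
    "write_network_grid",
    "read_network_grid",
    "write_labels",
    "read_labels",
]

MANIFEST_NAME = "manifest.yaml"


def binarize_top_quantile(C: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Threshold a symmetric correlation matrix to its top-|r| edges.

    Ranks all unordered pairs by absolute correlation and keeps the top
    ``ceil(q * G(G-1)/2)`` as edges.  Ties at the cutoff are resolved in
    favor of the lexicographically earlier pair, making the edge count
    exact and the result deterministic.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-12):
        raise ValueError("correlation matrix must be square and symmetric")
    if not (0.0 < q <= 1.0):
        raise ValueError("q must be in (0, 1]")
    G = C.shape[0]
    rows, cols = np.triu_indices(G, k=1)
    n_keep = int(np.ceil(q * rows.shape[0]))
    strengths = np.abs(C[rows, cols])
    # stable sort on -|C|: equal strengths keep row-major (lexicographic) order
    order = np.argsort(-strengths, kind="stable")[:n_keep]
    A = np.zeros((G, G))
    A[rows[order], cols[order]] = 1.0
    return A + A.T


def _slice_name(s: int, t: int, fmt: str) -> str:
    return f"A_s{s}_t{t}.{'mtx' if fmt == 'mtx' else 'tsv'}"


def write_network_grid(
    grid: NetworkGrid, out_dir, fmt: str = "mtx", provenance: dict | None = None
) -> Path:
    """Write one file per slice plus a YAML manifest; returns the manifest path."""
    if fmt not in ("mtx", "tsv"):
        raise ValueError("fmt must be 'mtx' or 'tsv'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    S, T, G = grid.shape
    slices = {}
    for s in range(S):
        for t in range(T):
            name = _slice_name(s, t, fmt)
            if fmt == "mtx":
                scipy.io.mmwrite(
                    out / name, sp.coo_matrix(grid[s, t]), symmetry="symmetric"
                )
            else:
                np.savetxt(out / name, grid[s, t], delimiter="\t", fmt="%.10g")
            slices[f"{s},{t}"] = name
    manifest = {
        "format": fmt,
        "shape": {"subjects": S, "times": T, "nodes": G},
        "slices": slices,
        "node_names": list(grid.node_names) if grid.node_names else None,
        "provenance": provenance or {},
    }
    path = out / MANIFEST_NAME
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def read_network_grid(manifest_path) -> NetworkGrid:
    """Load a grid written by :func:`write_network_grid`; validates symmetry."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    root = manifest_path.parent
    S = manifest["shape"]["subjects"]
    T = manifest["shape"]["times"]
    G = manifest["shape"]["nodes"]
    A = np.empty((S, T, G, G))
    for s in range(S):
        for t in range(T):
            key = f"{s},{t}"
            if key not in manifest["slices"]:
                raise ValueError(f"manifest missing slice for subject {s}, time {t}")
            path = root / manifest["slices"][key]
            if not path.exists():
                raise FileNotFoundError(
                    f"slice file for subject {s}, time {t} not found: {path}"
                )
            if path.suffix == ".mtx":
                M = np.asarray(scipy.io.mmread(path).todense(), dtype=float)
            elif path.suffix == ".tsv":
                M = np.loadtxt(path, delimiter="\t", ndmin=2)
            else:
                raise ValueError(f"unknown slice format: {path.suffix}")
            if M.shape != (G, G):
                raise ValueError(
                    f"slice ({s},{t}) has shape {M.shape}, manifest says G={G}"
                )
            A[s, t] = validate_adjacency(M)
    names = manifest.get("node_names") or None
    return NetworkGrid(A, node_names=names)


def write_labels(labels: CommunityGrid, path, node_names=None) -> None:
    """Tidy TSV with columns subject, time, node, community."""
    S, T, G = labels.shape
    s_idx, t_idx, n_idx = np.meshgrid(
        np.arange(S), np.arange(T), np.arange(G), indexing="ij"
    )
    nodes = (
        [node_names[i] for i in n_idx.ravel()] if node_names else n_idx.ravel()
    )
    pd.DataFrame(
        {
            "subject": s_idx.ravel(),
            "time": t_idx.ravel(),
            "node": nodes,
            "community": labels.z.ravel(),
        }
    ).to_csv(path, sep="\t", index=False)


def read_labels(path) -> CommunityGrid:
    """Inverse of :func:`write_labels` (node order taken from the file)."""
    df = pd.read_csv(path, sep="\t")
    S = int(df["subject"].max()) + 1
    T = int(df["time"].max()) + 1
    G = len(df) // (S * T)
    if S * T * G != len(df):
        raise ValueError("label table is not a complete subject x time x node grid")
    z = np.empty((S, T, G), dtype=np.int64)
    for (s, t), sub in df.groupby(["subject", "time"]):
        if len(sub) != G:
            raise ValueError(f"slice ({s},{t}) has {len(sub)} rows, expected {G}")
        z[s, t] = sub["community"].to_numpy()
    return CommunityGrid(z)
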