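"""Structural connectivity networks from streamline endpoint records.

A connectome is represented as a symmetric, hollow (zero-diagonal),
non-negative weighted adjacency matrix over a shared node index, where nodes
are atlas ROIs and the weight of edge (i, j) is

    w_ij = n_ij * (1 / L_ij) * (2 / (V_i + V_j))

with n_ij the number of streamlines ending in ROIs i and j, L_ij their mean
length in mm, and V_i, V_j the ROI sizes in voxels.  The 1/L_ij factor
down-weights long fibers (deterministic tractography over-reconstructs them),
and 2/(V_i + V_j) corrects for residual ROI size differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "build_weighted_matrix",
    "binarize",
    "validate_streamlines",
    "STREAMLINE_COLUMNS",
]

#: Required columns of a streamline endpoint table: one row per streamline.
STREAMLINE_COLUMNS = ("roi_a", "roi_b", "length_mm")


@dataclass
class ConnectivityMatrix:
    """Symmetric, hollow, non-negative weighted adjacency over ``node_ids``.

    Parameters
    ----------
    weights
        (n, n) float array; symmetrised view of edge weights, zero diagonal.
    node_ids
        Ordered node identifiers (ROI ids).  Defaults to ``0..n-1``.
    """

    weights: np.ndarray
    node_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        bad = np.argwhere(~np.isclose(w, w.T, rtol=1e-10, atol=1e-12))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"weights must be symmetric; first asymmetric entry at ({i}, {j})"
            )
        if np.any(w < 0):
            i, j = np.argwhere(w < 0)[0]
            raise ValueError(f"weights must be non-negative; negative at ({i}, {j})")
        if np.any(np.diag(w) != 0):
            i = int(np.flatnonzero(np.diag(w))[0])
            raise ValueError(f"diagonal must be zero; non-zero at node {i}")
        self.weights = w
        if self.node_ids is None:
            self.node_ids = np.arange(w.shape[0])
        else:
            self.node_ids = np.asarray(self.node_ids)
            if self.node_ids.shape[0] != w.shape[0]:
                raise ValueError("node_ids length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def binarized(self) -> "ConnectivityMatrix":
        return binarize(self)

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, ConnectivityMatrix):
            return NotImplemented
        return np.array_equal(self.weights, other.weights) and np.array_equal(
            self.node_ids, other.node_ids
        )


def validate_streamlines(table: pd.DataFrame) -> pd.DataFrame:
    """Check a streamline endpoint table and return it with canonical columns."""
    missing = [c for c in STREAMLINE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"streamline table missing columns {missing}")
    lengths = table["length_mm"].to_numpy(dtype=float)
    if np.any(~np.isfinite(lengths)) or np.any(lengths <= 0):
        bad = int(np.flatnonzero(~(np.isfinite(lengths) & (lengths > 0)))[0])
        raise ValueError(
            f"streamline lengths must be finite and > 0 mm; offending row {bad}"
        )
    return table.loc[:, list(STREAMLINE_COLUMNS)]


def build_weighted_matrix(
    streamlines: pd.DataFrame,
    roi_sizes: dict | pd.Series,
    node_ids: np.ndarray | list | None = None,
) -> ConnectivityMatrix:
    """Build the weighted connectome from per-streamline endpoint records.

    For every unordered ROI pair (i, j) with at least one streamline,
    ``w_ij = n_ij * (1 / mean length) * (2 / (V_i + V_j))``.  Streamlines with
    both endpoints in the same ROI are dropped (the matrix is hollow).

    Parameters
    ----------
    streamlines
        DataFrame with columns ``roi_a``, ``roi_b``, ``length_mm`` (one row
        per streamline).
    roi_sizes
        Mapping ROI id -> voxel count V_i (all counts must be positive).
    node_ids
        Node order of the output matrix.  Defaults to sorted ``roi_sizes``
        keys.
    """
    sizes = pd.Series(roi_sizes, dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("all ROI voxel counts must be positive")
    if node_ids is None:
        node_ids = np.asarray(sorted(sizes.index))
    else:
        node_ids = np.asarray(node_ids)
    index = {roi: k for k, roi in enumerate(node_ids)}
    missing = set(node_ids) - set(sizes.index)
    if missing:
        raise KeyError(f"ROI ids without a voxel count: {sorted(missing)}")

    n = len(node_ids)
    w = np.zeros((n, n), dtype=float)
    if len(streamlines):
        table = validate_streamlines(streamlines)
        unknown = set(table["roi_a"]).union(table["roi_b"]) - set(index)
        if unknown:
            raise KeyError(f"streamline ROI ids not in node index: {sorted(unknown)}")
        a = table["roi_a"].map(index).to_numpy()
        b = table["roi_b"].map(index).to_numpy()
        keep = a != b  # intra-ROI streamlines carry no pairwise information
        lo, hi = np.minimum(a, b)[keep], np.maximum(a, b)[keep]
        lengths = table["length_mm"].to_numpy(dtype=float)[keep]
        if lo.size:
            pair = lo * n + hi
            order = np.argsort(pair, kind="stable")
            pair, lengths = pair[order], lengths[order]
            uniq, start, counts = np.unique(pair, return_index=True, return_counts=True)
            mean_len = np.add.reduceat(lengths, start) / counts
            i, j = uniq // n, uniq % n
            vi = sizes.loc[node_ids[i]].to_numpy()
            vj = sizes.loc[node_ids[j]].to_numpy()
            w[i, j] = counts * (1.0 / mean_len) * (2.0 / (vi + vj))
            w[j, i] = w[i, j]
    return ConnectivityMatrix(w, node_ids)


def binarize(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Unit-weight graph: 1 wherever the weighted graph has any edge."""
    return ConnectivityMatrix(
        (matrix.weights > 0).astype(float), matrix.node_ids
    )
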