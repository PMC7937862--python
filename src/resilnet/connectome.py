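"""Weighted structural connectomes and global network efficiency.

A structural connectome is represented as a symmetric matrix of streamline
counts between gray-matter atlas regions (nodes).  Streamlines are accepted
as per-streamline sets of region labels; a streamline touching regions
``{i, j, k}`` supports the connections (i,j), (i,k) and (j,k), each at most
once per streamline.  After applying a minimum-streamline threshold, global
structural network efficiency (SNE) is

    SNE = 1 / (n (n - 1)) * sum_{i != j} 1 / d_ij

where ``d_ij`` is the shortest path length between nodes i and j when each
edge with count ``w`` has length ``1 / w`` (the weighted global-efficiency
convention of Latora & Marchiori).  Unreachable pairs contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "ConnectivityMatrix",
    "EfficiencyResult",
    "ConnectomeError",
    "count_connections",
    "apply_threshold",
    "shortest_path_distances",
    "compute_sne",
    "read_counts_csv",
    "write_counts_csv",
    "read_intersections_csv",
]

DEFAULT_THRESHOLD = 3
"""Minimum number of streamlines for a connection to be retained."""


class ConnectomeError(ValueError):
    """Invalid connectome input (labels out of range, asymmetry, ...)."""


@dataclass
class ConnectivityMatrix:
    """Symmetric n x n matrix of streamline counts with zero diagonal."""

    counts: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ConnectomeError("counts must be a square matrix")
        if np.any(self.counts < 0):
            raise ConnectomeError("streamline counts must be nonnegative")
        if not np.allclose(self.counts, self.counts.T):
            raise ConnectomeError("counts must be symmetric")
        if np.any(np.diag(self.counts) != 0):
            raise ConnectomeError("diagonal must be zero (no self-connections)")
        if not self.labels:
            self.labels = list(range(1, self.counts.shape[0] + 1))
        if len(self.labels) != self.counts.shape[0]:
            raise ConnectomeError("label count does not match matrix dimension")

    @property
    def n_nodes(self) -> int:
        return self.counts.shape[0]


@dataclass
class EfficiencyResult:
    """Global efficiency of a thresholded connectome.

    ``sne`` is on the streamline-count scale (reciprocal of summed
    reciprocal-count path lengths).  ``distances`` holds the pairwise
    shortest path lengths with ``inf`` for unreachable pairs.
    """

    sne: float
    n: int
    distances: np.ndarray | None = None


def _intersections_to_sets(
    intersections: Mapping | pd.DataFrame | Iterable,
) -> Iterable[Iterable[int]]:
    if isinstance(intersections, pd.DataFrame):
        cols = list(intersections.columns)
        if len(cols) < 2:
            raise ConnectomeError(
                "long-format intersections need (streamline_id, roi_label) columns"
            )
        grouped = intersections.groupby(cols[0])[cols[1]]
        return (set(v) for _, v in grouped)
    if isinstance(intersections, Mapping):
        return (set(v) for v in intersections.values())
    return (set(v) for v in intersections)


def count_connections(
    intersections: Mapping | pd.DataFrame | Iterable,
    n_rois: int,
) -> ConnectivityMatrix:
    """Count, for every region pair, the streamlines intersecting both.

    Parameters
    ----------
    intersections
        Per-streamline ROI label sets: a mapping ``streamline_id -> labels``,
        an iterable of label collections, or a long-format DataFrame with
        ``(streamline_id, roi_label)`` columns.  Labels are 1-based atlas
        indices in ``1..n_rois``.
    n_rois
        Number of atlas regions (matrix dimension).

    A streamline increments each pair of distinct regions it touches by
    exactly one; streamlines touching fewer than two regions contribute
    nothing.
    """
    if n_rois < 2:
        raise ConnectomeError("need at least 2 ROIs")
    counts = np.zeros((n_rois, n_rois), dtype=np.int64)
    for roi_set in _intersections_to_sets(intersections):
        rois = np.fromiter(roi_set, dtype=np.int64)
        if rois.size and (rois.min() < 1 or rois.max() > n_rois):
            raise ConnectomeError(
                f"ROI label out of range 1..{n_rois}: {sorted(roi_set)}"
            )
        if rois.size < 2:
            continue
        idx = rois - 1
        ii, jj = np.meshgrid(idx, idx)
        counts[ii, jj] += 1
        counts[idx, idx] -= 1
    return ConnectivityMatrix(counts)


def apply_threshold(
    m: ConnectivityMatrix, min_streamlines: int = DEFAULT_THRESHOLD
) -> ConnectivityMatrix:
    """Zero out connections supported by fewer than ``min_streamlines``.

    Entries at or above the threshold are unchanged; the operation is
    idempotent.
    """
    if min_streamlines < 1:
        raise ConnectomeError("min_streamlines must be >= 1")
    counts = m.counts.copy()
    counts[counts < min_streamlines] = 0
    return ConnectivityMatrix(counts, labels=list(m.labels))


def shortest_path_distances(m: ConnectivityMatrix) -> np.ndarray:
    """Pairwise shortest path lengths with edge length = 1 / count.

    Returns an ``n x n`` matrix with ``inf`` for unreachable pairs and zero
    diagonal.
    """
    counts = np.asarray(m.counts, dtype=float)
    with np.errstate(divide="ignore"):
        lengths = np.where(counts > 0, 1.0 / counts, 0.0)
    graph = csr_matrix(lengths)
    return dijkstra(graph, directed=False)


def compute_sne(m: ConnectivityMatrix) -> EfficiencyResult:
    """Global structural network efficiency of a thresholded connectome.

    Averages ``1 / d_ij`` over all ordered node pairs (unreachable pairs
    contribute zero) with the ``1 / (n (n - 1))`` normalizer.  Computed on
    the full node set, not the largest connected component.
    """
    n = m.n_nodes
    if n < 2:
        raise ConnectomeError("SNE needs at least 2 nodes")
    d = shortest_path_distances(m)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    sne = float(inv.sum() / (n * (n - 1)))
    return EfficiencyResult(sne=sne, n=n, distances=d)


def read_counts_csv(path, sep: str | None = None) -> ConnectivityMatrix:
    """Read a square count matrix from CSV/TSV with a node-label header row."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[0] != df.shape[1]:
        raise ConnectomeError(
            f"matrix file is not square: {df.shape[0]} rows x {df.shape[1]} columns"
        )
    return ConnectivityMatrix(df.to_numpy(), labels=list(df.columns))


def write_counts_csv(m: ConnectivityMatrix, path, sep: str = ",") -> None:
    pd.DataFrame(m.counts, columns=[str(c) for c in m.labels]).to_csv(
        path, sep=sep, index=False
    )


def read_intersections_csv(path) -> pd.DataFrame:
    """Read long-format (streamline_id, roi_label) records."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ConnectomeError("intersections CSV needs two columns")
    return df
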