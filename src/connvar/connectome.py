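"""Connectome construction: streamline trimming, connection-probability
matrices, and density thresholding of functional matrices.

Structural matrices follow the streamline-count route: count streamlines per
ROI pair, declare pairs with fewer than 50 streamlines unconnected, and
row-normalize the remaining counts so each row holds connection
probabilities. Functional matrices are proportionally thresholded, with the
retained density chosen by cost-efficiency (global efficiency minus density).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .parcellation import Parcellation
from .synthetic import StreamlineSet

__all__ = [
    "ConnectivityMatrix",
    "TrimReport",
    "trim_streamlines",
    "build_count_matrix",
    "counts_to_probability",
    "global_efficiency",
    "cost_efficiency_curve",
    "threshold_functional",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """One subject's R x R connectome with declared semantics.

    ``semantics`` is one of ``count``, ``connection_probability``,
    ``correlation`` or ``thresholded_correlation``; the constructor enforces
    the corresponding invariants (symmetry, value range, row normalization).
    """

    values: np.ndarray
    semantics: str
    subject_id: str = ""
    modality: str = ""
    session: Optional[str] = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix must be finite")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if self.semantics == "count":
            if np.any(v < 0) or not np.allclose(v, np.round(v)):
                raise ValueError("counts must be non-negative integers")
            if not np.allclose(v, v.T):
                raise ValueError("count matrix must be symmetric")
        elif self.semantics == "connection_probability":
            if np.any(v < 0):
                raise ValueError("probabilities must be non-negative")
            sums = v.sum(axis=1)
            nz = sums > 0
            if np.any(np.abs(sums[nz] - 1.0) > 1e-9):
                raise ValueError("rows with retained connections must sum to 1")
        elif self.semantics in ("correlation", "thresholded_correlation"):
            if not np.allclose(v, v.T):
                raise ValueError("correlation matrix must be symmetric")
            if np.any(np.abs(v) > 1.0 + 1e-12):
                raise ValueError("correlations must lie in [-1, 1]")
        else:
            raise ValueError(f"unknown semantics: {self.semantics!r}")
        object.__setattr__(self, "values", v)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class TrimReport:
    """Outcome of streamline trimming for one ROI pair."""

    n_input: int
    n_kept: int
    n_discarded: int
    clusters: list  # (size, kept) per cluster

    def __post_init__(self):
        if self.n_kept + self.n_discarded != self.n_input:
            raise ValueError("kept + discarded must equal input")


def _resample_streamline(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a polyline to n_points equidistant points by arc length."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise ValueError("streamline needs at least 2 points")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return np.repeat(points[:1], n_points, axis=0)
    targets = np.linspace(0.0, total, n_points)
    out = np.empty((n_points, 3))
    for dim in range(3):
        out[:, dim] = np.interp(targets, s, points[:, dim])
    return out


def _mdf(a: np.ndarray, b: np.ndarray) -> tuple:
    """Flip-invariant mean pointwise distance; returns (distance, flipped)."""
    direct = np.linalg.norm(a - b, axis=1).mean()
    flipped = np.linalg.norm(a - b[::-1], axis=1).mean()
    return (direct, False) if direct <= flipped else (flipped, True)


def trim_streamlines(
    streams: StreamlineSet,
    threshold_mm: float = 20.0,
    min_cluster: int = 3,
    n_points: int = 12,
):
    """Remove outlier streamlines by sequential geometric clustering.

    Streamlines (all connecting one ROI pair) are resampled to ``n_points``
    equidistant points. Scanning in input order, a streamline joins the
    nearest existing cluster if its flip-invariant mean pointwise Euclidean
    distance to that cluster's centroid is at most ``threshold_mm``;
    otherwise it seeds a new cluster. Centroids are running means of
    flip-aligned resampled points. Clusters with fewer than ``min_cluster``
    members are discarded as outliers. Kept streamlines are returned in
    their original, unresampled form.
    """
    n = len(streams)
    if n == 0:
        return streams, TrimReport(0, 0, 0, [])
    resampled = [_resample_streamline(s, n_points) for s in streams.streamlines]

    centroids: list = []
    counts: list = []
    members: list = []
    for i, r in enumerate(resampled):
        best_j, best_d, best_flip = -1, np.inf, False
        for j, c in enumerate(centroids):
            d, flip = _mdf(r, c)
            if d < best_d:
                best_j, best_d, best_flip = j, d, flip
        if best_j >= 0 and best_d <= threshold_mm:
            aligned = r[::-1] if best_flip else r
            counts[best_j] += 1
            centroids[best_j] += (aligned - centroids[best_j]) / counts[best_j]
            members[best_j].append(i)
        else:
            centroids.append(r.copy())
            counts.append(1)
            members.append([i])

    kept_idx = []
    cluster_info = []
    for c_members in members:
        keep = len(c_members) >= min_cluster
        cluster_info.append((len(c_members), keep))
        if keep:
            kept_idx.extend(c_members)
    kept_idx.sort()
    kept = StreamlineSet(
        streamlines=[streams.streamlines[i] for i in kept_idx],
        endpoint_rois=[streams.endpoint_rois[i] for i in kept_idx],
    )
    report = TrimReport(
        n_input=n,
        n_kept=len(kept_idx),
        n_discarded=n - len(kept_idx),
        clusters=cluster_info,
    )
    return kept, report


def build_count_matrix(streams: StreamlineSet, parc: Parcellation) -> ConnectivityMatrix:
    """Count streamlines per ROI pair into a symmetric matrix."""
    R = parc.n_rois
    counts = np.zeros((R, R))
    for a, b in streams.endpoint_rois:
        i, j = parc.index_of(a), parc.index_of(b)
        if i == j:
            continue
        counts[i, j] += 1
        counts[j, i] += 1
    return ConnectivityMatrix(values=counts, semantics="count")


def counts_to_probability(
    counts: ConnectivityMatrix, min_streamlines: int = 50
) -> ConnectivityMatrix:
    """Threshold a count matrix and row-normalize to connection probabilities.

    Entries below ``min_streamlines`` are considered unconnected and set to
    zero; each row with a positive remaining sum is divided by that sum.
    Rows left with no retained connection stay all-zero.
    """
    if counts.semantics != "count":
        raise ValueError("input must have count semantics")
    v = counts.values.copy()
    if np.any(v < 0):
        raise ValueError("negative count")
    v[v < min_streamlines] = 0.0
    sums = v.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(sums > 0, v / sums, 0.0)
    return ConnectivityMatrix(
        values=p,
        semantics="connection_probability",
        subject_id=counts.subject_id,
        modality=counts.modality,
        session=counts.session,
    )


def global_efficiency(adj: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    ``adj`` is a binary symmetric adjacency matrix with zero diagonal; path
    lengths are unweighted hop counts and disconnected pairs contribute 0.
    """
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    n = adj.shape[0]
    if n < 2:
        return 0.0
    sp = shortest_path(csr_matrix(adj != 0), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / sp
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _binarize_top(values: np.ndarray, n_keep: int) -> np.ndarray:
    """Keep the n_keep strongest upper-triangle entries; deterministic ties.

    Ties are broken by (row, col) lexicographic order via a stable sort on
    the negated values.
    """
    R = values.shape[0]
    iu = np.triu_indices(R, k=1)
    w = values[iu]
    order = np.argsort(-w, kind="stable")
    keep = order[:n_keep]
    adj = np.zeros((R, R), dtype=int)
    adj[iu[0][keep], iu[1][keep]] = 1
    return adj + adj.T


def cost_efficiency_curve(fc: ConnectivityMatrix, densities) -> list:
    """Cost-efficiency (global efficiency minus density) over a density grid.

    At each density rho, the graph keeps the rho-fraction strongest
    off-diagonal connections (symmetric pairs treated once, ties broken by
    ROI index order). Returns a list of ``(density, cost_efficiency)`` pairs.
    """
    if fc.semantics not in ("correlation", "thresholded_correlation"):
        raise ValueError("input must be a correlation-type matrix")
    R = fc.n_rois
    n_pairs = R * (R - 1) // 2
    out = []
    for rho in densities:
        if not 0.0 < rho <= 1.0:
            raise ValueError("density must lie in (0, 1]")
        n_keep = int(round(rho * n_pairs))
        adj = _binarize_top(fc.values, n_keep)
        out.append((float(rho), global_efficiency(adj) - float(rho)))
    return out


def threshold_functional(
    fc: ConnectivityMatrix, retain_fraction: float = 0.75
) -> ConnectivityMatrix:
    """Zero out the weakest connections, retaining the strongest fraction.

    The weakest ``1 - retain_fraction`` of off-diagonal entries (symmetric
    pairs treated once, ranked by value) are set to zero; survivors keep
    their weights and symmetry is preserved.
    """
    if not 0.0 < retain_fraction <= 1.0:
        raise ValueError("retain_fraction must lie in (0, 1]")
    if fc.semantics not in ("correlation", "thresholded_correlation"):
        raise ValueError("input must be a correlation-type matrix")
    R = fc.n_rois
    n_pairs = R * (R - 1) // 2
    n_keep = int(np.ceil(retain_fraction * n_pairs))
    mask = _binarize_top(fc.values, n_keep)
    v = np.where(mask > 0, fc.values, 0.0)
    return ConnectivityMatrix(
        values=v,
        semantics="thresholded_correlation",
        subject_id=fc.subject_id,
        modality=fc.modality,
        session=fc.session,
    )
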