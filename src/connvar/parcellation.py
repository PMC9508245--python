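"""Atlas data model: ROIs, clusters, coordinates, geodesic distances.

A :class:`Parcellation` fixes the canonical ROI ordering for every matrix in
the package; all other modules index by position in this object. The synthetic
atlas lives on a sphere, so the geodesic (along-surface) distance between two
ROIs is the great-circle distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Parcellation",
    "GeodesicDistanceMatrix",
    "AtlasMapping",
    "load_parcellation",
    "save_parcellation",
    "geodesic_distances",
    "load_atlas_mapping",
    "map_to_coarse",
]

_LUT_COLUMNS = ["roi_id", "roi_name", "cluster", "size_mm2", "x", "y", "z"]


class ParcellationError(ValueError):
    """Malformed or inconsistent atlas input."""


@dataclass(frozen=True)
class Parcellation:
    """Cortical atlas: ordered ROIs grouped into macroscopic clusters.

    Parameters
    ----------
    roi_ids : array of str
        Ordered ROI identifiers; this order is the canonical axis for every
        connectivity matrix and per-ROI vector in the package.
    roi_names : array of str
        Human-readable names, same order.
    roi_size : array of float
        Surface area per ROI (mm^2 semantics); strictly positive.
    cluster_of : array of int
        Cluster label per ROI. Cluster ids are arbitrary but hashable ints.
    coords : (R, 3) array
        Cartesian coordinates on a sphere of ``radius``.
    radius : float
        Sphere radius in mm.
    resolution_tag : str
        Free-form label, e.g. ``"upsampled"`` or ``"downsampled"``.
    """

    roi_ids: np.ndarray
    roi_names: np.ndarray
    roi_size: np.ndarray
    cluster_of: np.ndarray
    coords: np.ndarray
    radius: float = 100.0
    resolution_tag: str = "custom"
    _index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        roi_ids = np.asarray(self.roi_ids, dtype=object)
        if len(set(roi_ids)) != roi_ids.size:
            raise ParcellationError("duplicate ROI ids")
        size = np.asarray(self.roi_size, dtype=float)
        if np.any(~np.isfinite(size)) or np.any(size <= 0):
            raise ParcellationError("roi_size must be finite and > 0")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (roi_ids.size, 3):
            raise ParcellationError("coords must be (R, 3)")
        norms = np.linalg.norm(coords, axis=1)
        if np.any(norms == 0):
            raise ParcellationError("zero-norm coordinate")
        if not np.allclose(norms, self.radius, rtol=1e-9):
            raise ParcellationError(
                "coordinates do not lie on the stated sphere"
            )
        object.__setattr__(self, "roi_ids", roi_ids)
        object.__setattr__(self, "roi_names", np.asarray(self.roi_names, dtype=object))
        object.__setattr__(self, "roi_size", size)
        object.__setattr__(self, "cluster_of", np.asarray(self.cluster_of))
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "_index", {r: i for i, r in enumerate(roi_ids)})

    @property
    def n_rois(self) -> int:
        return self.roi_ids.size

    @property
    def cluster_ids(self) -> np.ndarray:
        """Distinct cluster labels in order of first appearance."""
        _, idx = np.unique(self.cluster_of, return_index=True)
        return self.cluster_of[np.sort(idx)]

    @property
    def n_clusters(self) -> int:
        return self.cluster_ids.size

    def cluster_members(self, cluster) -> np.ndarray:
        """Positional indices of the ROIs in one cluster."""
        return np.flatnonzero(self.cluster_of == cluster)

    def index_of(self, roi_id) -> int:
        try:
            return self._index[roi_id]
        except KeyError:
            raise ParcellationError(f"unknown ROI id: {roi_id!r}") from None


@dataclass(frozen=True)
class GeodesicDistanceMatrix:
    """Pairwise along-surface distances (mm) between ROI centers."""

    dist: np.ndarray
    radius: float

    def __post_init__(self):
        d = np.asarray(self.dist, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ParcellationError("distance matrix must be square")
        if not np.allclose(d, d.T):
            raise ParcellationError("distance matrix must be symmetric")
        if np.any(d < 0) or np.any(np.diag(d) != 0):
            raise ParcellationError("distances must be non-negative with zero diagonal")
        if np.any(d > np.pi * self.radius * (1 + 1e-9)):
            raise ParcellationError("distance exceeds half circumference")
        object.__setattr__(self, "dist", d)


def geodesic_distances(parc: Parcellation) -> GeodesicDistanceMatrix:
    """Great-circle distance between every pair of ROI centers.

    ``dist(i, j) = radius * arccos(u_i . u_j)`` for unit vectors ``u``.
    """
    u = parc.coords / np.linalg.norm(parc.coords, axis=1, keepdims=True)
    cosang = np.clip(u @ u.T, -1.0, 1.0)
    d = parc.radius * np.arccos(cosang)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return GeodesicDistanceMatrix(dist=d, radius=parc.radius)


def load_parcellation(path, radius: float = 100.0, resolution_tag: str = "custom") -> Parcellation:
    """Read a tab-separated atlas lookup table.

    Expected header: ``roi_id roi_name cluster size_mm2 x y z``, one row per
    ROI; the file's row order becomes the canonical ROI order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"roi_id": str, "roi_name": str})
    missing = [c for c in _LUT_COLUMNS if c not in df.columns]
    if missing:
        raise ParcellationError(f"missing columns: {missing}")
    return Parcellation(
        roi_ids=df["roi_id"].to_numpy(dtype=object),
        roi_names=df["roi_name"].to_numpy(dtype=object),
        roi_size=df["size_mm2"].to_numpy(dtype=float),
        cluster_of=df["cluster"].to_numpy(),
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
        radius=radius,
        resolution_tag=resolution_tag,
    )


def save_parcellation(parc: Parcellation, path) -> None:
    """Write the lookup table read back by :func:`load_parcellation`."""
    df = pd.DataFrame(
        {
            "roi_id": parc.roi_ids,
            "roi_name": parc.roi_names,
            "cluster": parc.cluster_of,
            "size_mm2": parc.roi_size,
            "x": parc.coords[:, 0],
            "y": parc.coords[:, 1],
            "z": parc.coords[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


@dataclass(frozen=True)
class AtlasMapping:
    """Many-to-one map from a fine-resolution atlas onto a coarse one."""

    fine: Parcellation
    coarse: Parcellation
    parent_of: dict

    def __post_init__(self):
        fine_ids = set(self.fine.roi_ids)
        if set(self.parent_of) != fine_ids:
            raise ParcellationError("mapping must cover every fine ROI exactly once")
        coarse_ids = set(self.coarse.roi_ids)
        used = set(self.parent_of.values())
        if not used <= coarse_ids:
            raise ParcellationError("mapping targets unknown coarse ROI")
        if used != coarse_ids:
            raise ParcellationError("some coarse ROI has no fine constituent")


def load_atlas_mapping(path, fine: Parcellation, coarse: Parcellation) -> AtlasMapping:
    """Read a tab-separated ``fine_roi_id\tcoarse_roi_id`` table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["fine_roi_id", "coarse_roi_id"]:
        raise ParcellationError("mapping header must be fine_roi_id\tcoarse_roi_id")
    return AtlasMapping(
        fine=fine,
        coarse=coarse,
        parent_of=dict(zip(df["fine_roi_id"], df["coarse_roi_id"])),
    )


def map_to_coarse(values: np.ndarray, mapping: AtlasMapping) -> np.ndarray:
    """Aggregate a fine-atlas per-ROI map onto the coarse atlas.

    The coarse value is the size-weighted mean of its constituent fine values,
    so a constant map is conserved and the global size-weighted mean is exact.
    Missing (NaN) fine values are ignored in their parent's average.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (mapping.fine.n_rois,):
        raise ParcellationError("values must be one per fine ROI")
    num = np.zeros(mapping.coarse.n_rois)
    den = np.zeros(mapping.coarse.n_rois)
    for i, rid in enumerate(mapping.fine.roi_ids):
        if np.isnan(values[i]):
            continue
        j = mapping.coarse.index_of(mapping.parent_of[rid])
        w = mapping.fine.roi_size[i]
        num[j] += w * values[i]
        den[j] += w
    out = np.full(mapping.coarse.n_rois, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out
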