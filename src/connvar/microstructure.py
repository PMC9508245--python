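"""Connection-level white-matter microstructure and its principal components.

Seven microstructural metrics (ICVF, ODI from NODDI; FR from CHARMED; FA,
MD, AD, RD from the diffusion tensor) are sampled along streamlines per
connection, z-scored within subject, pooled across subjects and connections,
and reduced by PCA. The first two components typically capture tissue
hindrance/restriction (PC1) and tissue complexity (PC2); per-ROI component
maps average the scores over each region's retained connections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix
from .parcellation import Parcellation
from .synthetic import METRIC_NAMES, StreamlineSet

__all__ = [
    "sample_metric_along_streamlines",
    "zscore_per_subject",
    "pca_microstructure",
    "roi_pc_map",
    "PCAResult",
    "MicrostructurePCA",
]

_META_COLS = ("roi_i", "roi_j")


def _metric_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [m for m in METRIC_NAMES if m not in df.columns]
    if missing:
        raise ValueError(f"table missing metric columns: {missing}")
    return df[list(METRIC_NAMES)]


def sample_metric_along_streamlines(field, streams: StreamlineSet) -> dict:
    """Median-of-medians metric value per connection.

    ``field`` is a callable mapping an (n, 3) array of points to n scalar
    samples. Per streamline the median over its points is taken; per
    connection (ROI pair, order-insensitive) the median over its
    streamlines. Returns ``{(roi_i, roi_j): value}`` with sorted ROI pairs.
    """
    per_conn: dict = {}
    for s, (a, b) in zip(streams.streamlines, streams.endpoint_rois):
        pts = np.asarray(s, dtype=float)
        vals = np.asarray(field(pts), dtype=float)
        if vals.shape != (pts.shape[0],):
            raise ValueError("field must return one sample per point")
        if not np.all(np.isfinite(vals)):
            raise ValueError("field returned non-finite samples")
        key = tuple(sorted((a, b)))
        per_conn.setdefault(key, []).append(float(np.median(vals)))
    return {k: float(np.median(v)) for k, v in per_conn.items()}


def zscore_per_subject(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize each metric column within one subject's table.

    Columns end up with mean 0 and sample standard deviation 1 (n-1
    denominator). A zero-variance column is an error: it carries no
    comparable information and would divide by zero.
    """
    metrics = _metric_frame(table)
    sd = metrics.std(ddof=1)
    if (sd < 1e-15).any():
        bad = sd.index[sd < 1e-15].tolist()
        raise ValueError(f"zero-variance metric column(s): {bad}")
    out = table.copy()
    out[list(METRIC_NAMES)] = (metrics - metrics.mean()) / sd
    return out


@dataclass(frozen=True)
class PCAResult:
    """Loadings and explained variance of the pooled-metric PCA."""

    loadings: np.ndarray  # 7 x n_components, unit-norm columns
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # pooled rows x n_components
    sign_convention: str

    def loading_table(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=list(METRIC_NAMES), columns=cols)


def pca_microstructure(
    tables: Sequence[pd.DataFrame], n_components: int = 2
) -> PCAResult:
    """PCA of the seven metrics pooled across participants and connections.

    Rows (already z-scored per subject) are pooled and the 7 x 7 sample
    covariance is eigendecomposed. Component signs are fixed so that the FR
    loading on PC1 and the MD loading on PC2 are positive — eigenvector
    sign is arbitrary, and this anchoring matches the empirically reported
    orientation of the hindrance and complexity axes.
    """
    pooled = np.vstack([_metric_frame(t).to_numpy(dtype=float) for t in tables])
    if pooled.shape[0] <= pooled.shape[1]:
        raise ValueError("need more pooled rows than metrics")
    cov = np.cov(pooled, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    loadings = evecs[:, :n_components].copy()
    ratio = evals[:n_components] / evals.sum()

    fr = METRIC_NAMES.index("FR")
    md = METRIC_NAMES.index("MD")
    anchors = [fr, md]
    for c in range(min(n_components, 2)):
        if loadings[anchors[c], c] < 0:
            loadings[:, c] = -loadings[:, c]
    scores = pooled @ loadings
    return PCAResult(
        loadings=loadings,
        explained_variance_ratio=ratio,
        scores=scores,
        sign_convention="FR>0 on PC1, MD>0 on PC2",
    )


def roi_pc_map(
    scores: dict,
    sc: ConnectivityMatrix,
    parc: Parcellation,
) -> np.ndarray:
    """Average a per-connection score over each ROI's retained connections.

    ``scores`` maps sorted ROI-id pairs to scalars; ``sc`` (connection
    probabilities) defines which connections are retained — a connection
    counts for ROI r if either direction survived thresholding. ROIs with
    no retained scored connection are NaN.
    """
    if sc.semantics != "connection_probability":
        raise ValueError("sc must hold connection probabilities")
    R = parc.n_rois
    sums = np.zeros(R)
    counts = np.zeros(R)
    v = sc.values
    for (a, b), val in scores.items():
        i, j = parc.index_of(a), parc.index_of(b)
        if v[i, j] > 0 or v[j, i] > 0:
            sums[i] += val
            counts[i] += 1
            sums[j] += val
            counts[j] += 1
    out = np.full(R, np.nan)
    ok = counts > 0
    out[ok] = sums[ok] / counts[ok]
    return out


class MicrostructurePCA:
    """Model object: per-subject metric tables -> pooled PCA -> ROI maps.

    ``fit`` z-scores each subject's table, runs the pooled PCA, averages
    each connection's component scores across subjects, and (when given a
    connection-probability matrix) renders per-ROI PC1/PC2 maps.
    """

    def __init__(self, tables: Sequence[pd.DataFrame], parc: Optional[Parcellation] = None):
        self.tables = list(tables)
        self.parc = parc

    def fit(self, sc: Optional[ConnectivityMatrix] = None, n_components: int = 2):
        zscored = [zscore_per_subject(t) for t in self.tables]
        pca = pca_microstructure(zscored, n_components=n_components)

        # group-average score per connection, across subjects
        conn_scores = [dict() for _ in range(n_components)]
        offset = 0
        accum: dict = {}
        for t in zscored:
            n = len(t)
            block = pca.scores[offset : offset + n]
            for row, sc_row in zip(t.itertuples(index=False), block):
                key = tuple(sorted((row.roi_i, row.roi_j)))
                accum.setdefault(key, []).append(sc_row)
            offset += n
        for key, rows in accum.items():
            mean = np.mean(rows, axis=0)
            for c in range(n_components):
                conn_scores[c][key] = float(mean[c])

        maps = None
        if sc is not None and self.parc is not None:
            maps = [roi_pc_map(conn_scores[c], sc, self.parc) for c in range(n_components)]
        return MicrostructureResults(pca=pca, connection_scores=conn_scores, roi_maps=maps)


@dataclass(frozen=True)
class MicrostructureResults:
    """PCA outcome plus group-average connection scores and ROI maps."""

    pca: PCAResult
    connection_scores: list
    roi_maps: Optional[list]

    @property
    def pc1_map(self):
        return None if self.roi_maps is None else self.roi_maps[0]

    @property
    def pc2_map(self):
        return None if self.roi_maps is None or len(self.roi_maps) < 2 else self.roi_maps[1]

    def summary(self) -> str:
        evr = self.pca.explained_variance_ratio
        lines = [
            "Microstructure PCA (pooled subjects x connections)",
            "=" * 50,
            "explained variance: "
            + ", ".join(f"PC{i + 1}={v * 100:.2f}%" for i, v in enumerate(evr)),
            f"sign convention: {self.pca.sign_convention}",
            "",
            self.pca.loading_table().to_string(float_format="%.4f"),
        ]
        return "\n".join(lines)
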