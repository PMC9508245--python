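"""Inter-subject variability (ISV) of connectivity profiles.

The central statistic: for each region, the mean cosine distance between the
region's connectivity profiles (rows of the connectome) over all pairs of
subjects. Supporting machinery covers intersession correction (regressing
within-subject between-session variability out of the between-subject
distances), ROI-size regression, cluster-level aggregation, and a bootstrap
over subject-pair rows.

The module exposes both the individual operations and a statsmodels-style
model object, :class:`ConnectomeISV`, whose ``fit`` returns an
:class:`ISVResults` carrying the estimates, bootstrap distributions and a
``summary`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .parcellation import Parcellation

__all__ = [
    "cosine_distance",
    "pair_distances",
    "isv_from_pairs",
    "regress_out_covariate",
    "cluster_isv",
    "bootstrap_cluster_isv",
    "session_distances",
    "correct_intersession",
    "SubjectPairDistanceMatrix",
    "SessionDistanceMatrix",
    "RegressionFit",
    "ConnectomeISV",
    "ISVResults",
]


class ZeroVectorError(ValueError):
    """Cosine distance is undefined for an all-zero vector."""


@dataclass(frozen=True)
class SubjectPairDistanceMatrix:
    """P x R matrix of per-ROI cosine distances over all subject pairs.

    Rows are ordered lexicographically in the pair ``(m, n)`` with ``m < n``;
    ``P = N(N-1)/2``. Entries are NaN where either subject's connectivity
    row was all-zero (unconnected ROI). ``corrected`` marks matrices from
    which intersession variability has been regressed out; corrected entries
    may be negative.
    """

    dist: np.ndarray
    pair_index: list
    n_subjects: int
    corrected: bool = False

    def __post_init__(self):
        d = np.asarray(self.dist, dtype=float)
        N = self.n_subjects
        if len(self.pair_index) != N * (N - 1) // 2 or d.shape[0] != len(self.pair_index):
            raise ValueError("P must equal N(N-1)/2")
        if not self.corrected:
            with np.errstate(invalid="ignore"):
                if np.nanmin(d, initial=0.0) < -1e-12 or np.nanmax(d, initial=0.0) > 2.0 + 1e-12:
                    raise ValueError("uncorrected cosine distances must lie in [0, 2]")
        object.__setattr__(self, "dist", d)

    @property
    def n_rois(self) -> int:
        return self.dist.shape[1]


@dataclass(frozen=True)
class SessionDistanceMatrix:
    """N x R within-subject between-session cosine distances."""

    dist: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.dist, dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(d, initial=0.0) < -1e-12 or np.nanmax(d, initial=0.0) > 2.0 + 1e-12:
                raise ValueError("session distances must lie in [0, 2]")
        object.__setattr__(self, "dist", d)


@dataclass(frozen=True)
class RegressionFit:
    """Slope and intercept of an ordinary least squares fit."""

    slope: float
    intercept: float
    predictor: str = ""

    def __post_init__(self):
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("regression coefficients must be finite")


def cosine_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 minus the cosine of the angle between two vectors; in [0, 2].

    Symmetric and invariant to positive rescaling of either argument.
    Raises :class:`ZeroVectorError` for an all-zero input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("vectors must be finite")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ZeroVectorError("cosine distance undefined for a zero vector")
    return float(1.0 - (x @ y) / (nx * ny))


def _stack_cohort(cohort) -> np.ndarray:
    mats = []
    for c in cohort:
        v = c.values if hasattr(c, "values") else np.asarray(c, dtype=float)
        if hasattr(v, "to_numpy"):
            v = v.to_numpy()
        mats.append(np.asarray(v, dtype=float))
    shapes = {m.shape for m in mats}
    if len(shapes) != 1 or mats[0].ndim != 2 or mats[0].shape[0] != mats[0].shape[1]:
        raise ValueError("all connectivity matrices must share one square shape")
    return np.stack(mats)


def _roi_profiles(A: np.ndarray, r: int, exclude_self: bool) -> np.ndarray:
    """Subjects' connectivity profiles of ROI r, optionally without entry r."""
    rows = A[:, r, :]
    if exclude_self:
        rows = np.delete(rows, r, axis=1)
    return rows


def _pairwise_cosine_dist(rows: np.ndarray, iu) -> np.ndarray:
    """Cosine distances between all row pairs; NaN where a row is all-zero."""
    norms = np.linalg.norm(rows, axis=1)
    ok = norms > 0
    safe = np.where(ok, norms, 1.0)
    unit = rows / safe[:, None]
    gram = np.clip(unit @ unit.T, -1.0, 1.0)
    d = 1.0 - gram
    bad = ~ok
    d[bad, :] = np.nan
    d[:, bad] = np.nan
    return d[iu]


def pair_distances(cohort: Sequence, exclude_self: bool = True) -> SubjectPairDistanceMatrix:
    """Per-ROI cosine distance between every pair of subjects' profiles.

    For ROI ``r`` and pair ``(m, n)``, the distance between row ``r`` of the
    two subjects' matrices, with entry ``r`` removed from both rows when
    ``exclude_self`` (the self-connection is structurally zero and would add
    a shared constant coordinate). ROIs whose row is all-zero for a subject
    yield NaN for that subject's pairs.
    """
    A = _stack_cohort(cohort)
    N, R = A.shape[0], A.shape[1]
    if N < 2:
        raise ValueError("need at least 2 subjects")
    iu = np.triu_indices(N, k=1)
    P = iu[0].size
    dist = np.empty((P, R))
    for r in range(R):
        rows = _roi_profiles(A, r, exclude_self)
        dist[:, r] = _pairwise_cosine_dist(rows, iu)
    pairs = list(zip(iu[0].tolist(), iu[1].tolist()))
    return SubjectPairDistanceMatrix(dist=dist, pair_index=pairs, n_subjects=N)


def isv_from_pairs(d: SubjectPairDistanceMatrix) -> np.ndarray:
    """Per-ROI ISV: mean distance over subject pairs, ignoring NaN entries."""
    if d.dist.shape[0] < 1:
        raise ValueError("empty distance matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(d.dist, axis=0)


def regress_out_covariate(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """OLS residuals of ``values`` on an intercept plus one covariate.

    NaNs in either input are preserved as NaN in the output and excluded
    from the fit. A (near-)constant covariate degenerates to plain
    centering.
    """
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if values.shape != covariate.shape:
        raise ValueError("values and covariate must have equal length")
    ok = np.isfinite(values) & np.isfinite(covariate)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-missing entries")
    out = np.full_like(values, np.nan)
    y, x = values[ok], covariate[ok]
    if np.var(x) < 1e-12:
        out[ok] = y - y.mean()
        return out
    b1, b0 = np.polyfit(x, y, 1)
    out[ok] = y - (b1 * x + b0)
    return out


def cluster_isv(roi_isv: np.ndarray, parc: Parcellation) -> np.ndarray:
    """Unweighted mean of non-missing ROI values within each cluster."""
    roi_isv = np.asarray(roi_isv, dtype=float)
    if roi_isv.shape != (parc.n_rois,):
        raise ValueError("vector length must match the parcellation")
    out = np.full(parc.n_clusters, np.nan)
    for k, c in enumerate(parc.cluster_ids):
        vals = roi_isv[parc.cluster_members(c)]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out[k] = vals.mean()
    return out


def _residual_projector(covariate: np.ndarray) -> np.ndarray:
    """Linear operator mapping a vector to its OLS residuals on (1, cov)."""
    R = covariate.size
    if np.var(covariate) < 1e-12:
        X = np.ones((R, 1))
    else:
        X = np.column_stack([np.ones(R), covariate])
    H = X @ np.linalg.solve(X.T @ X, X.T)
    return np.eye(R) - H


def bootstrap_cluster_isv(
    d: SubjectPairDistanceMatrix,
    parc: Parcellation,
    B: int = 5000,
    seed: Optional[int] = None,
    covariate: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Bootstrap the cluster-level ISV by resampling subject-pair rows.

    Each of the B replicates resamples the P rows of the distance matrix
    with replacement and recomputes ROI-level then cluster-level ISV. When
    ``covariate`` is given (ROI size), it is regressed out of the ROI ISV
    vector inside every replicate. Returns a B x K matrix.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    P, R = d.dist.shape
    if P < 2:
        raise ValueError("need at least 2 pair rows")
    rng = np.random.default_rng(seed)
    # multiplicity matrix: counts[b, p] = times row p appears in replicate b
    idx = rng.integers(0, P, size=(B, P))
    counts = np.zeros((B, P))
    np.add.at(counts, (np.repeat(np.arange(B), P), idx.ravel()), 1.0)

    valid = np.isfinite(d.dist)
    filled = np.where(valid, d.dist, 0.0)
    sums = counts @ filled
    ns = counts @ valid.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        roi = np.where(ns > 0, sums / ns, np.nan)

    if covariate is not None:
        covariate = np.asarray(covariate, dtype=float)
        if np.all(np.isfinite(roi)):
            M = _residual_projector(covariate)
            roi = roi @ M.T
        else:
            roi = np.stack([regress_out_covariate(row, covariate) for row in roi])

    K = parc.n_clusters
    memb = np.zeros((R, K))
    for k, c in enumerate(parc.cluster_ids):
        memb[parc.cluster_members(c), k] = 1.0
    ok = np.isfinite(roi)
    num = np.where(ok, roi, 0.0) @ memb
    den = ok.astype(float) @ memb
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def session_distances(
    session1: Sequence, session2: Sequence, exclude_self: bool = True
) -> SessionDistanceMatrix:
    """Within-subject between-session cosine distance per ROI.

    The intersession variability measure: subject m's row r compared across
    the two recording sessions, with the self entry excluded as in
    :func:`pair_distances`.
    """
    A1 = _stack_cohort(session1)
    A2 = _stack_cohort(session2)
    if A1.shape != A2.shape:
        raise ValueError("sessions must contain the same subjects and ROIs")
    N, R = A1.shape[0], A1.shape[1]
    out = np.empty((N, R))
    for r in range(R):
        x = _roi_profiles(A1, r, exclude_self)
        y = _roi_profiles(A2, r, exclude_self)
        nx = np.linalg.norm(x, axis=1)
        ny = np.linalg.norm(y, axis=1)
        ok = (nx > 0) & (ny > 0)
        dot = np.einsum("ij,ij->i", x, y)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - dot / (nx * ny)
        d[~ok] = np.nan
        out[:, r] = np.clip(d, 0.0, 2.0)
    return SessionDistanceMatrix(dist=out)


def correct_intersession(
    d: SubjectPairDistanceMatrix,
    ses: SessionDistanceMatrix,
    mode: str = "pooled",
) -> tuple:
    """Regress intersession variability out of the between-subject distances.

    The predictor for pair ``(m, n)`` at ROI ``r`` is the mean of the two
    subjects' session distances at that ROI. ``pooled`` fits one OLS slope
    and intercept over all (pair, ROI) entries; ``per_roi`` fits one per ROI
    column. Residuals (which may be negative) replace the raw distances.
    Returns ``(corrected SubjectPairDistanceMatrix, RegressionFit)``; in
    per-ROI mode the fit holds the mean slope and intercept.
    """
    if mode not in ("pooled", "per_roi"):
        raise ValueError("mode must be 'pooled' or 'per_roi'")
    N = d.n_subjects
    if ses.dist.shape != (N, d.n_rois):
        raise ValueError("session matrix inconsistent with pair matrix")
    m_idx = np.array([p[0] for p in d.pair_index])
    n_idx = np.array([p[1] for p in d.pair_index])
    pred = 0.5 * (ses.dist[m_idx, :] + ses.dist[n_idx, :])

    raw = d.dist
    corrected = np.full_like(raw, np.nan)

    def _fit(y, x):
        ok = np.isfinite(y) & np.isfinite(x)
        if ok.sum() < 2 or np.var(x[ok]) < 1e-15:
            return 0.0, 0.0, ok
        b1, b0 = np.polyfit(x[ok], y[ok], 1)
        return b1, b0, ok

    if mode == "pooled":
        b1, b0, ok = _fit(raw.ravel(), pred.ravel())
        if b1 == 0.0 and b0 == 0.0:
            warnings.warn("zero predictor variance; intersession correction is a no-op")
        corrected = raw - b1 * pred - b0
        corrected[~np.isfinite(raw)] = np.nan
        fit = RegressionFit(slope=b1, intercept=b0, predictor="mean session distance")
    else:
        slopes, intercepts = [], []
        for r in range(d.n_rois):
            b1, b0, ok = _fit(raw[:, r], pred[:, r])
            corrected[:, r] = raw[:, r] - b1 * pred[:, r] - b0
            slopes.append(b1)
            intercepts.append(b0)
        fit = RegressionFit(
            slope=float(np.mean(slopes)),
            intercept=float(np.mean(intercepts)),
            predictor="mean session distance (per ROI)",
        )
    out = SubjectPairDistanceMatrix(
        dist=corrected, pair_index=d.pair_index, n_subjects=N, corrected=True
    )
    return out, fit


class ConnectomeISV:
    """Inter-subject variability model for one connectome cohort.

    Parameters
    ----------
    cohort : sequence of matrices or ConnectivityMatrix
        One connectome per subject (structural route), or session-1
        connectomes when ``session2`` is given (functional route).
    parc : Parcellation
        Atlas fixing ROI order, sizes and cluster structure.
    session2 : sequence, optional
        Second-session connectomes for the same subjects. When present, the
        fit runs the two-session pipeline: pair distances per session,
        intersession correction per session, per-session ISV, then the
        average of the two sessions' ISV vectors.
    regress_size : bool
        Regress ROI size out of the ROI-level ISV vector (default True).
    intersession : {"pooled", "per_roi", None}
        Regression scope of the intersession correction; only used with two
        sessions.
    exclude_self : bool
        Drop the self entry from each connectivity row before the cosine
        distance (default True).

    Examples
    --------
    >>> model = ConnectomeISV(prob_matrices, parc)
    >>> res = model.fit(bootstrap=5000, seed=7)
    >>> res.summary()  # doctest: +SKIP
    """

    def __init__(
        self,
        cohort,
        parc: Parcellation,
        session2=None,
        regress_size: bool = True,
        intersession: Optional[str] = "pooled",
        exclude_self: bool = True,
        modality: str = "",
    ):
        self.cohort = list(cohort)
        self.session2 = list(session2) if session2 is not None else None
        self.parc = parc
        self.regress_size = regress_size
        self.intersession = intersession
        self.exclude_self = exclude_self
        self.modality = modality
        A = _stack_cohort(self.cohort)
        if A.shape[1] != parc.n_rois:
            raise ValueError("matrix size does not match the parcellation")
        if self.session2 is not None and len(self.session2) != len(self.cohort):
            raise ValueError("both sessions must cover the same subjects")

    def fit(self, bootstrap: int = 5000, seed: Optional[int] = None) -> "ISVResults":
        parc = self.parc
        if self.session2 is None:
            d = pair_distances(self.cohort, exclude_self=self.exclude_self)
            dist_for_boot = d
            roi_raw = isv_from_pairs(d)
            ses_fit = None
        else:
            d1 = pair_distances(self.cohort, exclude_self=self.exclude_self)
            d2 = pair_distances(self.session2, exclude_self=self.exclude_self)
            ses_fit = None
            if self.intersession is not None:
                ses = session_distances(
                    self.cohort, self.session2, exclude_self=self.exclude_self
                )
                d1, ses_fit = correct_intersession(d1, ses, mode=self.intersession)
                d2, _ = correct_intersession(d2, ses, mode=self.intersession)
            roi_raw = 0.5 * (isv_from_pairs(d1) + isv_from_pairs(d2))
            dist_for_boot = SubjectPairDistanceMatrix(
                dist=0.5 * (d1.dist + d2.dist),
                pair_index=d1.pair_index,
                n_subjects=d1.n_subjects,
                corrected=d1.corrected,
            )
        if self.regress_size:
            roi_isv = regress_out_covariate(roi_raw, parc.roi_size)
            cov = parc.roi_size
        else:
            roi_isv = roi_raw
            cov = None
        clus = cluster_isv(roi_isv, parc)
        boot = None
        if bootstrap and bootstrap > 0:
            boot = bootstrap_cluster_isv(
                dist_for_boot, parc, B=bootstrap, seed=seed, covariate=cov
            )
        return ISVResults(
            model=self,
            roi_isv=roi_isv,
            roi_isv_raw=roi_raw,
            cluster_isv=clus,
            bootstrap=boot,
            pair_dist=dist_for_boot,
            intersession_fit=ses_fit,
            seed=seed,
        )


class ISVResults:
    """Fitted ISV estimates with bootstrap uncertainty.

    Attributes
    ----------
    roi_isv : per-ROI ISV after optional ROI-size regression.
    roi_isv_raw : per-ROI ISV before size regression.
    cluster_isv : per-cluster mean of ``roi_isv``.
    bootstrap : B x K matrix of resampled cluster ISVs (or None).
    pair_dist : the subject-pair distance matrix the estimates came from.
    intersession_fit : RegressionFit of the intersession correction, if run.
    """

    def __init__(
        self,
        model,
        roi_isv,
        roi_isv_raw,
        cluster_isv,
        bootstrap,
        pair_dist,
        intersession_fit,
        seed,
    ):
        self.model = model
        self.roi_isv = roi_isv
        self.roi_isv_raw = roi_isv_raw
        self.cluster_isv = cluster_isv
        self.bootstrap = bootstrap
        self.pair_dist = pair_dist
        self.intersession_fit = intersession_fit
        self.seed = seed

    def cluster_table(self) -> pd.DataFrame:
        parc = self.model.parc
        df = pd.DataFrame({"cluster": parc.cluster_ids, "isv": self.cluster_isv})
        df["n_rois"] = [parc.cluster_members(c).size for c in parc.cluster_ids]
        if self.bootstrap is not None:
            df["boot_median"] = np.nanmedian(self.bootstrap, axis=0)
            df["boot_ci_lo"] = np.nanpercentile(self.bootstrap, 2.5, axis=0)
            df["boot_ci_hi"] = np.nanpercentile(self.bootstrap, 97.5, axis=0)
        return df

    def roi_table(self) -> pd.DataFrame:
        parc = self.model.parc
        return pd.DataFrame(
            {
                "roi_id": parc.roi_ids,
                "cluster": parc.cluster_of,
                "isv": self.roi_isv,
                "isv_raw": self.roi_isv_raw,
            }
        )

    def summary(self) -> str:
        lines = [
            "Inter-subject variability of connectivity",
            "=" * 42,
            f"subjects: {self.pair_dist.n_subjects}   "
            f"pairs: {len(self.pair_dist.pair_index)}   "
            f"ROIs: {self.pair_dist.n_rois}",
            f"modality: {self.model.modality or 'unspecified'}   "
            f"intersession-corrected: {self.pair_dist.corrected}   "
            f"size-regressed: {self.model.regress_size}",
        ]
        if self.intersession_fit is not None:
            lines.append(
                f"intersession fit: slope={self.intersession_fit.slope:.4f} "
                f"intercept={self.intersession_fit.intercept:.4f}"
            )
        lines.append("")
        lines.append(self.cluster_table().to_string(index=False, float_format="%.6f"))
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<ISVResults: N={self.pair_dist.n_subjects}, "
            f"R={self.pair_dist.n_rois}, K={self.cluster_isv.size}>"
        )
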