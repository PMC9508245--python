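"""Synthetic cohorts with the statistical structure the analysis assumes.

Every generator is a pure function of its arguments and a seed: the same call
returns bit-identical output. The generators emulate, at desk scale, the
inputs the pipeline consumes —

* a spherical parcellation with contiguous clusters,
* sparse symmetric streamline-count matrices whose expected connectivity
  decays with inter-ROI distance and whose between-subject variability is
  region-dependent (``sigma(r)``),
* two-session functional correlation-type matrices with additive session
  noise ``tau``,
* cross-modally coupled cohorts in which a cluster's subject-level deviations
  are shared between modalities with strength ``kappa``,
* seven inter-correlated microstructure metrics driven by two latent factors,
* spatially autocorrelated scalar maps (Gaussian random fields on the sphere),
* small streamline bundles with planted outliers for trimming tests.

They produce matrices directly rather than simulated time series or diffusion
signal: the downstream statistics consume matrices, and direct construction
gives exact control over sigma(r), tau and kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .parcellation import Parcellation, geodesic_distances

__all__ = [
    "CohortSpec",
    "StreamlineSet",
    "make_parcellation",
    "make_sc_cohort",
    "make_meg_cohort",
    "make_coupled_cohorts",
    "make_microstructure",
    "make_sa_map",
    "make_streamline_fixture",
    "METRIC_NAMES",
    "DEFAULT_LOADINGS",
]

#: Fixed metric order for microstructure tables.
METRIC_NAMES = ("ICVF", "ODI", "FR", "FA", "MD", "AD", "RD")

#: Default 7x2 generative loadings. Signs follow the empirical pattern of a
#: "tissue hindrance" factor (positive on FR, ICVF, FA, AD; negative on ODI,
#: RD) and a "tissue complexity" factor (positive on MD, AD).
DEFAULT_LOADINGS = np.array(
    [
        #  F1     F2
        [0.36, -0.34],  # ICVF
        [-0.43, -0.31],  # ODI
        [0.42, -0.26],  # FR
        [0.48, 0.19],  # FA
        [-0.04, 0.61],  # MD
        [0.30, 0.50],  # AD
        [-0.43, 0.26],  # RD
    ]
)


@dataclass(frozen=True)
class StreamlineSet:
    """A bag of streamlines (3-D polylines, mm) with endpoint ROI labels."""

    streamlines: list
    endpoint_rois: list

    def __post_init__(self):
        for s in self.streamlines:
            s = np.asarray(s, dtype=float)
            if s.ndim != 2 or s.shape[0] < 2 or s.shape[1] != 3:
                raise ValueError("each streamline needs >= 2 finite 3-D points")
            if not np.all(np.isfinite(s)):
                raise ValueError("streamline coordinates must be finite")
        if len(self.endpoint_rois) != len(self.streamlines):
            raise ValueError("one endpoint ROI pair per streamline")

    def __len__(self):
        return len(self.streamlines)


@dataclass(frozen=True)
class CohortSpec:
    """Generative conditions for one synthetic cohort.

    ``sigma_profile`` is the per-ROI between-subject variability sigma(r);
    ``session_noise`` is the functional intersession noise scale tau.
    Subjects differ in how noisy their recordings are (head motion and SNR
    vary between people — the situation intersession correction exists
    for): subject m's own noise scale is ``tau * u_m`` with ``u_m`` uniform
    on ``[1 - spread, 1 + spread]``; ``session_noise_spread = 0`` gives
    every subject the same tau.
    ``coupling`` gives the per-cluster cross-modal coupling kappa in [0, 1];
    ``connection_lengthscale`` is the decay length (mm) of the expected
    structural connectivity with geodesic distance.
    """

    n_subjects: int
    parc: Parcellation
    sigma_profile: np.ndarray
    session_noise: float = 0.0
    session_noise_spread: float = 0.5
    n_sessions: int = 1
    coupling: dict = None
    connection_lengthscale: float = 60.0
    density: float = 0.2
    base_count: float = 2000.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        sig = np.asarray(self.sigma_profile, dtype=float)
        if sig.shape != (self.parc.n_rois,):
            raise ValueError("sigma_profile must have one entry per ROI")
        if np.any(~np.isfinite(sig)) or np.any(sig < 0):
            raise ValueError("sigma_profile must be finite and non-negative")
        if self.session_noise < 0:
            raise ValueError("session_noise (tau) must be >= 0")
        if not 0.0 <= self.session_noise_spread <= 1.0:
            raise ValueError("session_noise_spread must lie in [0, 1]")
        if self.n_sessions not in (1, 2):
            raise ValueError("n_sessions must be 1 or 2")
        if self.coupling is not None:
            clusters = set(np.asarray(self.parc.cluster_ids).tolist())
            if set(self.coupling) != clusters:
                raise ValueError("coupling must define kappa for every cluster")
            for k, v in self.coupling.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("coupling kappa must lie in [0, 1]")
        object.__setattr__(self, "sigma_profile", sig)


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Near-uniform points on a sphere via the Fibonacci (golden-angle) lattice."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return radius * pts


def _spherical_kmeans(points: np.ndarray, k: int, rng, n_iter: int = 50) -> np.ndarray:
    """Cluster unit vectors by cosine similarity with normalized-mean centroids."""
    u = points / np.linalg.norm(points, axis=1, keepdims=True)
    n = u.shape[0]
    # k-means++-style greedy seeding on chord distance
    centers = [u[rng.integers(n)]]
    for _ in range(k - 1):
        sim = np.max(np.stack([u @ c for c in centers]), axis=0)
        d2 = np.maximum(0.0, 2.0 - 2.0 * sim)
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers.append(u[rng.choice(n, p=probs)])
    centers = np.stack(centers)
    labels = np.full(n, -1, dtype=int)
    for _ in range(n_iter):
        new_labels = np.argmax(u @ centers.T, axis=1)
        # keep every cluster non-empty: hand empty clusters the point
        # farthest from its currently assigned center
        for j in range(k):
            if not np.any(new_labels == j):
                worst = np.argmin((u * centers[new_labels]).sum(axis=1))
                new_labels[worst] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            m = u[labels == j].mean(axis=0)
            nm = np.linalg.norm(m)
            if nm > 0:
                centers[j] = m / nm
    return labels


def make_parcellation(
    R: int,
    K: int = 22,
    radius: float = 100.0,
    seed: int = 0,
    median_size: float = 300.0,
    size_sd_log: float = 0.25,
    resolution_tag: str = "custom",
) -> Parcellation:
    """Synthetic atlas: R ROIs on a Fibonacci lattice, K contiguous clusters.

    Cluster labels come from spherical k-means on the lattice points, so
    clusters are spatially contiguous caps. ROI sizes are log-normal with the
    given median. Deterministic given ``seed``.
    """
    if not (R >= K >= 1):
        raise ValueError("need R >= K >= 1")
    rng = np.random.default_rng(seed)
    coords = _fibonacci_sphere(R, radius)
    if K == R:
        labels = np.arange(R)
    else:
        labels = _spherical_kmeans(coords, K, rng)
    sizes = np.exp(np.log(median_size) + size_sd_log * rng.standard_normal(R))
    ids = np.array([f"roi{i:04d}" for i in range(R)], dtype=object)
    names = np.array([f"ROI {i}" for i in range(R)], dtype=object)
    return Parcellation(
        roi_ids=ids,
        roi_names=names,
        roi_size=sizes,
        cluster_of=labels,
        coords=coords,
        radius=radius,
        resolution_tag=resolution_tag,
    )


def _pair_sigma(sigma: np.ndarray) -> np.ndarray:
    """Symmetric per-entry variability: arithmetic mean of the row sigmas."""
    return 0.5 * (sigma[:, None] + sigma[None, :])


def _symmetric_normal(rng, R: int) -> np.ndarray:
    z = rng.standard_normal((R, R))
    z = (z + z.T) / np.sqrt(2.0)
    np.fill_diagonal(z, 0.0)
    return z


def _sc_support_and_mean(spec: CohortSpec, rng) -> np.ndarray:
    """Group-mean count field mu(i,j) on a random sparse symmetric support."""
    R = spec.parc.n_rois
    d = geodesic_distances(spec.parc).dist
    mu = spec.base_count * np.exp(-d / spec.connection_lengthscale)
    iu = np.triu_indices(R, k=1)
    keep = rng.random(iu[0].size) < spec.density
    support = np.zeros((R, R), dtype=bool)
    support[iu[0][keep], iu[1][keep]] = True
    support |= support.T
    mu = np.where(support, mu, 0.0)
    np.fill_diagonal(mu, 0.0)
    return mu


def _sc_from_deviations(spec: CohortSpec, mu, z_list, rng, observation_noise):
    sig = _pair_sigma(spec.sigma_profile)
    cohort = []
    for z in z_list:
        lam = mu * np.exp(sig * z)
        if observation_noise:
            iu = np.triu_indices(spec.parc.n_rois, k=1)
            counts = np.zeros_like(lam)
            counts[iu] = rng.poisson(lam[iu])
            counts = counts + counts.T
        else:
            counts = lam
        np.fill_diagonal(counts, 0.0)
        cohort.append(counts)
    return cohort


def make_sc_cohort(spec: CohortSpec, observation_noise: bool = True) -> list:
    """Per-subject streamline-count matrices.

    Subject m's latent intensity is ``mu(i,j) * exp(s(i,j) * z_m(i,j))`` with
    ``z_m`` symmetric standard normal and ``s`` the mean of the two row
    sigmas; observed counts are Poisson-sampled per upper-triangle entry and
    mirrored, so matrices are exactly symmetric non-negative integers. With
    ``observation_noise=False`` the latent intensities are returned directly.
    """
    rng = np.random.default_rng(spec.seed)
    mu = _sc_support_and_mean(spec, rng)
    z_list = [_symmetric_normal(rng, spec.parc.n_rois) for _ in range(spec.n_subjects)]
    return _sc_from_deviations(spec, mu, z_list, rng, observation_noise)


def _meg_from_deviations(spec: CohortSpec, G, deltas, rng):
    R = spec.parc.n_rois
    tau = spec.session_noise
    # per-subject noise scale: tau * u_m, u_m ~ U[1 - spread, 1 + spread]
    u = 1.0 + spec.session_noise_spread * rng.uniform(-1.0, 1.0, size=len(deltas))
    out = []
    for delta, u_m in zip(deltas, u):
        L = G + delta
        sessions = []
        for _ in range(spec.n_sessions):
            E = _symmetric_normal(rng, R) if tau > 0 else 0.0
            S = np.tanh(L + tau * u_m * E)
            np.fill_diagonal(S, 0.0)
            sessions.append(S)
        out.append(sessions)
    return out


def make_meg_cohort(spec: CohortSpec) -> list:
    """Per-subject, per-session functional matrices in (-1, 1).

    Subject m's latent connectivity is a shared group pattern G plus a
    symmetric deviation whose scale per entry follows sigma(r); each session
    adds fresh symmetric noise of scale tau before a tanh squash (correlation
    semantics without enforcing positive semidefiniteness). Returns a list of
    per-subject lists of session matrices.
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.parc.n_rois
    G = 0.3 * _symmetric_normal(rng, R)
    sig = _pair_sigma(spec.sigma_profile)
    deltas = [sig * _symmetric_normal(rng, R) for _ in range(spec.n_subjects)]
    return _meg_from_deviations(spec, G, deltas, rng)


def make_coupled_cohorts(spec: CohortSpec, observation_noise: bool = True):
    """Structural and functional cohorts with cluster-wise shared deviations.

    The functional cohort's subject deviations mix the structural cohort's
    deviations with independent noise. The per-entry mixing weight is the
    larger of the two ROIs' cluster couplings, ``max(kappa_ci, kappa_cj)``,
    which keeps matrices symmetric while sharing a coupled cluster's whole
    rows: with kappa = 1 in one cluster and 0 elsewhere, every entry of that
    cluster's rows (and their transposes) carries the structural cohort's
    deviations. Returns ``(sc_cohort, meg_cohort)``.
    """
    if spec.coupling is None:
        raise ValueError("spec.coupling must define kappa per cluster")
    rng = np.random.default_rng(spec.seed)
    R = spec.parc.n_rois
    kappa_roi = np.array([spec.coupling[c] for c in spec.parc.cluster_of], dtype=float)
    c_entry = np.maximum(kappa_roi[:, None], kappa_roi[None, :])

    mu = _sc_support_and_mean(spec, rng)
    z_sc = [_symmetric_normal(rng, R) for _ in range(spec.n_subjects)]
    sc = _sc_from_deviations(spec, mu, z_sc, rng, observation_noise)

    G = 0.3 * _symmetric_normal(rng, R)
    sig = _pair_sigma(spec.sigma_profile)
    deltas = []
    for z in z_sc:
        w = _symmetric_normal(rng, R)
        mixed = c_entry * z + np.sqrt(np.maximum(0.0, 1.0 - c_entry**2)) * w
        deltas.append(sig * mixed)
    meg = _meg_from_deviations(spec, G, deltas, rng)
    return sc, meg


def make_microstructure(
    n_subjects: int,
    connections: Sequence,
    loadings: np.ndarray = None,
    noise_sd: float = 0.2,
    factor_sd: Sequence[float] = (1.25, 1.0),
    seed: int = 0,
):
    """Per-subject microstructure tables driven by two latent factors.

    Each connection row is ``factor_scores @ loadings.T + noise`` over the
    seven metrics (ICVF, ODI, FR, FA, MD, AD, RD in that fixed order). The
    first (hindrance) factor carries more variance than the second
    (complexity) by default — ``factor_sd`` squared gives a ~1.56 variance
    ratio, mirroring the distinct variance shares of the two empirical
    components — which also keeps the covariance eigenvalues separated so
    the factor directions are identifiable. Returns a list of pandas
    DataFrames, one per subject, with columns ``roi_i, roi_j`` plus the
    seven metrics.
    """
    import pandas as pd

    if loadings is None:
        loadings = DEFAULT_LOADINGS
    loadings = np.asarray(loadings, dtype=float)
    if loadings.shape != (7, 2) or not np.all(np.isfinite(loadings)):
        raise ValueError("loadings must be a finite 7x2 matrix")
    factor_sd = np.asarray(factor_sd, dtype=float)
    rng = np.random.default_rng(seed)
    tables = []
    conns = list(connections)
    for _ in range(n_subjects):
        scores = rng.standard_normal((len(conns), 2)) * factor_sd
        vals = scores @ loadings.T
        if noise_sd > 0:
            vals = vals + noise_sd * rng.standard_normal(vals.shape)
        df = pd.DataFrame(vals, columns=list(METRIC_NAMES))
        df.insert(0, "roi_j", [c[1] for c in conns])
        df.insert(0, "roi_i", [c[0] for c in conns])
        tables.append(df)
    return tables


def make_sa_map(parc: Parcellation, lengthscale: float, seed: int = 0) -> np.ndarray:
    """Spatially autocorrelated scalar map: a GRF with covariance exp(-d/l).

    Sampled by Cholesky factorization of the exponential covariance over the
    geodesic distance matrix (1e-8 diagonal jitter).
    """
    if lengthscale <= 0:
        raise ValueError("lengthscale must be > 0")
    d = geodesic_distances(parc).dist
    cov = np.exp(-d / lengthscale)
    cov[np.diag_indices_from(cov)] += 1e-8
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as e:
        raise ArithmeticError("covariance not positive definite after jitter") from e
    rng = np.random.default_rng(seed)
    return L @ rng.standard_normal(parc.n_rois)


def sa_map_cholesky(parc: Parcellation, lengthscale: float) -> np.ndarray:
    """Precomputed Cholesky factor for repeated GRF draws on one atlas."""
    if lengthscale <= 0:
        raise ValueError("lengthscale must be > 0")
    d = geodesic_distances(parc).dist
    cov = np.exp(-d / lengthscale)
    cov[np.diag_indices_from(cov)] += 1e-8
    return np.linalg.cholesky(cov)


def make_streamline_fixture(
    bundle_size: int,
    n_outliers: int,
    separation_mm: float,
    seed: int = 0,
    n_points: int = 20,
    jitter_sd: float = 1.0,
    roi_pair=("roiA", "roiB"),
) -> StreamlineSet:
    """One coherent bundle plus displaced outliers, for trimming tests.

    The bundle follows a gentle arc from the origin; outliers are translated
    by ``separation_mm`` perpendicular to it. Half the outliers (and every
    second bundle member) are stored with reversed point order to exercise
    flip handling.
    """
    if separation_mm <= 0:
        raise ValueError("separation_mm must be > 0")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_points)
    center = np.column_stack([80.0 * t, 10.0 * np.sin(np.pi * t), np.zeros_like(t)])
    streams, rois = [], []
    for i in range(bundle_size):
        s = center + jitter_sd * rng.standard_normal(center.shape)
        if i % 2 == 1:
            s = s[::-1]
        streams.append(s)
        rois.append(tuple(roi_pair))
    offset = np.array([0.0, 0.0, separation_mm])
    for i in range(n_outliers):
        s = center + offset + jitter_sd * rng.standard_normal(center.shape)
        if i % 2 == 1:
            s = s[::-1]
        streams.append(s)
        rois.append(tuple(roi_pair))
    return StreamlineSet(streamlines=streams, endpoint_rois=rois)
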