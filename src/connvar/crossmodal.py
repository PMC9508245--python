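"""Cross-modal alignment of inter-subject differences at the cluster level.

For each macroscopic cluster, the subject-pair distance vectors from two
modalities (e.g., structural and functional connectomes) are compared by
Spearman rank correlation: do pairs of subjects who differ more in one
modality also differ more in the other? Family-wise error over clusters is
controlled by a permutation-based maximum statistic in which subject labels
(not individual pair entries, which are dependent) are relabelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .isv import SubjectPairDistanceMatrix, regress_out_covariate
from .parcellation import Parcellation

__all__ = [
    "cluster_pair_vectors",
    "spearman",
    "crossmodal_fwe",
    "FwePermResult",
    "CrossModalCorrespondence",
]


def cluster_pair_vectors(
    d: SubjectPairDistanceMatrix,
    parc: Parcellation,
    roi_sizes: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-cluster subject-pair distance vectors, ROI size regressed out.

    For every pair row of the distance matrix, ROI size is regressed out
    across ROIs; the residuals are then averaged over each cluster's ROIs.
    Returns a K x P array (clusters in ``parc.cluster_ids`` order).
    """
    if d.n_rois != parc.n_rois:
        raise ValueError("distance matrix does not match the parcellation")
    sizes = parc.roi_size if roi_sizes is None else np.asarray(roi_sizes, dtype=float)
    P, R = d.dist.shape
    resid = np.empty_like(d.dist)
    if np.all(np.isfinite(d.dist)) and np.var(sizes) >= 1e-12:
        # one shared projector: residual operator of OLS on (1, size)
        X = np.column_stack([np.ones(R), sizes])
        H = X @ np.linalg.solve(X.T @ X, X.T)
        resid = d.dist - d.dist @ H.T
    else:
        for p in range(P):
            resid[p] = regress_out_covariate(d.dist[p], sizes)
    K = parc.n_clusters
    out = np.full((K, P), np.nan)
    for k, c in enumerate(parc.cluster_ids):
        cols = resid[:, parc.cluster_members(c)]
        ok = np.isfinite(cols)
        if ok.any():
            with np.errstate(invalid="ignore"):
                out[k] = np.nanmean(cols, axis=1)
    return out


def spearman(x: np.ndarray, y: np.ndarray) -> tuple:
    """Spearman rank correlation with a Fisher-z 95% confidence interval.

    Average ranks for ties, Pearson on the ranks; the CI uses the rank
    variance approximation ``1.06 / (n - 3)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.var(rx) == 0 or np.var(ry) == 0:
        raise ValueError("zero rank variance: correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n > 3 and abs(rho) < 1.0:
        z = np.arctanh(rho)
        se = np.sqrt(1.06 / (n - 3))
        ci = (float(np.tanh(z - 1.96 * se)), float(np.tanh(z + 1.96 * se)))
    else:
        ci = (rho, rho)
    return rho, ci


@dataclass(frozen=True)
class FwePermResult:
    """Observed cluster correlations with max-statistic FWE p-values."""

    observed: np.ndarray
    ci95: list
    p_fwe: np.ndarray
    null_max: np.ndarray
    n_perm: int
    seed: Optional[int]

    def table(self, cluster_ids=None) -> pd.DataFrame:
        ids = cluster_ids if cluster_ids is not None else np.arange(self.observed.size)
        return pd.DataFrame(
            {
                "cluster": ids,
                "rho": self.observed,
                "ci_lo": [c[0] for c in self.ci95],
                "ci_hi": [c[1] for c in self.ci95],
                "p_fwe": self.p_fwe,
            }
        )


def _rank_columns(M: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, M)


def _pearson_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between matched rows of A and B."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", A, B)
    den = np.sqrt(np.einsum("ij,ij->i", A, A) * np.einsum("ij,ij->i", B, B))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, 0.0)


def crossmodal_fwe(
    sc_vectors: np.ndarray,
    meg_vectors: np.ndarray,
    pair_index: list,
    n_subjects: int,
    n_perm: int = 10000,
    seed: Optional[int] = None,
) -> FwePermResult:
    """Cluster-wise Spearman correlations with max-statistic FWE control.

    The null relabels subjects: a random permutation ``pi`` of subject
    labels remaps one modality's pair vector entries via
    ``(m, n) -> (pi(m), pi(n))`` (Mantel-style), preserving the dependence
    between pairs that share a subject. Each permutation records the
    maximum over clusters of the absolute Spearman correlation;
    ``p_fwe(k) = (1 + #{max_b >= |rho_k|}) / (1 + n_perm)`` (two-sided).
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects for a non-trivial permutation null")
    sc_vectors = np.asarray(sc_vectors, dtype=float)
    meg_vectors = np.asarray(meg_vectors, dtype=float)
    if sc_vectors.shape != meg_vectors.shape:
        raise ValueError("both modalities must share clusters and pair index")
    K, P = sc_vectors.shape
    if len(pair_index) != P:
        raise ValueError("pair_index length mismatch")

    observed = np.empty(K)
    ci95 = []
    for k in range(K):
        rho, ci = spearman(sc_vectors[k], meg_vectors[k])
        observed[k] = rho
        ci95.append(ci)

    # ranks are permutation-stable: relabeling subjects permutes the entries
    # of a pair vector, so its ranks permute identically
    sc_ranks = _rank_columns(sc_vectors)
    meg_ranks = _rank_columns(meg_vectors)

    pair_id = np.full((n_subjects, n_subjects), -1, dtype=np.int64)
    for idx, (m, n) in enumerate(pair_index):
        pair_id[m, n] = idx
        pair_id[n, m] = idx

    rng = np.random.default_rng(seed)
    m_idx = np.array([p[0] for p in pair_index])
    n_idx = np.array([p[1] for p in pair_index])
    identity = np.arange(n_subjects)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        while True:
            perm = rng.permutation(n_subjects)
            if not np.array_equal(perm, identity):
                break
        remap = pair_id[perm[m_idx], perm[n_idx]]
        permuted = meg_ranks[:, remap]
        rhos = _pearson_rows(sc_ranks, permuted)
        null_max[b] = np.max(np.abs(rhos))

    p_fwe = (1.0 + np.sum(null_max[None, :] >= np.abs(observed)[:, None], axis=1)) / (
        1.0 + n_perm
    )
    return FwePermResult(
        observed=observed,
        ci95=ci95,
        p_fwe=p_fwe,
        null_max=null_max,
        n_perm=n_perm,
        seed=seed,
    )


class CrossModalCorrespondence:
    """Model object for the cross-modal subject-pair alignment analysis.

    Built from two subject-pair distance matrices on atlases sharing the
    same cluster structure (each modality may use its own resolution).
    ``fit`` computes per-cluster Spearman correlations with FWE-corrected
    permutation p-values and returns the :class:`FwePermResult`.
    """

    def __init__(
        self,
        sc_dist: SubjectPairDistanceMatrix,
        meg_dist: SubjectPairDistanceMatrix,
        sc_parc: Parcellation,
        meg_parc: Optional[Parcellation] = None,
    ):
        meg_parc = meg_parc if meg_parc is not None else sc_parc
        if sc_dist.pair_index != meg_dist.pair_index:
            raise ValueError("modalities must share the subject-pair index")
        if sc_parc.n_clusters != meg_parc.n_clusters:
            raise ValueError("atlases must share the cluster structure")
        self.sc_dist = sc_dist
        self.meg_dist = meg_dist
        self.sc_parc = sc_parc
        self.meg_parc = meg_parc

    def fit(self, n_perm: int = 10000, seed: Optional[int] = None) -> FwePermResult:
        sc_vec = cluster_pair_vectors(self.sc_dist, self.sc_parc)
        meg_vec = cluster_pair_vectors(self.meg_dist, self.meg_parc)
        return crossmodal_fwe(
            sc_vec,
            meg_vec,
            self.sc_dist.pair_index,
            self.sc_dist.n_subjects,
            n_perm=n_perm,
            seed=seed,
        )
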