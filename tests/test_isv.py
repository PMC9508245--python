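"""ISV estimator: cosine distances, pair matrices, correction, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connvar import (
    ConnectomeISV,
    CohortSpec,
    bootstrap_cluster_isv,
    cluster_isv,
    correct_intersession,
    cosine_distance,
    isv_from_pairs,
    make_meg_cohort,
    make_parcellation,
    pair_distances,
    regress_out_covariate,
    session_distances,
)
from connvar.isv import SubjectPairDistanceMatrix, ZeroVectorError


def brute_force_pair_distances(cohort, exclude_self=True):
    """Naive double loop over subject pairs and ROIs."""
    N = len(cohort)
    R = cohort[0].shape[0]
    rows = []
    for m in range(N):
        for n in range(m + 1, N):
            row = np.empty(R)
            for r in range(R):
                x = np.delete(cohort[m][r], r) if exclude_self else cohort[m][r]
                y = np.delete(cohort[n][r], r) if exclude_self else cohort[n][r]
                if np.linalg.norm(x) == 0 or np.linalg.norm(y) == 0:
                    row[r] = np.nan
                else:
                    row[r] = 1 - x @ y / (np.linalg.norm(x) * np.linalg.norm(y))
            rows.append(row)
    return np.array(rows)


class TestCosineDistance:
    def test_identity_orthogonality_and_formula(self):
        assert cosine_distance([1.0, 2, 3], [1.0, 2, 3]) == pytest.approx(0.0)
        assert cosine_distance([1.0, 0], [0.0, 1]) == pytest.approx(1.0)
        assert cosine_distance([1.0, 0], [1.0, 1]) == pytest.approx(1 - 1 / np.sqrt(2))

    def test_zero_vector_raises(self):
        with pytest.raises(ZeroVectorError):
            cosine_distance([0.0, 0], [1.0, 1])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=8),
        st.floats(0.1, 100),
        st.floats(0.1, 100),
    )
    def test_scale_invariance_and_symmetry(self, xs, a, b):
        x = np.asarray(xs)
        if np.linalg.norm(x) < 1e-6:
            return
        y = x[::-1].copy()
        if np.linalg.norm(y) < 1e-6:
            return
        d = cosine_distance(x, y)
        assert cosine_distance(a * x, b * y) == pytest.approx(d, abs=1e-9)
        assert cosine_distance(y, x) == pytest.approx(d, abs=1e-12)
        assert -1e-12 <= d <= 2 + 1e-12


class TestPairDistances:
    def test_identical_cohort_all_zero(self, rng):
        m = rng.random((10, 10))
        m = m + m.T
        np.fill_diagonal(m, 0)
        d = pair_distances([m, m.copy(), m.copy()])
        np.testing.assert_allclose(d.dist, 0.0, atol=1e-12)

    def test_pair_order_lexicographic(self, rng):
        cohort = [rng.random((5, 5)) for _ in range(3)]
        d = pair_distances(cohort)
        assert d.pair_index == [(0, 1), (0, 2), (1, 2)]

    @pytest.mark.parametrize("exclude_self", [True, False])
    def test_matches_brute_force_oracle(self, rng, exclude_self):
        for _ in range(10):
            N, R = rng.integers(2, 7), rng.integers(5, 30)
            cohort = [rng.random((R, R)) for _ in range(N)]
            d = pair_distances(cohort, exclude_self=exclude_self)
            expect = brute_force_pair_distances(cohort, exclude_self=exclude_self)
            np.testing.assert_allclose(d.dist, expect, atol=1e-12)

    def test_all_zero_row_flagged_missing(self, rng):
        cohort = [rng.random((6, 6)) for _ in range(3)]
        cohort[1][2, :] = 0.0
        d = pair_distances(cohort)
        # pairs containing subject 1 are missing at ROI 2
        assert np.isnan(d.dist[0, 2])  # (0,1)
        assert np.isnan(d.dist[2, 2])  # (1,2)
        assert np.isfinite(d.dist[1, 2])  # (0,2)

    def test_scale_invariance_per_subject(self, rng):
        cohort = [rng.random((8, 8)) + 0.1 for _ in range(4)]
        scaled = [c * s for c, s in zip(cohort, [0.5, 2.0, 7.0, 1.3])]
        d1 = pair_distances(cohort)
        d2 = pair_distances(scaled)
        np.testing.assert_allclose(d1.dist, d2.dist, atol=1e-12)


class TestIsvAndAggregation:
    def test_two_subjects_isv_is_the_single_pair_row(self, rng):
        cohort = [rng.random((6, 6)) for _ in range(2)]
        d = pair_distances(cohort)
        np.testing.assert_allclose(isv_from_pairs(d), d.dist[0])

    def test_mean_oracle(self, rng):
        d = SubjectPairDistanceMatrix(
            dist=rng.random((6, 9)), pair_index=[(m, n) for m in range(4) for n in range(m + 1, 4)],
            n_subjects=4,
        )
        np.testing.assert_allclose(isv_from_pairs(d), d.dist.mean(axis=0), atol=1e-12)

    def test_cluster_means_match_groupby_oracle(self, parc60, rng):
        vals = rng.random(60)
        out = cluster_isv(vals, parc60)
        for k, c in enumerate(parc60.cluster_ids):
            assert out[k] == pytest.approx(vals[parc60.cluster_members(c)].mean())

    def test_constant_map_constant_clusters(self, parc60):
        np.testing.assert_allclose(cluster_isv(np.full(60, 3.3), parc60), 3.3)


class TestRegressOut:
    def test_perfect_linear_fit_gives_zero_residuals(self, rng):
        cov = rng.random(30)
        values = 2.5 * cov - 1.0
        resid = regress_out_covariate(values, cov)
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)

    def test_constant_covariate_centers(self, rng):
        values = rng.random(20)
        resid = regress_out_covariate(values, np.full(20, 5.0))
        np.testing.assert_allclose(resid, values - values.mean(), atol=1e-12)

    def test_residuals_orthogonal_to_covariate(self, rng):
        values, cov = rng.random(50), rng.random(50)
        resid = regress_out_covariate(values, cov)
        assert abs(resid @ cov) < 1e-9 * np.linalg.norm(resid) * np.linalg.norm(cov) + 1e-9


class TestBootstrap:
    def test_determinism(self, parc60, rng):
        d = pair_distances([rng.random((60, 60)) for _ in range(6)])
        b1 = bootstrap_cluster_isv(d, parc60, B=50, seed=3)
        b2 = bootstrap_cluster_isv(d, parc60, B=50, seed=3)
        np.testing.assert_array_equal(b1, b2)
        assert b1.shape == (50, 6)

    def test_bootstrap_mean_consistent_with_observed(self, parc60):
        spec = CohortSpec(
            n_subjects=20, parc=parc60, sigma_profile=np.full(60, 0.4),
            n_sessions=1, seed=11,
        )
        cohort = [s[0] for s in make_meg_cohort(spec)]
        d = pair_distances(cohort)
        obs = cluster_isv(isv_from_pairs(d), parc60)
        boot = bootstrap_cluster_isv(d, parc60, B=2000, seed=5)
        se = boot.std(axis=0)
        assert np.all(np.abs(boot.mean(axis=0) - obs) < 3 * se)

    def test_resampled_rows_reproduce_manual_computation(self, parc60, rng):
        d = pair_distances([rng.random((60, 60)) for _ in range(4)])
        seed = 99
        boot = bootstrap_cluster_isv(d, parc60, B=1, seed=seed)
        idx = np.random.default_rng(seed).integers(0, d.dist.shape[0], size=(1, d.dist.shape[0]))
        manual_roi = d.dist[idx[0]].mean(axis=0)
        manual = cluster_isv(manual_roi, parc60)
        np.testing.assert_allclose(boot[0], manual, atol=1e-12)


class TestIntersession:
    def test_identical_sessions_zero_distance(self, rng):
        cohort = [rng.random((7, 7)) for _ in range(4)]
        ses = session_distances(cohort, [c.copy() for c in cohort])
        np.testing.assert_allclose(ses.dist, 0.0, atol=1e-12)

    def test_brute_force_oracle(self, rng):
        s1 = [rng.random((8, 8)) for _ in range(5)]
        s2 = [rng.random((8, 8)) for _ in range(5)]
        ses = session_distances(s1, s2)
        for m in range(5):
            for r in range(8):
                x = np.delete(s1[m][r], r)
                y = np.delete(s2[m][r], r)
                expect = 1 - x @ y / (np.linalg.norm(x) * np.linalg.norm(y))
                assert ses.dist[m, r] == pytest.approx(expect, abs=1e-12)

    def test_planted_slope_recovered(self, rng):
        # raw = 2*predictor + 0.1 + small noise -> fitted slope near 2
        N, R = 10, 12
        P = N * (N - 1) // 2
        ses_dist = rng.uniform(0.1, 0.9, size=(N, R))
        pairs = [(m, n) for m in range(N) for n in range(m + 1, N)]
        pred = np.array([(ses_dist[m] + ses_dist[n]) / 2 for m, n in pairs])
        raw = 2.0 * pred + 0.1 + rng.normal(scale=0.01, size=(P, R))
        d = SubjectPairDistanceMatrix(dist=raw, pair_index=pairs, n_subjects=N)
        from connvar.isv import SessionDistanceMatrix

        corrected, fit = correct_intersession(d, SessionDistanceMatrix(dist=ses_dist))
        assert 1.9 <= fit.slope <= 2.1
        # residuals orthogonal to the predictor
        dot = corrected.dist.ravel() @ pred.ravel()
        assert abs(dot) < 1e-9 * np.linalg.norm(corrected.dist) * np.linalg.norm(pred) + 1e-6

    def test_independent_predictor_preserves_isv_ordering(self, parc60):
        spec = CohortSpec(
            n_subjects=12, parc=parc60,
            sigma_profile=np.linspace(0.1, 0.6, 60),
            session_noise=0.0, n_sessions=2, seed=21,
        )
        cohort = make_meg_cohort(spec)
        s1 = [c[0] for c in cohort]
        s2 = [c[1] for c in cohort]
        d = pair_distances(s1)
        ses = session_distances(s1, s2)  # all ~0: tau=0
        with pytest.warns(UserWarning):
            corrected, fit = correct_intersession(d, ses)
        from scipy.stats import spearmanr

        raw_isv = isv_from_pairs(d)
        cor_isv = isv_from_pairs(corrected)
        assert spearmanr(raw_isv, cor_isv).statistic == pytest.approx(1.0)


class TestConnectomeISVModel:
    def test_identical_everything_gives_zero_isv(self, parc60, rng):
        m = rng.random((60, 60))
        m = m + m.T
        np.fill_diagonal(m, 0)
        cohort = [m.copy() for _ in range(4)]
        res = ConnectomeISV(cohort, parc60, session2=[m.copy() for _ in range(4)],
                            intersession=None, regress_size=False).fit(bootstrap=0)
        np.testing.assert_allclose(res.roi_isv_raw, 0.0, atol=1e-12)

    def test_session_label_swap_invariance(self, parc60):
        spec = CohortSpec(
            n_subjects=8, parc=parc60, sigma_profile=np.full(60, 0.3),
            session_noise=0.2, n_sessions=2, seed=33,
        )
        cohort = make_meg_cohort(spec)
        s1 = [c[0] for c in cohort]
        s2 = [c[1] for c in cohort]
        r12 = ConnectomeISV(s1, parc60, session2=s2).fit(bootstrap=0)
        r21 = ConnectomeISV(s2, parc60, session2=s1).fit(bootstrap=0)
        np.testing.assert_allclose(r12.roi_isv, r21.roi_isv, atol=1e-12)

    def test_summary_contains_cluster_table(self, parc60, rng):
        cohort = [rng.random((60, 60)) for _ in range(4)]
        res = ConnectomeISV(cohort, parc60).fit(bootstrap=50, seed=1)
        text = res.summary()
        assert "subjects: 4" in text and "cluster" in text

    def test_step_sigma_profile_recovered_in_corrected_isv(self, parc60):
        # low-sigma half vs high-sigma half must separate after correction
        wins = 0
        n_rep = 20
        for s in range(n_rep):
            sigma = np.where(np.arange(60) < 30, 0.1, 0.5)
            spec = CohortSpec(
                n_subjects=14, parc=parc60, sigma_profile=sigma,
                session_noise=0.3, n_sessions=2, seed=1000 + s,
            )
            cohort = make_meg_cohort(spec)
            res = ConnectomeISV(
                [c[0] for c in cohort], parc60, session2=[c[1] for c in cohort],
                regress_size=False,
            ).fit(bootstrap=0)
            if np.mean(res.roi_isv[30:]) > np.mean(res.roi_isv[:30]):
                wins += 1
        assert wins >= int(0.95 * n_rep)
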