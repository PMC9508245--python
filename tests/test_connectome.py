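"""Connectome construction: trimming, counting, normalization, thresholding."""

import numpy as np
import pytest

from connvar import (
    ConnectivityMatrix,
    StreamlineSet,
    build_count_matrix,
    cost_efficiency_curve,
    counts_to_probability,
    global_efficiency,
    make_streamline_fixture,
    threshold_functional,
    trim_streamlines,
)


def _floyd_warshall_efficiency(adj):
    """Independent oracle: dense Floyd-Warshall on hop counts."""
    n = adj.shape[0]
    INF = np.inf
    d = np.where(adj != 0, 1.0, INF)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    inv = np.zeros_like(d)
    mask = (d > 0) & np.isfinite(d)
    inv[mask] = 1.0 / d[mask]
    return inv.sum() / (n * (n - 1))


class TestTrimming:
    def test_identical_streamlines_one_cluster(self):
        pts = np.column_stack([np.linspace(0, 50, 10), np.zeros(10), np.zeros(10)])
        s = StreamlineSet(streamlines=[pts.copy() for _ in range(5)],
                         endpoint_rois=[("a", "b")] * 5)
        kept, report = trim_streamlines(s)
        assert report.n_kept == 5 and report.n_discarded == 0
        assert len(report.clusters) == 1 and report.clusters[0] == (5, True)

    def test_planted_outliers_discarded(self):
        s = make_streamline_fixture(10, 2, separation_mm=60.0, seed=3)
        kept, report = trim_streamlines(s)
        assert report.n_input == 12
        assert report.n_kept == 10
        assert report.n_discarded == 2
        # the kept streamlines are exactly the bundle (first 10 in the fixture)
        for k, orig in zip(kept.streamlines, s.streamlines[:10]):
            np.testing.assert_array_equal(np.asarray(k), np.asarray(orig))

    def test_flip_invariance_of_partition(self):
        s = make_streamline_fixture(10, 2, separation_mm=60.0, seed=3)
        flipped = StreamlineSet(
            streamlines=[np.asarray(sl)[::-1] for sl in s.streamlines],
            endpoint_rois=list(s.endpoint_rois),
        )
        _, r1 = trim_streamlines(s)
        _, r2 = trim_streamlines(flipped)
        assert [c for c in r1.clusters] == [c for c in r2.clusters]

    def test_nothing_discarded_when_all_within_threshold(self, rng):
        base = np.column_stack([np.linspace(0, 60, 12), np.zeros(12), np.zeros(12)])
        streams = [base + rng.normal(scale=1.0, size=base.shape) for _ in range(8)]
        s = StreamlineSet(streamlines=streams, endpoint_rois=[("a", "b")] * 8)
        _, report = trim_streamlines(s)
        assert report.n_discarded == 0

    def test_short_streamline_rejected(self):
        with pytest.raises(ValueError):
            StreamlineSet(streamlines=[np.array([[0.0, 0, 0]])], endpoint_rois=[("a", "b")])


class TestCountMatrix:
    def test_counts_and_conservation(self, tiny_parc, rng):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        s = StreamlineSet(
            streamlines=[pts] * 3 + [pts] * 2,
            endpoint_rois=[("r1", "r2")] * 3 + [("r0", "r4")] * 2,
        )
        m = build_count_matrix(s, tiny_parc)
        assert m.values[1, 2] == m.values[2, 1] == 3
        assert m.values[0, 4] == 2
        assert m.values.sum() == 2 * len(s)

    def test_empty_set_gives_zero_matrix(self, tiny_parc):
        m = build_count_matrix(StreamlineSet(streamlines=[], endpoint_rois=[]), tiny_parc)
        assert np.all(m.values == 0)

    def test_unknown_roi_rejected(self, tiny_parc):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        s = StreamlineSet(streamlines=[pts], endpoint_rois=[("r0", "nope")])
        with pytest.raises(Exception, match="unknown"):
            build_count_matrix(s, tiny_parc)


class TestCountsToProbability:
    def test_row_normalization_arithmetic(self):
        v = np.zeros((3, 3))
        v[0, 1], v[0, 2] = 100, 300
        v[1, 0], v[2, 0] = 100, 300
        m = counts_to_probability(ConnectivityMatrix(values=v, semantics="count"))
        assert m.values[0, 1] == pytest.approx(0.25)
        assert m.values[0, 2] == pytest.approx(0.75)

    def test_subthreshold_entry_zeroed(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 49
        v[0, 2] = v[2, 0] = 60
        m = counts_to_probability(ConnectivityMatrix(values=v, semantics="count"),
                                  min_streamlines=50)
        assert m.values[0, 1] == 0
        assert m.values[0, 2] == 1.0

    def test_all_zero_row_stays_zero(self):
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = 80
        m = counts_to_probability(ConnectivityMatrix(values=v, semantics="count"))
        assert np.all(m.values[2] == 0) and np.all(m.values[3] == 0)

    def test_idempotent_on_own_support(self):
        rng = np.random.default_rng(0)
        v = rng.integers(0, 200, size=(6, 6)).astype(float)
        v = np.triu(v, 1)
        v = v + v.T
        m = counts_to_probability(ConnectivityMatrix(values=v, semantics="count"))
        sums = m.values.sum(axis=1)
        renorm = np.where(sums[:, None] > 0, m.values / np.where(sums[:, None] > 0, sums[:, None], 1), 0)
        np.testing.assert_allclose(renorm, m.values, atol=1e-12)


class TestEfficiency:
    def test_complete_graphs_have_unit_efficiency(self):
        for n in range(3, 9):
            adj = 1 - np.eye(n, dtype=int)
            assert global_efficiency(adj) == pytest.approx(1.0)

    def test_empty_graph_zero(self):
        assert global_efficiency(np.zeros((5, 5), dtype=int)) == 0.0

    def test_path_graph_closed_form(self):
        adj = np.zeros((4, 4), dtype=int)
        for i in range(3):
            adj[i, i + 1] = adj[i + 1, i] = 1
        # unordered pairs at hops (1,1,1,2,2,3) -> (3 + 2*0.5 + 1/3) * 2 / 12
        assert global_efficiency(adj) == pytest.approx((3 + 1 + 1 / 3) / 6)

    def test_matches_floyd_warshall_oracle_on_random_graphs(self, rng):
        for _ in range(50):
            n = 12
            p = rng.uniform(0.1, 0.6)
            upper = rng.random((n, n)) < p
            adj = np.triu(upper, 1).astype(int)
            adj = adj + adj.T
            assert global_efficiency(adj) == pytest.approx(
                _floyd_warshall_efficiency(adj), abs=1e-12
            )

    def test_asymmetric_rejected(self):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = 1
        with pytest.raises(ValueError):
            global_efficiency(adj)


class TestCostEfficiency:
    def test_full_density_gives_zero(self, rng):
        v = rng.uniform(0.1, 0.9, size=(8, 8))
        v = np.triu(v, 1)
        v = v + v.T
        fc = ConnectivityMatrix(values=v, semantics="correlation")
        curve = cost_efficiency_curve(fc, [1.0])
        assert curve[0][1] == pytest.approx(0.0)

    def test_matches_brute_force_on_random_matrix(self, rng):
        n = 10
        v = rng.uniform(-1, 1, size=(n, n))
        v = np.triu(v, 1)
        v = v + v.T
        np.fill_diagonal(v, 0)
        fc = ConnectivityMatrix(values=v, semantics="correlation")
        grid = [0.1, 0.25, 0.5, 0.75, 1.0]
        curve = cost_efficiency_curve(fc, grid)
        assert len(curve) == len(grid)
        iu = np.triu_indices(n, 1)
        for rho, ce in curve:
            n_keep = int(round(rho * iu[0].size))
            order = np.argsort(-v[iu], kind="stable")[:n_keep]
            adj = np.zeros((n, n), dtype=int)
            adj[iu[0][order], iu[1][order]] = 1
            adj = adj + adj.T
            assert ce == pytest.approx(_floyd_warshall_efficiency(adj) - rho, abs=1e-12)

    def test_invalid_density_rejected(self, rng):
        fc = ConnectivityMatrix(values=np.zeros((4, 4)), semantics="correlation")
        with pytest.raises(ValueError):
            cost_efficiency_curve(fc, [0.0])


class TestThresholdFunctional:
    def test_retain_all_is_identity(self, rng):
        v = rng.uniform(-1, 1, size=(6, 6))
        v = np.triu(v, 1)
        v = v + v.T
        fc = ConnectivityMatrix(values=v, semantics="correlation")
        out = threshold_functional(fc, retain_fraction=1.0)
        np.testing.assert_array_equal(out.values, v)

    def test_exactly_strongest_half_survive(self):
        v = np.zeros((4, 4))
        vals = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]
        iu = np.triu_indices(4, 1)
        v[iu] = vals
        v = v + v.T
        fc = ConnectivityMatrix(values=v, semantics="correlation")
        out = threshold_functional(fc, retain_fraction=0.5)
        survivors = sorted(out.values[iu][out.values[iu] != 0], reverse=True)
        assert survivors == [0.9, 0.8, 0.7]
        np.testing.assert_array_equal(out.values, out.values.T)

    def test_survivor_count_without_ties(self, rng):
        n = 9
        v = rng.permutation(np.linspace(0.1, 0.9, n * (n - 1) // 2))
        m = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        m[iu] = v
        m = m + m.T
        fc = ConnectivityMatrix(values=m, semantics="correlation")
        for frac in (0.25, 0.5, 0.75):
            out = threshold_functional(fc, retain_fraction=frac)
            expected = int(np.ceil(frac * iu[0].size))
            assert np.count_nonzero(out.values[iu]) == expected

    def test_invalid_fraction_rejected(self):
        fc = ConnectivityMatrix(values=np.zeros((4, 4)), semantics="correlation")
        with pytest.raises(ValueError):
            threshold_functional(fc, retain_fraction=0.0)
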