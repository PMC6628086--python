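"""Mapper construction: lens, cover, clustering cutoff, graph assembly."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statemapper import (
    ClusterParams,
    GridPoint,
    StateSeries,
    assign_bins,
    build_cover,
    build_graph,
    cluster_bin,
    compute_filter,
    first_empty_bin_cutoff,
    reference_state,
    run_mapper,
    single_linkage_heights,
)

from .conftest import cut_dendrogram, naive_single_linkage


def _series_from_values(values, baseline_end=2):
    return StateSeries(np.asarray(values, dtype=float), baseline_end=baseline_end)


class TestReferenceState:
    def test_identical_baseline_rows(self):
        v = np.array([3.0, -1.0, 2.0])
        s = _series_from_values(np.vstack([v, v, np.zeros(3), np.ones(3)]))
        assert np.allclose(reference_state(s), v)

    def test_two_row_mean(self):
        s = _series_from_values([[0, 0], [2, 4], [9, 9], [9, 9]])
        assert np.allclose(reference_state(s), [1.0, 2.0])

    def test_matches_columnwise_sum_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(34, 5))
        s = StateSeries(vals, baseline_end=30)
        expected = np.array([vals[:30, j].sum() / 30 for j in range(5)])
        assert np.allclose(reference_state(s), expected, atol=1e-12)


class TestComputeFilter:
    def test_zero_at_reference_and_pythagorean_offset(self):
        ref = np.zeros(5)
        row = np.array([3.0, 4.0, 0.0, 0.0, 0.0])
        s = _series_from_values(np.vstack([ref, ref, row, ref]))
        f = compute_filter(s, ref)
        assert f[0] == 0.0
        assert f[2] == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(10, 4))
        ref = rng.normal(size=4)
        s = _series_from_values(vals)
        f = compute_filter(s, ref)
        for t in range(10):
            acc = sum((vals[t, v] - ref[v]) ** 2 for v in range(4))
            assert f[t] == pytest.approx(np.sqrt(acc), abs=1e-12)

    def test_dimension_mismatch_raises(self):
        s = _series_from_values(np.zeros((4, 3)))
        with pytest.raises(ValueError):
            compute_filter(s, np.zeros(5))


class TestBuildCover:
    def test_four_interval_worked_example(self):
        cover = build_cover(np.array([0.0, 9.0]), 4, 100.0 / 3.0)
        expected = [[0, 3], [2, 5], [4, 7], [6, 9]]
        assert np.allclose(cover.intervals, expected, atol=1e-9)

    def test_single_interval_spans_range(self):
        cover = build_cover(np.array([1.0, 4.0, 2.0]), 1, 30.0)
        assert np.allclose(cover.intervals, [[1.0, 4.0]])

    def test_five_interval_closed_form(self):
        cover = build_cover(np.array([0.0, 10.0]), 5, 50.0)
        third = 10.0 / 3.0
        # closed form: L = 10/3, starts at i*L*(1-g) with g = 1/2
        starts = np.array([0, 5 / 3, 10 / 3, 5, 20 / 3])
        assert np.allclose(cover.intervals[:, 0], starts, atol=1e-12)
        assert np.allclose(cover.intervals[:, 1], starts + third, atol=1e-12)

    def test_degenerate_range(self):
        cover = build_cover(np.full(5, 2.5), 4, 50.0)
        assert cover.intervals.shape == (1, 2)
        assert np.allclose(cover.intervals, [[2.5, 2.5]])

    @given(
        n=st.integers(2, 9),
        ovr=st.floats(5.0, 95.0),
        lo=st.floats(-50, 50),
        r=st.floats(0.1, 100),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_cover_properties(self, n, ovr, lo, r):
        """Equal lengths, anchored ends, exact overlap fraction, full coverage."""
        cover = build_cover(np.array([lo, lo + r]), n, ovr)
        iv = cover.intervals
        lengths = iv[:, 1] - iv[:, 0]
        assert np.allclose(lengths, lengths[0], rtol=1e-9)
        assert iv[0, 0] == pytest.approx(lo)
        assert iv[-1, 1] == pytest.approx(lo + r)
        overlaps = iv[:-1, 1] - iv[1:, 0]
        assert np.allclose(overlaps, (ovr / 100.0) * lengths[0], rtol=1e-6)
        assert np.all(iv[1:, 0] <= iv[:-1, 1] + 1e-9 * r)


class TestAssignBins:
    def test_extremes_in_terminal_bins_only(self):
        f = np.array([0.0, 9.0])
        cover = build_cover(f, 4, 100.0 / 3.0)
        bins = assign_bins(f, cover)
        memberships = [[i for i, b in enumerate(bins) if t in b] for t in (1, 2)]
        assert memberships[0] == [0]
        assert memberships[1] == [3]

    def test_shared_boundary_belongs_to_both(self):
        # range [0, 9]: intervals [0,3],[2,5],[4,7],[6,9]; f = 2 on boundary
        f = np.array([0.0, 2.0, 9.0])
        cover = build_cover(f, 4, 100.0 / 3.0)
        bins = assign_bins(f, cover)
        assert 2 in bins[0] and 2 in bins[1]

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_membership_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.uniform(0, 10, size=30)
        cover = build_cover(f, int(rng.integers(2, 8)), float(rng.uniform(20, 80)))
        bins = assign_bins(f, cover)
        covered = set()
        for i, (a, b) in enumerate(cover.intervals):
            expected = {t + 1 for t in range(30) if a - 1e-9 <= f[t] <= b + 1e-9}
            assert set(bins[i]) == expected
            covered |= expected
        assert covered == set(range(1, 31))


class TestSingleLinkageHeights:
    def test_line_point_set(self):
        pts = np.array([[0.0], [1.0], [2.0], [10.0], [11.0]])
        heights, diameter = single_linkage_heights(pts)
        assert np.allclose(heights, [1, 1, 1, 8])
        assert diameter == 11.0

    def test_two_points(self):
        heights, diameter = single_linkage_heights(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert np.allclose(heights, [5.0])
        assert diameter == 5.0

    def test_single_point(self):
        heights, diameter = single_linkage_heights(np.array([[2.0, 2.0]]))
        assert heights.size == 0 and diameter == 0.0

    def test_heights_equal_sorted_mst_edges(self):
        """Single-linkage merge heights = Euclidean MST edge weights."""
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 2))
        g = nx.Graph()
        for i, j in itertools.combinations(range(8), 2):
            g.add_edge(i, j, weight=float(np.linalg.norm(pts[i] - pts[j])))
        mst_weights = sorted(
            d["weight"] for _, _, d in nx.minimum_spanning_tree(g).edges(data=True)
        )
        heights, _ = single_linkage_heights(pts)
        assert np.allclose(heights, mst_weights, atol=1e-12)


class TestFirstEmptyBinCutoff:
    def test_hand_histogram_with_empty_bin(self):
        # bins [1,3),[3,5),[5,7),[7,9),[9,11]; counts 3,0,0,1,1 -> midpoint 4
        cutoff = first_empty_bin_cutoff(np.array([1.0, 1, 1, 8]), 11.0, 5)
        assert cutoff == pytest.approx(4.0)

    def test_degenerate_two_point_range(self):
        assert first_empty_bin_cutoff(np.array([3.0]), 3.0, 5) == np.inf

    def test_no_empty_bin_means_single_cluster(self):
        cutoff = first_empty_bin_cutoff(np.array([1.0, 3, 5, 7]), 9.0, 5)
        assert cutoff == np.inf

    def test_empty_heights(self):
        assert first_empty_bin_cutoff(np.empty(0), 0.0, 5) == np.inf

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            first_empty_bin_cutoff(np.array([1.0]), 2.0, 1)


class TestClusterBin:
    def test_line_example_splits_at_gap(self):
        vals = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [100.0]])
        s = StateSeries(vals, baseline_end=1)
        parts = cluster_bin([1, 2, 3, 4, 5], s, ClusterParams(5))
        assert parts == [(1, 2, 3), (4, 5)]

    def test_singleton_bin(self):
        s = _series_from_values(np.zeros((4, 2)))
        assert cluster_bin([3], s, ClusterParams(5)) == [(3,)]

    def test_empty_bin(self):
        s = _series_from_values(np.zeros((4, 2)))
        assert cluster_bin([], s, ClusterParams(5)) == []

    @pytest.mark.parametrize("n_bins", [5, 10])
    def test_matches_exhaustive_dendrogram_cutting(self, n_bins):
        """Partition equals brute-force single-linkage cut at the same cutoff."""
        rng = np.random.default_rng(11)
        for _ in range(40):
            n = int(rng.integers(2, 13))
            pts = rng.normal(size=(n, 2))
            s = StateSeries(np.vstack([pts, pts[:1], pts[:1]]), baseline_end=1)
            members = list(range(1, n + 1))
            heights, diameter = single_linkage_heights(pts)
            cutoff = first_empty_bin_cutoff(heights, diameter, n_bins)
            got = {frozenset(c) for c in cluster_bin(members, s, ClusterParams(n_bins))}
            if np.isinf(cutoff):
                expected = {frozenset(members)}
            else:
                expected = {
                    frozenset(i + 1 for i in c) for c in cut_dendrogram(pts, cutoff)
                }
            assert got == expected


class TestBuildGraph:
    def test_disjoint_partitions_give_no_edges(self):
        g = build_graph([[(1, 2)], [(3, 4)]], 4)
        assert g.edges == ()

    def test_shared_members_give_single_edge(self):
        a = tuple(range(1, 32))
        b = tuple(range(29, 41))
        g = build_graph([[a], [b]], 40)
        assert len(g.edges) == 1
        shared = set(a) & set(b)
        assert shared == {29, 30, 31}

    def test_edges_match_all_pairs_intersection_scan(self, planted_subject):
        series, _, _ = planted_subject
        g = run_mapper(series, GridPoint(6, 60, 10))
        sets = {n.id: set(n.members) for n in g.nodes}
        expected = {
            tuple(sorted((a, b)))
            for a, b in itertools.combinations(sets, 2)
            if sets[a] & sets[b]
        }
        assert {tuple(sorted(e)) for e in g.edges} == expected


class TestRunMapper:
    def test_noise_free_baseline_in_lowest_interval(self):
        from statemapper import SynthParams, simulate_subject

        s, _ = simulate_subject(
            SynthParams(n_channels=10, noise_sd=0.0, planted_return=63, seed=0)
        )
        ref = reference_state(s)
        f = compute_filter(s, ref)
        cover = build_cover(f, 5, 50.0)
        bins = assign_bins(f, cover)
        assert set(range(1, 31)) <= set(bins[0])

    def test_deterministic(self, planted_subject):
        series, _, _ = planted_subject
        g1 = run_mapper(series, GridPoint(5, 50, 10))
        g2 = run_mapper(series, GridPoint(5, 50, 10))
        assert g1 == g2

    def test_planted_subject_mixes_baseline_and_late_points(self):
        from statemapper import SynthParams, simulate_subject

        s, _ = simulate_subject(SynthParams(n_channels=20, planted_return=63, seed=2))
        g = run_mapper(s, GridPoint(5, 50, 10))
        assert any(
            min(n.members) <= 30 and max(n.members) > 50 for n in g.nodes
        )

    def test_coverage_and_partition_invariants(self, planted_subject, full_grid):
        series, _, _ = planted_subject
        for gp in full_grid[::5]:
            g = run_mapper(series, gp)
            covered = set()
            by_interval: dict[int, list] = {}
            for n in g.nodes:
                covered |= set(n.members)
                by_interval.setdefault(n.interval, []).append(set(n.members))
            assert covered == set(range(1, series.n_timepoints + 1))
            for clusters in by_interval.values():
                for a, b in itertools.combinations(clusters, 2):
                    assert not (a & b)

    def test_scale_equivariance(self, planted_subject):
        """Scaling all states by c scales filter/heights/cutoff, graphs unchanged."""
        series, _, _ = planted_subject
        c = 7.3
        scaled = StateSeries(
            series.values * c, series.baseline_end, series.subject, series.condition
        )
        f = compute_filter(series, reference_state(series))
        f_scaled = compute_filter(scaled, reference_state(scaled))
        assert np.allclose(f_scaled, c * f, rtol=1e-9)
        pts = series.values[40:52]
        h, d = single_linkage_heights(pts)
        h2, d2 = single_linkage_heights(pts * c)
        assert np.allclose(h2, c * h) and d2 == pytest.approx(c * d)
        assert first_empty_bin_cutoff(h2, d2, 5) == pytest.approx(
            c * first_empty_bin_cutoff(h, d, 5)
        )
        for gp in (GridPoint(5, 50, 5), GridPoint(7, 70, 10)):
            assert run_mapper(series, gp) == run_mapper(scaled, gp)

    def test_cover_monotonicity_in_overlap(self, planted_subject):
        """More overlap never decreases the number of multi-bin points."""
        series, _, _ = planted_subject
        f = compute_filter(series, reference_state(series))
        prev = -1
        for ovr in (30.0, 50.0, 70.0, 90.0):
            bins = assign_bins(f, build_cover(f, 6, ovr))
            counts = np.zeros(series.n_timepoints, dtype=int)
            for b in bins:
                counts[np.asarray(b) - 1] += 1
            multi = int((counts > 1).sum())
            assert multi >= prev
            prev = multi
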