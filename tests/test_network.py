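"""GSCC, percolation, hubs, clusters and group comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mesoflow.network import (DegreeProfile, assign_clusters, compare_groups,
                              detect_hubs, gscc, percolation_curve,
                              robustness_curves, threshold_for_analysis,
                              vertex_degrees)


def reachability_oracle_gscc(adj: np.ndarray) -> set[int]:
    """O(N^3) transitive-closure oracle for the largest SCC."""
    n = adj.shape[0]
    reach = (adj > 0) | np.eye(n, dtype=bool)
    for k in range(n):
        for i in range(n):
            if reach[i, k]:
                reach[i] |= reach[k]
    mutual = reach & reach.T
    comps = {}
    for i in range(n):
        key = frozenset(np.nonzero(mutual[i])[0].tolist())
        comps[key] = key
    return set(max(comps.values(), key=lambda s: (len(s), -min(s))))


def cycle_matrix(n: int, w: float = 1.0) -> np.ndarray:
    a = np.zeros((n, n))
    for i in range(n):
        a[i, (i + 1) % n] = w
    return a


class TestGSCC:
    def test_directed_cycle_is_fully_connected(self):
        assert gscc(cycle_matrix(7)) == set(range(7))

    def test_dag_has_singleton_gscc(self):
        a = np.triu(np.ones((6, 6)), k=1)   # acyclic
        assert len(gscc(a)) == 1

    def test_matches_transitive_closure_oracle_on_random_digraphs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(2, 7)
            adj = (rng.random((n, n)) < 0.35).astype(float)
            np.fill_diagonal(adj, 0.0)
            assert gscc(adj) == reachability_oracle_gscc(adj)

    def test_empty_graph_rejected(self):
        import networkx as nx
        with pytest.raises(ValueError):
            gscc(nx.DiGraph())


class TestPercolation:
    def test_uniform_cycle_fragments_in_one_step(self):
        curve = percolation_curve(cycle_matrix(6, w=0.4))
        np.testing.assert_array_equal(curve.thresholds, [0.0, 0.4])
        np.testing.assert_allclose(curve.gscc_fraction, [1.0, 1 / 6])
        assert curve.descent_point == 0.4

    def test_nested_cycles_make_a_stepped_curve(self):
        """Outer 6-cycle at w1, inner 3-cycle at w2 > w1: two steps with the
        descent at w1 (fractions confirmed by the reachability oracle)."""
        a = cycle_matrix(6, w=0.2)
        for i, j in [(0, 2), (2, 4), (4, 0)]:
            a[i, j] = 0.8
        curve = percolation_curve(a)
        np.testing.assert_array_equal(curve.thresholds, [0.0, 0.2, 0.8])
        np.testing.assert_allclose(curve.gscc_fraction, [1.0, 0.5, 1 / 6])
        assert curve.descent_point == 0.2
        assert curve.n_steps() == 2
        assert len(reachability_oracle_gscc(np.where(a > 0.2, a, 0))) == 3

    def test_slope_is_secant_of_descending_segment(self):
        a = cycle_matrix(6, w=0.2)
        for i, j in [(0, 2), (2, 4), (4, 0)]:
            a[i, j] = 0.8
        curve = percolation_curve(a)
        assert curve.slope == pytest.approx((0.5 - 1 / 6) / (0.8 - 0.2))
        ls = percolation_curve(a, slope_method="least-squares")
        assert ls.slope > 0

    def test_weight_hierarchy_steps_more_than_iid_weights(self):
        """Nested cycles at separated weight tiers (a connection hierarchy)
        fragment through many transitory configurations, while the same
        links and weights placed at random collapse in far fewer steps."""
        n = 12
        steps_structured, steps_null = [], []
        for sd in range(20):
            rng = np.random.default_rng(sd)
            a = np.zeros((n, n))
            for i in range(n):                       # outer ring, weak
                a[i, (i + 1) % n] = 0.3 + 0.02 * rng.random()
            mids = list(range(0, n, 2))              # middle cycle
            for k, i in enumerate(mids):
                a[i, mids[(k + 1) % len(mids)]] = 0.6 + 0.02 * rng.random()
            core = [0, 4, 8]                         # strong core cycle
            for k, i in enumerate(core):
                a[i, core[(k + 1) % len(core)]] = 0.9 + 0.02 * rng.random()
            mask = a > 0
            w = a[mask].copy()
            rng.shuffle(w)
            offdiag = [(i, j) for i in range(n) for j in range(n) if i != j]
            pos = rng.permutation(len(offdiag))[:mask.sum()]
            null = np.zeros_like(a)
            for k, p in enumerate(pos):
                null[offdiag[p]] = w[k]
            steps_structured.append(percolation_curve(a).n_steps())
            steps_null.append(percolation_curve(null).n_steps())
        assert np.mean(steps_structured) > np.mean(steps_null) + 2

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_curve_monotone_nonincreasing_with_bounded_endpoints(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        a = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
        np.fill_diagonal(a, 0.0)
        if not np.any(a > 0):
            return
        curve = percolation_curve(a)
        assert np.all(np.diff(curve.gscc_fraction) <= 0)
        assert 1 / n <= curve.gscc_fraction[-1] <= 1.0
        assert curve.gscc_fraction[0] <= 1.0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            percolation_curve(np.zeros((4, 4)))


class TestThresholdForAnalysis:
    def test_cycle_retains_all_links(self):
        a = cycle_matrix(6, w=0.4)
        curve = percolation_curve(a)
        np.testing.assert_array_equal(threshold_for_analysis(curve, a), a)

    def test_nested_cycles_both_retained(self):
        a = cycle_matrix(6, w=0.2)
        for i, j in [(0, 2), (2, 4), (4, 0)]:
            a[i, j] = 0.8
        curve = percolation_curve(a)
        np.testing.assert_array_equal(threshold_for_analysis(curve, a), a)

    def test_weak_spurious_links_pruned(self):
        """Links below the descent point (noise floor) are removed."""
        a = cycle_matrix(6, w=0.5)
        a[0, 3] = 0.01
        a[3, 1] = 0.02
        curve = percolation_curve(a)
        out = threshold_for_analysis(curve, a)
        assert out[0, 3] == 0.0 and out[3, 1] == 0.0
        assert np.count_nonzero(out) == 6


class TestDegreesAndHubs:
    def test_degree_profiles(self):
        assert vertex_degrees(np.zeros((4, 4))).n_links == 0
        full = np.ones((5, 5)) - np.eye(5)
        prof = vertex_degrees(full)
        np.testing.assert_array_equal(prof.out_degree, 4)
        hand = np.zeros((4, 4))
        hand[0, 1] = hand[0, 2] = hand[2, 3] = hand[3, 0] = 1.0
        prof = vertex_degrees(hand)
        np.testing.assert_array_equal(prof.out_degree, [2, 0, 1, 1])
        np.testing.assert_array_equal(prof.in_degree, [1, 1, 1, 1])

    def test_uniform_degrees_have_no_hubs(self):
        prof = vertex_degrees(cycle_matrix(8))
        assert detect_hubs(prof) == set()

    def test_two_sd_rule_arithmetic(self):
        """Degrees {1 x 9, 20}: mean 2.9, SD ~ 6.0, threshold ~ 14.9."""
        deg = np.array([1] * 9 + [20])
        prof = DegreeProfile(in_degree=deg.copy(), out_degree=deg.copy())
        assert deg.mean() + 2 * deg.std(ddof=1) == pytest.approx(14.92, abs=0.01)
        assert detect_hubs(prof) == {9}

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        a = (rng.random((8, 8)) < 0.3).astype(float)
        a[2, :] = 1.0
        np.fill_diagonal(a, 0.0)
        perm = rng.permutation(8)
        hubs = detect_hubs(vertex_degrees(a))
        hubs_p = detect_hubs(vertex_degrees(a[np.ix_(perm, perm)]))
        assert {int(np.nonzero(perm == h)[0][0]) for h in hubs} == hubs_p

    def test_planted_hub_recovered_with_enough_nodes(self):
        """A shared hub among 20 nodes clears the mean + 2 SD bar."""
        n = 20
        a = cycle_matrix(n, w=0.5)
        for j in range(2, n):
            a[0, j] = 0.8
        assert detect_hubs(vertex_degrees(a)) == {0}

    def test_small_graph_rejected(self):
        prof = vertex_degrees(cycle_matrix(4))
        with pytest.raises(ValueError):
            detect_hubs(prof)


class TestClusters:
    def test_disjoint_hub_sets(self):
        cl = assign_clusters({0, 1}, {2}, set(), n_nodes=6)
        assert cl.nodes("C1") == {0, 1}
        assert cl.nodes("C2") == {2}
        assert cl.nodes("C3") == set()
        assert cl.nodes("C4") == {3, 4, 5}
        assert not cl.anomalies

    def test_identical_hub_sets_all_c3(self):
        cl = assign_clusters({1, 4}, {1, 4}, {1}, n_nodes=5)
        assert cl.nodes("C3") == {1, 4}
        assert cl.nodes("C1") == set() and cl.nodes("C2") == set()

    def test_empty_hub_sets_all_c4(self):
        cl = assign_clusters(set(), set(), set(), n_nodes=4)
        assert cl.nodes("C4") == {0, 1, 2, 3}

    def test_wrong_stop_only_hub_flagged(self):
        cl = assign_clusters({0}, {1}, {0, 3}, n_nodes=5)
        assert cl.anomalies == {3}
        assert cl.labels[3] == "C4"

    def test_hub_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            assign_clusters({7}, set(), set(), n_nodes=5)


class TestRobustness:
    def _hub_graph(self):
        a = cycle_matrix(10, w=0.5)
        for j in range(2, 10):
            a[0, j] = 0.9
        return a

    def test_dominant_cluster_stays_highest(self):
        a = self._hub_graph()
        cl = assign_clusters({0}, {0}, set(), n_nodes=10)  # hub node -> C3
        df = robustness_curves(a, cl)
        for t, g in df.groupby("threshold"):
            by = g.set_index("cluster")["mean_vd_out"]
            assert by["C3"] >= by["C4"]

    def test_curves_non_increasing(self):
        a = self._hub_graph()
        cl = assign_clusters({0}, {0}, set(), n_nodes=10)
        df = robustness_curves(a, cl)
        for _, g in df.groupby("cluster"):
            v = g.sort_values("threshold")["mean_vd_out"].to_numpy()
            assert np.all(np.diff(v) <= 0)

    def test_uniform_weights_collapse_and_empty_cluster_omitted(self):
        a = cycle_matrix(6, w=0.3)
        cl = assign_clusters(set(), set(), set(), n_nodes=6)
        df = robustness_curves(a, cl)
        assert set(df["cluster"]) == {"C4"}
        assert df[df.threshold == 0.3]["mean_vd_out"].item() == 0.0

    def test_hand_computed_counts(self):
        a = np.zeros((6, 6))
        a[0, 1] = a[0, 2] = a[0, 3] = 0.9
        a[1, 0] = 0.4
        a[4, 5] = a[5, 4] = 0.2
        cl = assign_clusters({0}, set(), set(), n_nodes=6)
        df = robustness_curves(a, cl).set_index(["threshold", "cluster"])
        assert df.loc[(0.0, "C1"), "mean_vd_out"] == 3.0
        assert df.loc[(0.0, "C4"), "mean_vd_out"] == pytest.approx(3 / 5)
        assert df.loc[(0.4, "C1"), "mean_vd_out"] == 3.0
        assert df.loc[(0.4, "C4"), "mean_vd_out"] == 0.0


class TestCompareGroups:
    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": np.arange(5.0)})

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(2)
        out = compare_groups({
            "go": rng.normal(0, 1, 40),
            "stop": rng.normal(2, 1, 40),
        })
        assert out["significant"]
        assert out["pairwise"][0]["p_adjusted"] < 0.01

    def test_null_calibration(self):
        """Identical groups: rejection rate stays near alpha."""
        rejections = 0
        n_sims = 200
        for sd in range(n_sims):
            rng = np.random.default_rng(sd)
            groups = {k: rng.normal(0, 1, 25) for k in ("a", "b", "c")}
            rejections += compare_groups(groups, alpha=0.05)["p"] < 0.05
        assert 0.005 <= rejections / n_sims <= 0.12
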