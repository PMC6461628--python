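import numpy as np
import pytest
from scipy import stats

from inflamnet import (
    TimeWindow,
    build_network,
    complexity_trajectory,
    edges_frame,
    focus_subnetwork,
    negative_fraction,
    network_complexity,
    total_connections,
)
from conftest import make_panel, net_from_edges

WINDOW = TimeWindow("w", 0, 100)


def brute_force_edges(values: np.ndarray, mediators, stringency, min_pairs):
    """Independent all-pairs Pearson scan over pooled (subject, time) samples.

    ``values`` is (subjects, times, mediators); rows are pooled, NaN-aware.
    """
    flat = values.reshape(-1, values.shape[-1])
    edges = {}
    for i in range(len(mediators)):
        for j in range(i + 1, len(mediators)):
            both = ~np.isnan(flat[:, i]) & ~np.isnan(flat[:, j])
            if both.sum() < max(min_pairs, 2):
                continue
            a, b = flat[both, i], flat[both, j]
            if a.min() == a.max() or b.min() == b.max():
                continue
            r = stats.pearsonr(a, b).statistic
            if abs(r) >= stringency:
                edges[frozenset((mediators[i], mediators[j]))] = np.sign(r)
    return edges


def signed_edge_set(net):
    return {
        frozenset((u, v)): (1.0 if d["sign"] == "+" else -1.0)
        for u, v, d in net.graph.edges(data=True)
    }


class TestBuildNetwork:
    def test_identical_trajectories_give_positive_unit_edge(self):
        seq = [1.0, 3.0, 2.0, 5.0]
        vals = np.stack([np.array(seq), np.array(seq)], axis=-1)[None, :, :]
        net = build_network(make_panel(vals), "g", WINDOW)
        assert signed_edge_set(net) == {frozenset(("M0", "M1")): 1.0}
        assert net.graph.edges["M0", "M1"]["r"] == pytest.approx(1.0)

    def test_anti_correlated_pair_gives_negative_edge(self):
        a = np.array([1.0, 3.0, 2.0, 5.0])
        vals = np.stack([a, 10.0 - a], axis=-1)[None, :, :]
        net = build_network(make_panel(vals), "g", WINDOW)
        assert signed_edge_set(net) == {frozenset(("M0", "M1")): -1.0}
        assert net.graph.edges["M0", "M1"]["r"] == pytest.approx(-1.0)

    def test_constant_vector_yields_no_edge(self):
        vals = np.stack(
            [np.ones(5), np.array([1.0, 2, 3, 4, 5])], axis=-1
        )[None, :, :]
        net = build_network(make_panel(vals), "g", WINDOW)
        assert net.edge_count == 0

    def test_min_pairs_blocks_short_vectors(self):
        seq = np.array([1.0, 3.0, 2.0])
        vals = np.stack([seq, seq], axis=-1)[None, :, :]
        panel = make_panel(vals)
        assert build_network(panel, "g", WINDOW, min_pairs=4).edge_count == 0
        assert build_network(panel, "g", WINDOW, min_pairs=3).edge_count == 1

    def test_unknown_group_is_error(self):
        panel = make_panel(np.ones((1, 4, 2)))
        with pytest.raises(ValueError, match="nope"):
            build_network(panel, "nope", WINDOW)

    def test_fewer_than_two_mediators_is_error(self):
        panel = make_panel(np.ones((1, 4, 1)))
        with pytest.raises(ValueError, match="2 mediators"):
            build_network(panel, "g", WINDOW)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_med = int(rng.integers(3, 9))
        n_obs = int(rng.integers(4, 13))
        vals = rng.lognormal(mean=2.0, sigma=1.0, size=(1, n_obs, n_med))
        vals[rng.random(vals.shape) < 0.15] = np.nan
        panel = make_panel(vals)
        net = build_network(panel, "g", WINDOW, stringency=0.7, min_pairs=4)
        expected = brute_force_edges(vals, panel.mediators, 0.7, 4)
        assert signed_edge_set(net) == expected


class TestInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(100 + seed)
        vals = rng.lognormal(sigma=1.0, size=(2, 6, 6))
        panel = make_panel(vals)
        edges = {
            s: set(signed_edge_set(build_network(panel, "g", WINDOW, stringency=s)))
            for s in (0.5, 0.7, 0.9)
        }
        assert edges[0.9] <= edges[0.7] <= edges[0.5]

    @pytest.mark.parametrize("seed", range(8))
    def test_relabeling_invariance(self, seed):
        rng = np.random.default_rng(200 + seed)
        vals = rng.lognormal(sigma=1.0, size=(3, 5, 5))
        panel = make_panel(vals)
        base = build_network(panel, "g", WINDOW)
        perm_m = rng.permutation(5)
        perm_s = rng.permutation(3)
        shuffled = make_panel(
            vals[perm_s][:, :, perm_m], mediators=[f"M{k}" for k in perm_m]
        )
        permuted = build_network(shuffled, "g", WINDOW)
        assert signed_edge_set(permuted) == signed_edge_set(base)
        assert network_complexity(permuted) == network_complexity(base)

    @pytest.mark.parametrize("seed", range(8))
    def test_degree_sum_identity(self, seed):
        rng = np.random.default_rng(300 + seed)
        panel = make_panel(rng.lognormal(sigma=1.0, size=(2, 6, 7)))
        net = build_network(panel, "g", WINDOW, stringency=0.5)
        assert network_complexity(net) * (net.n - 1) == 2 * net.edge_count

    @pytest.mark.parametrize("seed", range(5))
    def test_negating_one_mediator_flips_only_its_edges(self, seed):
        rng = np.random.default_rng(400 + seed)
        vals = rng.normal(size=(2, 6, 5)) + 10.0
        base = signed_edge_set(build_network(make_panel(vals), "g", WINDOW, stringency=0.5))
        flipped_vals = vals.copy()
        flipped_vals[:, :, 0] = 20.0 - flipped_vals[:, :, 0]  # reflect M0's pattern
        flipped = signed_edge_set(
            build_network(make_panel(flipped_vals), "g", WINDOW, stringency=0.5)
        )
        assert set(flipped) == set(base)
        for pair, sign in base.items():
            expected = -sign if "M0" in pair else sign
            assert flipped[pair] == expected


class TestComplexity:
    def test_single_edge_on_three_nodes(self):
        net = net_from_edges(["A", "B", "C"], [("A", "B", "+")])
        assert network_complexity(net) == 1.0  # (1 + 1 + 0) / 2

    def test_empty_network_is_zero(self):
        net = net_from_edges(["A", "B", "C", "D"], [])
        assert network_complexity(net) == 0.0

    def test_complete_graph_on_four(self):
        edges = [("A", "B", "+"), ("A", "C", "+"), ("A", "D", "+"),
                 ("B", "C", "+"), ("B", "D", "+"), ("C", "D", "+")]
        net = net_from_edges(list("ABCD"), edges)
        assert network_complexity(net) == 4.0  # degree sum 12 over n-1 = 3

    def test_fewer_than_two_mediators_is_error(self):
        net = net_from_edges(["A"], [])
        with pytest.raises(ValueError):
            network_complexity(net)


class TestTrajectory:
    def test_one_point_per_window(self):
        panel = make_panel(np.random.default_rng(0).lognormal(size=(3, 8, 4)))
        schedule = [TimeWindow(f"d{i}-{i+1}", i, i + 1) for i in range(7)]
        traj, nets = complexity_trajectory(panel, "g", schedule)
        assert len(traj.points) == 7 and len(nets) == 7
        assert [p[0] for p in traj.points] == [w.label for w in schedule]

    def test_all_missing_group_gives_zero_trajectory(self):
        panel = make_panel(np.full((2, 4, 3), np.nan))
        traj, _ = complexity_trajectory(panel, "g", [TimeWindow("w", 0, 3)])
        assert all(c == 0.0 and e == 0 for _, c, e in traj.points)

    def test_empty_schedule_is_error(self):
        panel = make_panel(np.ones((1, 2, 2)))
        with pytest.raises(ValueError):
            complexity_trajectory(panel, "g", [])


class TestAggregates:
    def test_total_connections_sums_windows(self):
        counts = [3, 5, 0, 2, 1, 0, 4]
        nets = [
            net_from_edges(
                [f"M{k}" for k in range(8)],
                [("M0", f"M{k + 1}", "+") for k in range(c)],
                label=f"w{i}",
            )
            for i, c in enumerate(counts)
        ]
        assert total_connections(nets) == 15

    def test_single_empty_window(self):
        assert total_connections([net_from_edges(["A", "B"], [])]) == 0

    def test_all_positive_set(self):
        nets = [net_from_edges(list("ABC"), [("A", "B", "+"), ("B", "C", "+")])]
        assert negative_fraction(nets) == (0, 2, 0.0)

    def test_zero_total_flagged(self):
        neg, tot, frac = negative_fraction([net_from_edges(["A", "B"], [])])
        assert (neg, tot, frac) == (0, 0, 0.0)


class TestFocusSubnetwork:
    def test_keeps_only_incident_edges(self):
        net = net_from_edges(
            ["HMGB1", "IL-6", "IL-8", "IP-10", "IL-4", "IL-5"],
            [("HMGB1", "IL-6", "+"), ("HMGB1", "IL-8", "+"),
             ("HMGB1", "IP-10", "+"), ("IL-4", "IL-5", "+")],
        )
        sub = focus_subnetwork(net, "HMGB1")
        assert sub.edge_count == 3
        assert set(sub.mediators) == set(net.mediators)  # node set unchanged
        assert all("HMGB1" in (u, v) for u, v in sub.graph.edges)

    def test_isolated_mediator_gives_empty_subnetwork(self):
        net = net_from_edges(["A", "B", "C"], [("B", "C", "+")])
        assert focus_subnetwork(net, "A").edge_count == 0

    def test_star_graph_is_identity(self):
        net = net_from_edges(list("ABCD"), [("A", "B", "+"), ("A", "C", "-"), ("A", "D", "+")])
        sub = focus_subnetwork(net, "A")
        assert set(sub.graph.edges) == set(net.graph.edges)

    def test_unknown_mediator_is_error(self):
        net = net_from_edges(["A", "B"], [])
        with pytest.raises(ValueError):
            focus_subnetwork(net, "Z")


def test_edges_frame_is_sorted_and_lexicographic():
    net = net_from_edges(list("ABC"), [("C", "A", "+"), ("B", "A", "-")])
    df = edges_frame([net])
    assert list(df["mediator_a"]) == ["A", "A"]
    assert (df["mediator_a"] < df["mediator_b"]).all()
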