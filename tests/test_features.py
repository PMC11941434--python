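import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emergence_pitch import (
    MatchTracking,
    TeamGraph,
    build_team_graph,
    center_of_mass,
    compute_feature_series,
    differentiate_positions,
    inverse_distance_weight,
    micro_center_distances,
    node_clustering,
    relative_distance_macro,
    team_clustering,
    velocity_edge_weight,
)
from emergence_pitch.features import FeatureError


def brute_force_node_clustering(W, A, i):
    """Literal ordered-pair triple loop of the weighted clustering coefficient."""
    n = W.shape[0]
    k = A[i].sum()
    total = 0.0
    for j in range(n):
        for m in range(n):
            if j == i or m == i or j == m:
                continue
            total += (W[i, j] + W[i, m]) / 2.0 * A[j, m]
    return total / (k * (k - 1))


def random_complete_graph(rng, n):
    W = rng.uniform(0, 3, size=(n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    return TeamGraph(W)


class TestAggregateMetrics:
    def test_com_symmetry(self):
        pts = np.array([[0, 0], [2, 0], [0, 2], [2, 2]], float)
        np.testing.assert_allclose(center_of_mass(pts), [1, 1])

    def test_com_single_player(self):
        np.testing.assert_allclose(center_of_mass(np.array([[3.0, -4.0]])), [3, -4])

    def test_com_matches_direct_mean(self, rng):
        pts = rng.normal(size=(10, 2))
        direct = np.array([pts[:, 0].sum() / 10, pts[:, 1].sum() / 10])
        np.testing.assert_allclose(center_of_mass(pts), direct, atol=1e-12)

    def test_relative_distance_cancellation(self):
        pts = np.array([[3, 4], [-3, -4]], float)
        assert relative_distance_macro(pts, "com_to_center") == pytest.approx(0.0)
        assert relative_distance_macro(pts, "mean_distance") == pytest.approx(5.0)

    def test_unknown_variant(self):
        with pytest.raises(FeatureError):
            relative_distance_macro(np.zeros((2, 2)), "nope")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_mean_distance_dominates_com_distance(self, seed):
        pts = np.random.default_rng(seed).normal(scale=20, size=(10, 2))
        assert relative_distance_macro(pts, "mean_distance") >= relative_distance_macro(
            pts, "com_to_center"
        ) - 1e-12

    def test_micro_distances(self, rng):
        pts = np.vstack([[0, 0], [3, 4], rng.normal(size=(5, 2))])
        expect = [np.hypot(x, y) for x, y in pts]
        np.testing.assert_allclose(micro_center_distances(pts), expect, atol=1e-12)


class TestEdgeWeights:
    def test_aligned_pair(self):
        assert velocity_edge_weight(1.0, 1.0, 0.0) == pytest.approx(2.0)

    def test_antiparallel_pair_vanishes(self):
        assert velocity_edge_weight(2.0, 3.0, np.pi) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_pair(self):
        assert velocity_edge_weight(1.0, 2.0, np.pi / 2) == pytest.approx(2.0)

    def test_negative_speed_rejected(self):
        with pytest.raises(FeatureError):
            velocity_edge_weight(-1.0, 1.0, 0.0)

    @given(
        st.floats(0, 15), st.floats(0, 15), st.floats(-np.pi, np.pi)
    )
    @settings(max_examples=50, deadline=None)
    def test_weight_bounds(self, su, sv, dtheta):
        w = velocity_edge_weight(su, sv, dtheta)
        assert -1e-9 <= w <= 2 * su * sv + 1e-9

    def test_inverse_distance_values(self):
        assert inverse_distance_weight([0, 0], [2, 0]) == pytest.approx(0.5)
        assert inverse_distance_weight([0, 0], [0.3, 0.4]) == pytest.approx(2.0)
        assert inverse_distance_weight([1, 1], [1, 1]) == pytest.approx(10.0)


class TestGraphs:
    def test_three_player_distance_graph_by_hand(self):
        pts = np.array([[0, 0], [2, 0], [0, 1]], float)
        g = build_team_graph(positions=pts, mode="inverse_distance")
        expect = np.array(
            [[0, 0.5, 1.0], [0.5, 0, 1 / np.sqrt(5)], [1.0, 1 / np.sqrt(5), 0]]
        )
        np.testing.assert_allclose(g.weights, expect, atol=1e-12)

    def test_three_player_velocity_graph_by_hand(self):
        vel = np.array([[1, 0], [0, 2], [-1, 0]], float)
        g = build_team_graph(velocities=vel, mode="velocity")
        # w = v_u . v_v + |v_u||v_v|
        expect = np.array([[0, 2.0, 0.0], [2.0, 0, 2.0], [0.0, 2.0, 0]])
        np.testing.assert_allclose(g.weights, expect, atol=1e-12)

    def test_stationary_players_zero_weights(self):
        g = build_team_graph(velocities=np.zeros((10, 2)), mode="velocity")
        np.testing.assert_array_equal(g.weights, 0.0)

    def test_symmetry_on_random_frame(self, rng):
        g = build_team_graph(positions=rng.normal(size=(10, 2)) * 20)
        np.testing.assert_array_equal(g.weights, g.weights.T)

    def test_to_networkx_round_trip(self, rng):
        g = random_complete_graph(rng, 5)
        nxg = g.to_networkx()
        assert nxg.number_of_edges() == 10
        assert nxg[0][1]["weight"] == g.weights[0, 1]


class TestClustering:
    def test_uniform_weight_identity(self):
        for n, w in [(4, 0.5), (10, 1.7)]:
            g = TeamGraph(w * (1 - np.eye(n)))
            for i in range(n):
                assert node_clustering(g, i) == pytest.approx(w, abs=1e-12)
            assert team_clustering(g) == pytest.approx(w, abs=1e-12)

    def test_zero_graph(self):
        g = TeamGraph(np.zeros((5, 5)))
        assert team_clustering(g) == 0.0

    @given(st.integers(0, 2**31 - 1), st.integers(3, 12))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, seed, n):
        g = random_complete_graph(np.random.default_rng(seed), n)
        for i in range(n):
            assert node_clustering(g, i) == pytest.approx(
                brute_force_node_clustering(g.weights, g.adjacency, i), abs=1e-12
            )
        brute_mean = np.mean(
            [brute_force_node_clustering(g.weights, g.adjacency, i) for i in range(n)]
        )
        assert team_clustering(g) == pytest.approx(brute_mean, abs=1e-12)

    def test_degree_below_two_errors(self):
        g = TeamGraph(np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(FeatureError):
            node_clustering(g, 0)
        with pytest.raises(FeatureError):
            team_clustering(g)


def small_half(rng, T=100):
    pos = {team: rng.uniform(-25, 25, size=(T, 10, 2)) for team in ("home", "away")}
    tr = MatchTracking(times=np.arange(float(T)), positions=pos)
    return differentiate_positions(tr)


class TestFeatureSeries:
    def test_com_shapes_and_consistency(self, rng):
        half = small_half(rng)
        s = compute_feature_series(half, "home", "com")
        assert s.macro.shape == (100, 2)
        assert s.micro.shape == (100, 10, 2)
        np.testing.assert_allclose(s.macro, s.micro.mean(axis=1), atol=1e-9)

    def test_clust_dist_matches_per_frame_graph(self, rng):
        half = small_half(rng, T=10)
        s = compute_feature_series(half, "away", "clust_dist")
        for t in (0, 5, 9):
            g = build_team_graph(positions=half.positions["away"][t])
            assert s.macro[t] == pytest.approx(team_clustering(g), abs=1e-12)

    def test_clust_vel_masks_first_frame(self, rng):
        half = small_half(rng)
        s = compute_feature_series(half, "home", "clust_vel")
        assert not s.valid[0] and s.valid[1:].all()

    def test_clust_vel_requires_velocities(self, rng):
        tr = MatchTracking(
            times=np.arange(10.0),
            positions={t: rng.uniform(-5, 5, (10, 10, 2)) for t in ("home", "away")},
        )
        with pytest.raises(FeatureError, match="velocit"):
            compute_feature_series(tr, "home", "clust_vel")

    def test_unknown_feature(self, rng):
        with pytest.raises(FeatureError):
            compute_feature_series(small_half(rng, T=5), "home", "wat")

    def test_translation_equivariance(self, rng):
        half = small_half(rng, T=40)
        shift = np.array([3.0, -2.0])
        shifted = MatchTracking(
            times=half.times,
            positions={k: v + shift for k, v in half.positions.items()},
            velocities=half.velocities,
            vel_valid=half.vel_valid,
            half_bounds=half.half_bounds,
        )
        for feat in ("clust_vel", "clust_dist"):
            a = compute_feature_series(half, "home", feat).macro
            b = compute_feature_series(shifted, "home", feat).macro
            np.testing.assert_allclose(a, b, atol=1e-9)
        a = compute_feature_series(half, "home", "com").macro
        b = compute_feature_series(shifted, "home", "com").macro
        np.testing.assert_allclose(b - a, np.broadcast_to(shift, a.shape), atol=1e-9)
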