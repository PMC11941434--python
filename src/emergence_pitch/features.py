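"""Macroscopic team features and their per-player microscopic series.

Four macro features are supported, each paired with the micro variables it
supervenes on:

========================  =========================  =======================
feature                   macro (per second)         micro (per player)
========================  =========================  =======================
``com``                   2-D centre of mass         2-D position
``relative_distance``     team-to-centre distance    distance to centre
``clust_vel``             weighted clustering of     2-D velocity
                          the velocity-similarity
                          graph, team-averaged
``clust_dist``            weighted clustering of     2-D position
                          the inverse-distance
                          graph, team-averaged
========================  =========================  =======================

Graphs are complete weighted graphs on the ten players.  The velocity edge
weight is ``S_u * S_v * (cos(dtheta) + 1)`` (large for fast, co-directed
pairs); the distance edge weight is the inverse Euclidean distance, capped
at ``1/eps`` for near-coincident players.  The node clustering coefficient
averages half-sums of incident edge weights over connected neighbour pairs,

    C_i = 1 / (k_i (k_i - 1)) * sum_{j,k != i, j != k} (w_ij + w_ik)/2 * a_jk,

and the team value is the player average.  Weights are not normalised.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .tracking import MatchTracking

FEATURE_NAMES = ("com", "relative_distance", "clust_vel", "clust_dist")
RELDIST_VARIANTS = ("com_to_center", "mean_distance")


class FeatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# aggregate positioning metrics
# ---------------------------------------------------------------------------


def center_of_mass(positions: np.ndarray) -> np.ndarray:
    """Mean position over players; ``positions`` is (..., N, 2)."""
    positions = np.asarray(positions, dtype=float)
    if positions.shape[-2] < 1:
        raise FeatureError("center_of_mass of an empty player set")
    return positions.mean(axis=-2)


def micro_center_distances(positions: np.ndarray) -> np.ndarray:
    """Per-player Euclidean distance to the pitch centre (origin)."""
    positions = np.asarray(positions, dtype=float)
    return np.linalg.norm(positions, axis=-1)


def relative_distance_macro(positions: np.ndarray, variant: str = "com_to_center") -> np.ndarray:
    """Scalar macro relating the team to the pitch centre.

    ``com_to_center``: distance from the team CoM to the centre spot.
    ``mean_distance``: mean of the players' distances to the centre spot
    (always >= the CoM variant, by the triangle inequality).
    """
    if variant == "com_to_center":
        return np.linalg.norm(center_of_mass(positions), axis=-1)
    if variant == "mean_distance":
        return micro_center_distances(positions).mean(axis=-1)
    raise FeatureError(f"unknown relative_distance variant {variant!r}")


# ---------------------------------------------------------------------------
# player graphs
# ---------------------------------------------------------------------------


def velocity_edge_weight(s_u, s_v, delta_theta):
    """Edge weight ``S_u * S_v * (cos(dtheta) + 1)`` for speeds in m/s.

    Zero whenever either speed is zero (the angle difference is then
    undefined but the weight vanishes regardless).
    """
    s_u = np.asarray(s_u, dtype=float)
    s_v = np.asarray(s_v, dtype=float)
    if np.any(s_u < 0) or np.any(s_v < 0):
        raise FeatureError("speeds must be non-negative")
    w = s_u * s_v * (np.cos(delta_theta) + 1.0)
    return w if w.ndim else float(w)


def inverse_distance_weight(p_u, p_v, eps: float = 0.1):
    """Inverse Euclidean distance, capped at ``1/eps`` for coincident players."""
    d = np.linalg.norm(np.asarray(p_u, dtype=float) - np.asarray(p_v, dtype=float), axis=-1)
    w = 1.0 / np.maximum(d, eps)
    return w if np.ndim(w) else float(w)


@dataclasses.dataclass
class TeamGraph:
    """Complete weighted player graph for one frame.

    ``weights`` is the symmetric non-negative N x N weight matrix with zero
    diagonal; ``adjacency`` defaults to the complete graph (1 for all j != k).
    Thresholded adjacencies may be supplied but are off by default.
    """

    weights: np.ndarray
    mode: str = "inverse_distance"
    adjacency: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise FeatureError("weight matrix must be square")
        if not np.allclose(self.weights, self.weights.T):
            raise FeatureError("weight matrix must be symmetric")
        if np.any(self.weights < 0):
            raise FeatureError("weights must be non-negative")
        if np.any(np.diag(self.weights) != 0):
            raise FeatureError("weight matrix must have zero diagonal")
        if self.adjacency is None:
            self.adjacency = 1.0 - np.eye(n)
        self.adjacency = np.asarray(self.adjacency, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def to_networkx(self):
        """Convert to a weighted :class:`networkx.Graph` (edges where a_jk=1)."""
        import networkx as nx

        g = nx.Graph()
        n = self.n_nodes
        g.add_nodes_from(range(n))
        for j in range(n):
            for k in range(j + 1, n):
                if self.adjacency[j, k]:
                    g.add_edge(j, k, weight=self.weights[j, k])
        return g


def _velocity_weights(velocities: np.ndarray) -> np.ndarray:
    """Batched velocity-similarity weights; ``velocities`` is (..., N, 2).

    Uses the identity S_u S_v cos(dtheta) = v_u . v_v, which also sends
    zero-speed pairs to weight 0.
    """
    v = np.asarray(velocities, dtype=float)
    dots = np.einsum("...ic,...jc->...ij", v, v)
    speeds = np.linalg.norm(v, axis=-1)
    w = dots + speeds[..., :, None] * speeds[..., None, :]
    w = np.clip(w, 0.0, None)  # guard tiny negative rounding at dtheta = pi
    idx = np.arange(v.shape[-2])
    w[..., idx, idx] = 0.0
    return w


def _distance_weights(positions: np.ndarray, eps: float = 0.1) -> np.ndarray:
    """Batched inverse-distance weights; ``positions`` is (..., N, 2)."""
    p = np.asarray(positions, dtype=float)
    diff = p[..., :, None, :] - p[..., None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    w = 1.0 / np.maximum(d, eps)
    idx = np.arange(p.shape[-2])
    w[..., idx, idx] = 0.0
    return w


def build_team_graph(
    positions: np.ndarray | None = None,
    velocities: np.ndarray | None = None,
    mode: str = "inverse_distance",
    eps: float = 0.1,
) -> TeamGraph:
    """Complete weighted graph for one frame of one team.

    ``mode='inverse_distance'`` needs positions (N, 2); ``mode='velocity'``
    needs velocities (N, 2).
    """
    if mode == "inverse_distance":
        if positions is None:
            raise FeatureError("inverse_distance mode requires positions")
        return TeamGraph(_distance_weights(positions, eps), mode=mode)
    if mode == "velocity":
        if velocities is None:
            raise FeatureError("velocity mode requires velocities")
        return TeamGraph(_velocity_weights(velocities), mode=mode)
    raise FeatureError(f"unknown graph mode {mode!r}")


def _clustering_nodes(weights: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
    """Batched per-node clustering coefficients.

    Because the weight matrix is symmetric, the ordered-pair sum
    ``sum_{j,k != i} (w_ij + w_ik)/2 a_jk`` collapses to
    ``sum_j w_ij (deg_j - a_ji)`` (w_ii = a_jj = 0), which vectorises.
    """
    deg = adjacency.sum(axis=-1)
    num = np.einsum("...ij,...j->...i", weights, deg) - (weights * adjacency).sum(axis=-1)
    denom = deg * (deg - 1.0)
    return num / denom


def node_clustering(graph: TeamGraph, i: int) -> float:
    """Weighted clustering coefficient of node ``i`` (requires degree >= 2)."""
    deg = graph.degrees()
    if deg[i] < 2:
        raise FeatureError(f"node {i} has degree {deg[i]} < 2")
    return float(_clustering_nodes(graph.weights, graph.adjacency)[i])


def team_clustering(graph: TeamGraph) -> float:
    """Team-level clustering: mean of node coefficients over all players."""
    if graph.n_nodes < 3:
        raise FeatureError(f"team clustering needs >= 3 players, got {graph.n_nodes}")
    if np.any(graph.degrees() < 2):
        raise FeatureError("every node needs degree >= 2")
    return float(_clustering_nodes(graph.weights, graph.adjacency).mean())


# ---------------------------------------------------------------------------
# per-half feature series
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MacroMicroSeries:
    """Aligned macro series and per-player micro series for one team.

    ``macro`` has shape (T,) for scalar features or (T, 2) for the CoM;
    ``micro`` has shape (T, N) for scalar micro variables or (T, N, 2) for
    2-D ones.  ``valid`` masks frames whose micro/macro values rest on
    placeholder velocities.
    """

    feature_name: str
    team: str
    times: np.ndarray
    macro: np.ndarray
    micro: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.macro = np.asarray(self.macro, dtype=float)
        self.micro = np.asarray(self.micro, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    def validate(self) -> "MacroMicroSeries":
        T = len(self.times)
        if self.macro.shape[0] != T or self.micro.shape[0] != T or self.valid.shape[0] != T:
            raise FeatureError("macro/micro/valid not aligned with times")
        if self.feature_name == "com":
            if not np.allclose(self.macro, self.micro.mean(axis=1), atol=1e-9):
                raise FeatureError("com macro must equal the mean of micro positions")
        return self

    @property
    def n_players(self) -> int:
        return self.micro.shape[1]


def compute_feature_series(
    half: MatchTracking,
    team: str,
    feature_name: str,
    *,
    variant: str = "com_to_center",
    eps: float = 0.1,
) -> MacroMicroSeries:
    """Per-second macro and micro series for one team over one half.

    ``clust_vel`` requires velocities (run :func:`differentiate_positions`
    first); frames with placeholder velocities are masked invalid.
    """
    pos = half.positions[team]
    T = half.n_frames
    valid = np.ones(T, dtype=bool)

    if feature_name == "com":
        macro = center_of_mass(pos)
        micro = pos
    elif feature_name == "relative_distance":
        macro = relative_distance_macro(pos, variant)
        micro = micro_center_distances(pos)
    elif feature_name == "clust_dist":
        W = _distance_weights(pos, eps)
        A = 1.0 - np.eye(pos.shape[1])
        macro = _clustering_nodes(W, A).mean(axis=-1)
        micro = pos
    elif feature_name == "clust_vel":
        if half.velocities is None:
            raise FeatureError("clust_vel requires velocities; call differentiate_positions first")
        vel = half.velocities[team]
        W = _velocity_weights(vel)
        A = 1.0 - np.eye(vel.shape[1])
        macro = _clustering_nodes(W, A).mean(axis=-1)
        micro = vel
        valid = half.vel_valid.copy()
    else:
        raise FeatureError(f"unknown feature {feature_name!r}; choose from {FEATURE_NAMES}")

    return MacroMicroSeries(
        feature_name=feature_name,
        team=team,
        times=half.times,
        macro=macro,
        micro=micro,
        valid=valid,
    ).validate()
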