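"""Trajectory linking: candidate-link graph, variational marginal link
probabilities under a Brownian motion model, and constrained
hill-climbing selection.

Pipeline
--------
1. :func:`build_link_graph` connects every pair of detections separated
   by at most 1.25 um in space and at most three frames in time.
2. :func:`infer_link_probabilities` runs loopy sum-product belief
   propagation on a factor graph with one binary variable per candidate
   link and one "at most one active link, else no-link" factor per
   detection side, jointly re-estimating a per-detection diffusion
   coefficient from belief-weighted squared displacements.  A candidate
   link's prior weight is the squared 2-D Brownian transition density of
   its displacement (per-axis variance 2 D dt_link + 2 sigma_loc^2), so
   that each detection side contributes exactly one density factor and
   the configuration weight is dimensionless up to a global constant;
   the no-link alternative carries a per-frame appearance/disappearance
   rate times the uniform density over the search disc,
   nolink_rate / (pi * max_distance^2).
3. :func:`select_links` prunes weak links and hill-climbs the
   configuration objective (sum of selected-link log marginals plus
   log no-link marginals for every unmatched detection side) under the
   constraint that no detection starts or ends two links.
4. :func:`assemble_trajectories` reads trajectories off the selected
   subgraph as connected components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

_P_FLOOR = 1e-12  # probability floor inside logs


@dataclass
class LinkGraph:
    """Candidate-link graph over a table of localizations.

    Edge arrays are parallel: ``src``/``dst`` index rows of
    ``detections``; ``gap`` is the frame difference (1..max_gap);
    ``dist`` the displacement in um.  After inference, ``p`` holds the
    marginal link probability, ``p_out``/``p_in`` the source- and
    target-side responsibilities, and ``no_out_p``/``no_in_p`` the
    per-detection no-link masses (each side sums to one).
    """

    detections: pd.DataFrame
    src: np.ndarray
    dst: np.ndarray
    gap: np.ndarray
    dist: np.ndarray
    max_distance: float
    max_gap: int
    #: per-frame appearance/disappearance rate multiplying the uniform
    #: spatial density of the no-link alternative.  Disappearance is not
    #: certain — it requires photobleaching or a missed detection
    #: (a few percent per frame each) — so the alternative is a rate
    #: times a density, not the bare density.
    nolink_rate: float = 0.1
    d_hat: np.ndarray = field(default=None)
    likelihood: np.ndarray = field(default=None)
    p: np.ndarray = field(default=None)
    p_out: np.ndarray = field(default=None)
    p_in: np.ndarray = field(default=None)
    no_out_p: np.ndarray = field(default=None)
    no_in_p: np.ndarray = field(default=None)

    @property
    def n_detections(self) -> int:
        return len(self.detections)

    @property
    def n_edges(self) -> int:
        return len(self.src)

    @property
    def nolink_density(self) -> float:
        """Appearance/disappearance weight: per-frame rate times the
        uniform density over the search disc."""
        return self.nolink_rate / (np.pi * self.max_distance**2)


def build_link_graph(
    localizations: pd.DataFrame,
    max_distance: float = 1.25,
    max_gap: int = 3,
    nolink_rate: float = 0.1,
) -> LinkGraph:
    """Candidate links between detections within the space-time bounds.

    The edge set equals brute-force enumeration of all pairs with
    displacement <= ``max_distance`` um and frame gap in 1..``max_gap``;
    a KD-tree is used per frame pair for speed.
    """
    det = localizations.reset_index(drop=True)
    frames = det["frame"].to_numpy()
    xy = det[["x_um", "y_um"]].to_numpy(dtype=float)
    by_frame: Dict[int, np.ndarray] = {
        int(f): np.nonzero(frames == f)[0] for f in np.unique(frames)
    }
    trees = {f: cKDTree(xy[idx]) for f, idx in by_frame.items()}
    src_l: List[int] = []
    dst_l: List[int] = []
    gap_l: List[int] = []
    for f, idx_a in sorted(by_frame.items()):
        for delta in range(1, max_gap + 1):
            idx_b = by_frame.get(f + delta)
            if idx_b is None:
                continue
            pairs = trees[f].query_ball_tree(trees[f + delta], r=max_distance)
            for ia, neighbors in zip(idx_a, pairs):
                for jb in neighbors:
                    src_l.append(ia)
                    dst_l.append(idx_b[jb])
                    gap_l.append(delta)
    src = np.array(src_l, dtype=np.int64)
    dst = np.array(dst_l, dtype=np.int64)
    gap = np.array(gap_l, dtype=np.int64)
    dist = (
        np.linalg.norm(xy[src] - xy[dst], axis=1) if len(src) else np.zeros(0)
    )
    return LinkGraph(det, src, dst, gap, dist, max_distance, max_gap, nolink_rate)


def _brownian_density(r: np.ndarray, variance_per_axis: np.ndarray) -> np.ndarray:
    """2-D isotropic Gaussian density of a displacement of length r."""
    return np.exp(-(r * r) / (2.0 * variance_per_axis)) / (2.0 * np.pi * variance_per_axis)


#: components with at most this many candidate links are marginalized by
#: exact enumeration; larger ones fall back to loopy BP
EXACT_COMPONENT_MAX_EDGES = 12


def _marginals(
    graph: LinkGraph, weight: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Marginal link probabilities under the matching constraints.

    The factor graph decomposes over connected components of the
    candidate graph: small components (up to
    :data:`EXACT_COMPONENT_MAX_EDGES` links) are solved by exact
    enumeration over their matchings, larger ones by loopy sum-product
    belief propagation (exact on trees, approximate on cycles).
    Returns (p, p_out, p_in, no_out_p, no_in_p); the per-side masses sum
    to one by construction.
    """
    n_det, n_edge = graph.n_detections, graph.n_edges
    if n_edge == 0:
        ones = np.ones(n_det)
        return np.zeros(0), np.zeros(0), np.zeros(0), ones, ones.copy()
    # connected components over detections through candidate links
    parent = np.arange(n_det)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for s, d in zip(graph.src, graph.dst):
        parent[find(s)] = find(d)
    edge_root = np.array([find(int(s)) for s in graph.src])
    p = np.zeros(n_edge)
    p_out = np.zeros(n_edge)
    p_in = np.zeros(n_edge)
    no_out_p = np.ones(n_det)
    no_in_p = np.ones(n_det)
    l0 = graph.nolink_density
    for root in np.unique(edge_root):
        edges = np.nonzero(edge_root == root)[0]
        if len(edges) <= EXACT_COMPONENT_MAX_EDGES:
            pe = _exact_component_marginals(graph, weight, edges, l0)
        else:
            pe = _bp_component_marginals(graph, weight, edges, l0)
        p[edges] = pe
        p_out[edges] = pe
        p_in[edges] = pe
        np.subtract.at(no_out_p, graph.src[edges], pe)
        np.subtract.at(no_in_p, graph.dst[edges], pe)
    eps = 1e-12
    return p, p_out, p_in, np.clip(no_out_p, eps, 1.0), np.clip(no_in_p, eps, 1.0)


def _exact_component_marginals(
    graph: LinkGraph, weight: np.ndarray, edges: np.ndarray, l0: float
) -> np.ndarray:
    """Exact marginals for one component by matching enumeration.

    A matching M over the component's links has weight
    ``prod_{e in M} weight_e * l0^2{unmatched sides}``; constant factors
    from sides outside the component cancel in the normalization.
    """
    m = len(edges)
    src = graph.src[edges]
    dst = graph.dst[edges]
    w = weight[edges]
    totals = np.zeros(m)
    z = 0.0
    for bits in range(1 << m):
        chosen = [e for e in range(m) if bits >> e & 1]
        s_used = [src[e] for e in chosen]
        d_used = [dst[e] for e in chosen]
        if len(set(s_used)) != len(s_used) or len(set(d_used)) != len(d_used):
            continue
        # each selected link replaces one no-link factor on each side
        wt = float(np.prod([w[e] for e in chosen])) * l0 ** (-2.0 * len(chosen))
        z += wt
        for e in chosen:
            totals[e] += wt
    return totals / z


def _bp_component_marginals(
    graph: LinkGraph, weight: np.ndarray, edges: np.ndarray, l0_lin: float,
    damping: float = 0.5, max_iterations: int = 200, tol: float = 1e-9,
) -> np.ndarray:
    """Loopy sum-product BP marginals for one (large) component."""
    n_det = graph.n_detections
    l0 = l0_lin**2  # squared: one density factor per detection side
    src, dst = graph.src[edges], graph.dst[edges]
    weight = weight[edges]
    n_edge = len(edges)
    # message ratios: mu_s[e] = m_{SourceFactor(src[e]) -> e}(1)/(0), mu_t likewise
    mu_s = np.full(n_edge, 1.0 / l0)
    mu_t = np.full(n_edge, 1.0 / l0)
    for _ in range(max_iterations):
        rho_to_s = weight * mu_t  # n_{e -> source factor} ratio
        rho_to_t = weight * mu_s
        sum_s = np.bincount(src, weights=rho_to_s, minlength=n_det)
        sum_t = np.bincount(dst, weights=rho_to_t, minlength=n_det)
        new_mu_s = 1.0 / (l0 + sum_s[src] - rho_to_s)
        new_mu_t = 1.0 / (l0 + sum_t[dst] - rho_to_t)
        delta = max(
            np.abs(new_mu_s - mu_s).max() / max(mu_s.max(), 1e-300),
            np.abs(new_mu_t - mu_t).max() / max(mu_t.max(), 1e-300),
        )
        mu_s = damping * mu_s + (1 - damping) * new_mu_s
        mu_t = damping * mu_t + (1 - damping) * new_mu_t
        if delta < tol:
            break
    rho_to_s = weight * mu_t
    rho_to_t = weight * mu_s
    sum_s = np.bincount(src, weights=rho_to_s, minlength=n_det)
    sum_t = np.bincount(dst, weights=rho_to_t, minlength=n_det)
    p_out = rho_to_s / (l0 + sum_s[src])
    p_in = rho_to_t / (l0 + sum_t[dst])
    return 0.5 * (p_out + p_in)


def infer_link_probabilities(
    graph: LinkGraph,
    dt: float,
    localization_error: float = 0.035,
    initial_diffusion: float = 0.5,
    max_rounds: int = 20,
    tol: float = 1e-4,
) -> LinkGraph:
    """Jointly infer marginal link probabilities and per-spot diffusion.

    Alternates (i) Brownian link likelihoods with per-axis variance
    ``2 * D_blend * gap * dt + 2 * localization_error^2`` where D_blend
    averages the source and target per-spot estimates, (ii) BP marginals
    under the matching constraints, (iii) re-estimation of each spot's
    diffusion coefficient from probability-weighted squared
    displacements.  Stops when the marginals move by less than ``tol``
    or after ``max_rounds`` rounds.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_det = graph.n_detections
    d_hat = np.full(n_det, float(initial_diffusion))
    sigma2 = localization_error**2
    p_prev = np.zeros(graph.n_edges)
    for _ in range(max_rounds):
        d_blend = 0.5 * (d_hat[graph.src] + d_hat[graph.dst]) if graph.n_edges else np.zeros(0)
        var = 2.0 * d_blend * graph.gap * dt + 2.0 * sigma2
        lik = _brownian_density(graph.dist, var) if graph.n_edges else np.zeros(0)
        p, p_out, p_in, no_out, no_in = _marginals(graph, lik**2)
        if graph.n_edges:
            # D implied by each link's squared displacement, floored at ~0
            d_link = np.maximum(
                graph.dist**2 / (4.0 * graph.gap * dt) - sigma2 / (graph.gap * dt), 1e-4
            )
            num = np.bincount(graph.src, weights=p * d_link, minlength=n_det)
            num += np.bincount(graph.dst, weights=p * d_link, minlength=n_det)
            den = np.bincount(graph.src, weights=p, minlength=n_det)
            den += np.bincount(graph.dst, weights=p, minlength=n_det)
            # unit-weight prior toward the initial estimate stabilizes
            # spots with no confident links
            d_hat = np.clip(
                (num + float(initial_diffusion)) / (den + 1.0), 1e-4, 100.0
            )
        graph.d_hat = d_hat
        graph.likelihood = lik
        graph.p, graph.p_out, graph.p_in = p, p_out, p_in
        graph.no_out_p, graph.no_in_p = no_out, no_in
        if graph.n_edges == 0 or np.abs(p - p_prev).max() < tol:
            break
        p_prev = p
    return graph


def enumerate_exact_marginals(graph: LinkGraph, weight: np.ndarray) -> np.ndarray:
    """Exact link marginals by enumeration over all matchings (test oracle).

    The joint weight of a matching M is
    ``prod_{e in M} weight_e * L0^(number of unmatched detection sides)``
    with ``L0`` the no-link density (one density factor per detection
    side: a selected link supplies both of its sides' factors through
    ``weight_e``, an unmatched side supplies L0).  Feasible only for
    tiny graphs.
    """
    n_edge = graph.n_edges
    l0 = graph.nolink_density
    totals = np.zeros(n_edge)
    z = 0.0
    for bits in range(1 << n_edge):
        chosen = [e for e in range(n_edge) if bits >> e & 1]
        srcs = [graph.src[e] for e in chosen]
        dsts = [graph.dst[e] for e in chosen]
        if len(set(srcs)) != len(srcs) or len(set(dsts)) != len(dsts):
            continue
        w = float(np.prod([weight[e] for e in chosen])) if chosen else 1.0
        n_free_sides = (graph.n_detections - len(srcs)) + (graph.n_detections - len(dsts))
        w *= l0**n_free_sides
        z += w
        for e in chosen:
            totals[e] += w
    return totals / z if z > 0 else totals


@dataclass
class Matching:
    """Conflict-free selected link set (edge indices into the graph)."""

    edges: List[int]
    objective: float


def _configuration_objective(
    graph: LinkGraph, out_edge: np.ndarray, in_edge: np.ndarray
) -> float:
    logp = np.log(np.maximum(graph.p, _P_FLOOR))
    log_no_out = np.log(np.maximum(graph.no_out_p, _P_FLOOR))
    log_no_in = np.log(np.maximum(graph.no_in_p, _P_FLOOR))
    obj = 0.0
    for i in range(graph.n_detections):
        obj += logp[out_edge[i]] if out_edge[i] >= 0 else log_no_out[i]
        obj += log_no_in[i] if in_edge[i] < 0 else 0.0
    return obj


def select_links(graph: LinkGraph, prune_factor: float = 0.5) -> Matching:
    """Hill-climb a conflict-free link set maximizing the configuration
    log-probability.

    Links with marginal below ``prune_factor`` times the mean of the two
    incident no-link masses are pruned first.  Moves are add / remove /
    swap (adding a link after evicting its conflicts); each accepted
    move strictly increases the objective, so termination is guaranteed,
    and ties are broken deterministically by (marginal, source, target)
    order.  On small instances the result matches exhaustive search over
    all matchings.
    """
    n_det = graph.n_detections
    if graph.n_edges == 0 or graph.p is None:
        out_edge = np.full(n_det, -1)
        in_edge = np.full(n_det, -1)
        return Matching([], _configuration_objective(graph, out_edge, in_edge))
    logp = np.log(np.maximum(graph.p, _P_FLOOR))
    log_no_out = np.log(np.maximum(graph.no_out_p, _P_FLOOR))
    log_no_in = np.log(np.maximum(graph.no_in_p, _P_FLOOR))
    floor = prune_factor * 0.5 * (graph.no_out_p[graph.src] + graph.no_in_p[graph.dst])
    candidates = np.nonzero(graph.p >= floor)[0]
    order = candidates[
        np.lexsort((graph.dst[candidates], graph.src[candidates], -graph.p[candidates]))
    ]
    out_edge = np.full(n_det, -1, dtype=np.int64)  # edge whose src is this det
    in_edge = np.full(n_det, -1, dtype=np.int64)

    def add_gain(e: int) -> float:
        s, d = graph.src[e], graph.dst[e]
        gain = logp[e]
        old_out = out_edge[s]
        old_in = in_edge[d]
        if old_out == e or old_in == e:
            return -np.inf
        gain -= log_no_out[s] if old_out < 0 else logp[old_out]
        gain -= log_no_in[d] if old_in < 0 else logp[old_in]
        # evicted links free the other side of their conflict partner
        if old_out >= 0:
            gain += log_no_in[graph.dst[old_out]]
        if old_in >= 0:
            gain += log_no_out[graph.src[old_in]]
        return gain

    def remove_gain(e: int) -> float:
        s, d = graph.src[e], graph.dst[e]
        return (log_no_out[s] + log_no_in[d]) - logp[e]

    improved = True
    while improved:
        improved = False
        for e in order:
            s, d = graph.src[e], graph.dst[e]
            if out_edge[s] == e:  # selected: try removal
                if remove_gain(e) > 1e-12:
                    out_edge[s] = -1
                    in_edge[d] = -1
                    improved = True
            else:  # try add (with eviction)
                if add_gain(e) > 1e-12:
                    if out_edge[s] >= 0:
                        in_edge[graph.dst[out_edge[s]]] = -1
                    if in_edge[d] >= 0:
                        out_edge[graph.src[in_edge[d]]] = -1
                    out_edge[s] = e
                    in_edge[d] = e
                    improved = True
    edges = sorted(int(e) for e in out_edge[out_edge >= 0])
    # feasibility re-check
    assert len({graph.src[e] for e in edges}) == len(edges)
    assert len({graph.dst[e] for e in edges}) == len(edges)
    return Matching(edges, _configuration_objective(graph, out_edge, in_edge))


def exhaustive_best_matching(graph: LinkGraph) -> Matching:
    """Global optimum of the configuration objective by enumeration
    (test oracle; exponential in the edge count)."""
    n_edge = graph.n_edges
    best: Optional[Matching] = None
    for bits in range(1 << n_edge):
        chosen = [e for e in range(n_edge) if bits >> e & 1]
        srcs = [graph.src[e] for e in chosen]
        dsts = [graph.dst[e] for e in chosen]
        if len(set(srcs)) != len(srcs) or len(set(dsts)) != len(dsts):
            continue
        out_edge = np.full(graph.n_detections, -1, dtype=np.int64)
        in_edge = np.full(graph.n_detections, -1, dtype=np.int64)
        for e in chosen:
            out_edge[graph.src[e]] = e
            in_edge[graph.dst[e]] = e
        obj = _configuration_objective(graph, out_edge, in_edge)
        if best is None or obj > best.objective:
            best = Matching(sorted(chosen), obj)
    return best


def assemble_trajectories(
    matching: Matching, graph: LinkGraph
) -> pd.DataFrame:
    """Connected components of the selected subgraph, one per trajectory.

    Singleton detections become length-1 trajectories.  Returns the
    localization table with a ``trajectory_id`` column, sorted by
    (trajectory_id, frame); every localization appears exactly once.
    """
    n = graph.n_detections
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    seen_out, seen_in = set(), set()
    for e in matching.edges:
        s, d = int(graph.src[e]), int(graph.dst[e])
        if s in seen_out or d in seen_in:
            raise ValueError("matching is not conflict-free")
        seen_out.add(s)
        seen_in.add(d)
        parent[find(s)] = find(d)
    roots = np.array([find(i) for i in range(n)])
    _, traj_ids = np.unique(roots, return_inverse=True)
    out = graph.detections.copy()
    out["trajectory_id"] = traj_ids
    out = out.sort_values(["trajectory_id", "frame"], ignore_index=True)
    # integrity: frames strictly increasing within each trajectory
    frames = out["frame"].to_numpy()
    tid = out["trajectory_id"].to_numpy()
    same = tid[1:] == tid[:-1]
    if np.any(same & (np.diff(frames) <= 0)):
        raise ValueError("trajectory frames not strictly increasing")
    return out


def trajectories_to_jumps(trajectories: pd.DataFrame, dt: float) -> pd.DataFrame:
    """Per-trajectory jumps: (trajectory_id, dx_um, dy_um, gap, dt_s)."""
    df = trajectories.sort_values(["trajectory_id", "frame"])
    tid = df["trajectory_id"].to_numpy()
    same = tid[1:] == tid[:-1]
    dx = np.diff(df["x_um"].to_numpy())[same]
    dy = np.diff(df["y_um"].to_numpy())[same]
    gap = np.diff(df["frame"].to_numpy())[same]
    return pd.DataFrame(
        {
            "trajectory_id": tid[1:][same],
            "dx_um": dx,
            "dy_um": dy,
            "gap": gap,
            "dt_s": gap * dt,
        }
    )


class TrajectoryLinker(BaseEstimator):
    """Probabilistic Brownian linker (scikit-learn style transformer).

    ``transform(localizations)`` takes the localization table (frame,
    x_um, y_um, ...) and returns it with a ``trajectory_id`` column.
    """

    def __init__(
        self,
        dt: float = 0.01,
        max_distance: float = 1.25,
        max_gap: int = 3,
        localization_error: float = 0.035,
        initial_diffusion: float = 0.5,
        prune_factor: float = 0.5,
        nolink_rate: float = 0.1,
    ):
        self.dt = dt
        self.max_distance = max_distance
        self.max_gap = max_gap
        self.localization_error = localization_error
        self.initial_diffusion = initial_diffusion
        self.prune_factor = prune_factor
        self.nolink_rate = nolink_rate

    def fit(self, X=None, y=None) -> "TrajectoryLinker":
        return self

    def transform(self, localizations: pd.DataFrame) -> pd.DataFrame:
        graph = build_link_graph(
            localizations, self.max_distance, self.max_gap, self.nolink_rate
        )
        graph = infer_link_probabilities(
            graph,
            self.dt,
            localization_error=self.localization_error,
            initial_diffusion=self.initial_diffusion,
        )
        matching = select_links(graph, self.prune_factor)
        self.graph_ = graph
        self.matching_ = matching
        return assemble_trajectories(matching, graph)


def link_localizations(localizations: pd.DataFrame, dt: float, **params) -> pd.DataFrame:
    """Functional wrapper over :class:`TrajectoryLinker`."""
    return TrajectoryLinker(dt=dt, **params).transform(localizations)
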