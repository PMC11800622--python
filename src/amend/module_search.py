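"""The iterative active-module search.

Each iteration diffuses seed values over the current subnetwork, shifts
the scores so that roughly a retention fraction of nodes carry positive
weight, extracts a maximum-weight connected subgraph (heuristically, over
the aggregated graph in which multiplex components are collapsed onto a
primary layer's edge set), scores the resulting subnetwork on experimental
and topological information, and induces the next, strictly smaller
subnetwork.  The retention fraction decays geometrically toward a target
module size; the best-scoring iteration's subnetwork is returned as the
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np

from .degree_bias import AdjustmentSpec, apply_adjustment, sds_adjust
from .diffusion import (
    brw_attribute_from_noi,
    build_seed_vector,
    rwr,
    stationary_distribution,
)
from .graph_model import (
    GraphConfigError,
    MultiplexComponent,
    MultiplexHeterogeneousGraph,
    build_index,
)
from .transition import BiasVector, TransitionOptions, assemble_transition

__all__ = [
    "IterationRecord",
    "ModuleResult",
    "AggregatedComponent",
    "AmendOptions",
    "aggregate_multiplex",
    "expand_module",
    "shift_scores",
    "mwcs_heuristic",
    "score_subnetwork",
    "amend_run",
]

Node = tuple[str, str]  # (component_id, node_id)


@dataclass
class IterationRecord:
    iteration: int
    n_subnetwork: int  # aggregated node count entering the iteration
    n_module: int  # MWCS output size
    experimental_term: float
    topology_term: float
    score: float
    retention_fraction: float


@dataclass
class ModuleResult:
    """Final module with per-iteration provenance.

    ``nodes`` are (component_id, node_id) pairs from the best-scoring
    iteration; ``edges`` the induced aggregated edges (primary-layer
    precedence); ``layer_subgraphs`` the expansion back to the original
    layers.  ``removal_iteration`` records, for every node of the input
    graph, the iteration at which it left the shrinking subnetwork (nodes
    surviving to the end get the total iteration count).
    """

    nodes: set[Node]
    edges: dict[tuple[Node, Node], float]
    node_attrs: dict[Node, dict]
    records: list[IterationRecord]
    selected_iteration: int
    stopping_reason: str
    layer_subgraphs: dict[str, dict[str, nx.Graph]] = field(default_factory=dict)
    removal_iteration: dict[Node, int] = field(default_factory=dict)
    total_iterations: int = 0

    def run_log(self) -> dict:
        return {
            "stopping_reason": self.stopping_reason,
            "selected_iteration": self.selected_iteration,
            "total_iterations": self.total_iterations,
            "module_size": len(self.nodes),
            "iterations": [
                {
                    "iteration": r.iteration,
                    "n_subnetwork": r.n_subnetwork,
                    "n_module": r.n_module,
                    "experimental_term": r.experimental_term,
                    "topology_term": r.topology_term,
                    "score": r.score,
                    "retention_fraction": r.retention_fraction,
                }
                for r in self.records
            ],
        }


@dataclass
class AggregatedComponent:
    """A multiplex component collapsed to one graph over the union node set."""

    component_id: str
    graph: nx.Graph  # edges carry weight + source_layer attributes
    scores: dict[str, float]


def aggregate_multiplex(
    component: MultiplexComponent,
    primary_layer: str,
    scores: Mapping[tuple[str, str], float],
    summary_fn: Callable[[Sequence[float]], float] = lambda v: float(np.mean(v)),
) -> AggregatedComponent:
    """Collapse a multiplex component onto the union node set.

    Every primary-layer edge is kept; for node pairs without a primary-
    layer edge, the first remaining layer (in layer order) that connects
    them contributes its edge.  Per-node scores are summarized (default
    mean) over the node's layer replicas; ``scores`` is keyed by
    ``(layer_id, node_id)``.
    """
    if primary_layer not in component.layer_ids:
        raise KeyError(
            f"primary layer {primary_layer!r} not in component {component.component_id!r}"
        )
    agg = nx.Graph()
    agg.add_nodes_from(component.node_union)
    ordered = [component.layer(primary_layer)] + [
        l for l in component.layers if l.layer_id != primary_layer
    ]
    for layer in ordered:
        for u, v, d in layer.graph.edges(data=True):
            if not agg.has_edge(u, v):
                agg.add_edge(
                    u, v, weight=float(d.get("weight", 1.0)), source_layer=layer.layer_id
                )
    node_scores = {}
    for v in agg.nodes:
        vals = [
            scores[(l.layer_id, v)]
            for l in component.layers
            if (l.layer_id, v) in scores
        ]
        node_scores[v] = summary_fn(vals) if vals else 0.0
    return AggregatedComponent(component.component_id, agg, node_scores)


def expand_module(
    module_nodes: set[str], component: MultiplexComponent
) -> dict[str, nx.Graph]:
    """Expand an aggregated module back to the component's original layers:
    each layer restricted to module nodes and any edges between them."""
    out = {}
    for layer in component.layers:
        keep = [v for v in layer.graph.nodes if v in module_nodes]
        out[layer.layer_id] = layer.graph.subgraph(keep).copy()
    return out


def shift_scores(
    scores: np.ndarray, retention_fraction: float
) -> tuple[np.ndarray, bool]:
    """Standardize scores and subtract the order-statistic threshold so
    that ``ceil(retention_fraction * n)`` nodes have non-negative weight.

    Diffusion scores span orders of magnitude (hub scores dominate the
    variance), so standardization is applied to log-scores: the sign
    pattern still follows score ranks, while weight magnitudes — which the
    connected-subgraph step trades off — stay commensurate.  Non-positive
    scores are clamped to a tenth of the smallest positive score first.

    Returns ``(weights, degenerate)``; ``degenerate`` is True when all
    scores are equal, in which case the weights are all zero and the
    caller should stop.  The sign pattern is invariant under positive
    affine transforms of the scores.
    """
    if not 0.0 < retention_fraction < 1.0:
        raise ValueError(f"retention fraction must lie in (0, 1), got {retention_fraction}")
    p = np.asarray(scores, dtype=float)
    n = len(p)
    if n == 0 or p.std() == 0:
        return np.zeros(n), True
    pos = p[p > 0]
    if pos.size == 0:
        return np.zeros(n), True
    logp = np.log(np.maximum(p, pos.min() / 10.0))
    sd = logp.std()
    if sd == 0:
        return np.zeros(n), True
    z = (logp - logp.mean()) / sd
    k = int(np.ceil(retention_fraction * n))
    k = min(max(k, 1), n)
    q = np.sort(z)[::-1][k - 1]  # k-th largest standardized score
    return z - q, False


def _node_costs(w: Mapping, nodes) -> dict:
    return {v: max(0.0, -float(w[v])) for v in nodes}


def mwcs_heuristic(graph: nx.Graph, w: Mapping) -> set:
    """Heuristic maximum-weight connected subgraph for signed node weights.

    Clusters of non-negative-weight nodes are contracted into supernodes
    (weight = member sum); supernodes are linked by cheapest paths whose
    cost is the summed |w| of negative nodes crossed; on a minimum
    spanning forest of those links, dynamic programming keeps the
    maximum-weight subtree.  The result is connected and its weight is at
    least the best single supernode's (hence the best single positive
    node's).  Empty when no node has non-negative weight.
    """
    pos = [v for v in graph.nodes if v in w and w[v] >= 0]
    if not pos:
        return set()
    clusters = [set(c) for c in nx.connected_components(graph.subgraph(pos))]
    cluster_w = [sum(float(w[v]) for v in c) for c in clusters]
    if len(clusters) == 1:
        return set(clusters[0])

    cost = _node_costs(w, graph.nodes)
    H = nx.Graph()
    for u, v in graph.edges:
        H.add_edge(u, v, cost=0.5 * (cost[u] + cost[v]))
    member_of = {}
    for ci, c in enumerate(clusters):
        for v in c:
            member_of[v] = ci

    # cheapest inter-cluster connections (positive endpoints cost 0, so a
    # path's cost is exactly the |w| of the negative nodes it crosses)
    K = nx.Graph()
    K.add_nodes_from(range(len(clusters)))
    paths_between: dict[tuple[int, int], list] = {}
    for ci, c in enumerate(clusters):
        dist, paths = nx.multi_source_dijkstra(H, set(c), weight="cost")
        best: dict[int, tuple[float, list]] = {}
        for v, d in dist.items():
            cj = member_of.get(v)
            if cj is None or cj == ci:
                continue
            if cj not in best or d < best[cj][0]:
                best[cj] = (d, paths[v])
        for cj, (d, path) in best.items():
            a, b = min(ci, cj), max(ci, cj)
            if not K.has_edge(a, b) or d < K[a][b]["cost"]:
                K.add_edge(a, b, cost=d)
                paths_between[(a, b)] = path

    forest = nx.minimum_spanning_tree(K, weight="cost")
    best_nodes: set = set()
    best_weight = -np.inf
    for tree_nodes in nx.connected_components(forest):
        tree = forest.subgraph(tree_nodes)
        for root in tree_nodes:
            total, kept = _best_subtree(tree, root, cluster_w)
            if total > best_weight:
                best_weight = total
                best_nodes = kept
    out: set = set()
    for ci in best_nodes:
        out |= clusters[ci]
    for a, b in forest.edges:
        if a in best_nodes and b in best_nodes:
            key = (min(a, b), max(a, b))
            out |= set(paths_between[key])
    return _explore(graph, w, _local_improve(graph, w, out))


def _explore(graph: nx.Graph, w: Mapping, out: set, rounds: int = 3) -> set:
    """Escape local optima where several expansions only pay off jointly:
    tentatively expand along the cheapest path to the most promising
    excluded non-negative node (even at a loss), re-run the improvement
    pass so follow-up attachments can recoup it, and keep the best
    solution seen."""
    if not out:
        return out

    def total(s):
        return sum(float(w[v]) for v in s if v in w)

    best, best_w = set(out), total(out)
    for _ in range(rounds):
        cost = {
            v: (0.0 if v in out else max(0.0, -float(w.get(v, 0.0))))
            for v in graph.nodes
        }
        H = nx.Graph()
        for u, v in graph.edges:
            H.add_edge(u, v, cost=0.5 * (cost[u] + cost[v]))
        dist, paths = nx.multi_source_dijkstra(H, set(out), weight="cost")
        cand, cand_gain = None, -np.inf
        for u, d in dist.items():
            if u in out or u not in w or float(w[u]) < 0:
                continue
            gain = float(w[u]) - d
            if gain > cand_gain:
                cand_gain, cand = gain, u
        if cand is None:
            break
        out = _local_improve(graph, w, out | set(paths[cand]))
        tw = total(out)
        if tw > best_w + 1e-12:
            best_w, best = tw, set(out)
    return best


def _local_improve(graph: nx.Graph, w: Mapping, out: set) -> set:
    """Grow/prune refinement of a connected candidate solution.

    Three weight-increasing, connectivity-preserving moves to a fixed
    point: attach adjacent non-negative nodes (never lowers the total);
    expand through an adjacent negative hub whose own cost is outweighed
    by the new non-negative neighbors it brings (repairs the tree-DP's
    blind spot for shared connectors, which it charges once per branch);
    drop negative non-articulation members."""
    improved = True
    while improved:
        improved = False
        boundary = {u for v in out for u in graph.neighbors(v)} - out
        adds = {u for u in boundary if u in w and w[u] >= 0}
        if adds:
            out |= adds
            improved = True
            continue
        best_gain, best_add = 0.0, None
        for v in boundary:
            if v not in w or w[v] >= 0:
                continue
            new_pos = {
                u for u in graph.neighbors(v)
                if u not in out and u in w and w[u] >= 0
            }
            gain = w[v] + sum(w[u] for u in new_pos)
            if gain > best_gain + 1e-12:
                best_gain, best_add = gain, {v} | new_pos
        if best_add:
            out |= best_add
            improved = True
            continue
        sub = graph.subgraph(out)
        articulation = set(nx.articulation_points(sub)) if len(out) > 2 else set()
        drops = [v for v in out if w.get(v, 0.0) < 0 and v not in articulation]
        if drops and len(out) > 1:
            out.remove(min(drops, key=lambda v: w[v]))
            improved = True
    return out


def _best_subtree(tree: nx.Graph, root, cluster_w) -> tuple[float, set]:
    """Tree DP: best-weight connected subtree containing ``root``.

    A child subtree is kept iff its value exceeds the connection cost.
    """
    kept = {root}
    order = list(nx.dfs_postorder_nodes(tree, root))
    parent = {root: None}
    for u, v in nx.dfs_edges(tree, root):
        parent[v] = u
    f: dict = {}
    keep_child: dict = {v: [] for v in tree.nodes}
    for v in order:
        val = cluster_w[v]
        for c in tree.neighbors(v):
            if parent.get(c) == v:
                gain = f[c] - tree[v][c]["cost"]
                if gain > 0:
                    val += gain
                    keep_child[v].append(c)
        f[v] = val
    # collect kept subtree from root
    stack = [root]
    while stack:
        v = stack.pop()
        for c in keep_child[v]:
            kept.add(c)
            stack.append(c)
    return f[root], kept


def score_subnetwork(
    nodes: set,
    seed_values: Mapping,
    graph: nx.Graph,
    standardization: tuple[float, float] | None = None,
    size_target: int | None = None,
) -> tuple[float, float, float]:
    """Score a candidate module on experimental and topological terms.

    Experimental term: mean of module nodes' seed values standardized
    against the full input network (``standardization = (mean, std)`` of
    the full network's seed values; computed from ``seed_values`` over
    ``graph`` when omitted).  Topology term: fraction of module nodes in
    the module's largest connected component times ``d / (d + 1)`` for
    mean module degree ``d``.  Both factors improve monotonically as a
    module collapses onto its best few nodes, so when ``size_target`` is
    given the topology term additionally carries the saturating size
    factor ``1 - exp(-3 |V| / size_target)``: essentially no penalty at or
    above the requested scale (0.95 at ``|V| = size_target``) but a steep
    one below about a third of it, which blocks collapse onto a
    near-singleton without dragging the optimum above the data's own
    scale.  Returns (experimental, topological, product).
    """
    if not nodes:
        raise ValueError("cannot score an empty subnetwork")
    if standardization is None:
        vals = np.array([float(seed_values.get(v, 0.0)) for v in graph.nodes])
        standardization = (float(vals.mean()), float(vals.std()))
    mean, sd = standardization
    mod_vals = np.array([float(seed_values.get(v, 0.0)) for v in nodes])
    exp_term = float((mod_vals - mean).mean() / sd) if sd > 0 else 0.0
    sub = graph.subgraph(nodes)
    lcc = max((len(c) for c in nx.connected_components(sub)), default=0)
    frac = lcc / len(nodes)
    mean_deg = 2.0 * sub.number_of_edges() / len(nodes)
    topo = frac * mean_deg / (mean_deg + 1.0)
    if size_target is not None and size_target > 0:
        topo *= 1.0 - float(np.exp(-3.0 * len(nodes) / size_target))
    return exp_term, topo, exp_term * topo


@dataclass
class AmendOptions:
    """Run options for the module search.

    ``n_target`` is the module size at which the loop stops; the retention
    fraction decays geometrically (rate ``decay``) toward it.  Crosstalk,
    normalization, degree-bias, and biased-walk settings are passed through
    to the transition/diffusion machinery each iteration; degree-bias
    adjustment recomputes the stationary distribution on the current
    subnetwork.
    """

    n_target: int = 50
    restart: float = 0.5
    decay: float = 0.5
    refine_below_target: bool = True
    min_module_size: int = 4
    lambda_switch: float | None = None
    delta_jump: float | None = None
    normalization: str = "degree"
    k_pen: float = 0.5
    adjustment: AdjustmentSpec = field(default_factory=AdjustmentSpec)
    bias_values: Mapping[str, float] | None = None  # node_id -> mu
    noi: Mapping[str, set] | set | None = None
    k_scale: float = 0.5
    primary_layers: Mapping[str, str] | None = None  # component -> layer
    summary_fn: Callable = lambda v: float(np.mean(v))
    seed_tol: float = 1e-10
    max_rwr_iter: int = 1000
    max_loop_iter: int = 100


def _aggregated_view(
    g: MultiplexHeterogeneousGraph,
    replica_scores: Mapping[tuple[str, str, str], float],
    primary_layers: Mapping[str, str],
    summary_fn: Callable,
) -> tuple[nx.Graph, dict[Node, float]]:
    """Heterogeneous graph over aggregated (component, node) pairs with
    bipartite edges preserved, plus aggregated node scores."""
    G = nx.Graph()
    scores: dict[Node, float] = {}
    for c in g.components:
        layer_scores = {
            (l.layer_id, v): replica_scores[(c.component_id, l.layer_id, v)]
            for l in c.layers
            for v in l.graph.nodes
        }
        agg = aggregate_multiplex(
            c, primary_layers[c.component_id], layer_scores, summary_fn
        )
        for v in agg.graph.nodes:
            node = (c.component_id, v)
            G.add_node(node)
            scores[node] = agg.scores[v]
        for u, v, d in agg.graph.edges(data=True):
            G.add_edge((c.component_id, u), (c.component_id, v), **d)
    for (ca, cb), edges in g.bipartite_edges.items():
        for u, v, w in edges:
            a, b = (ca, u), (cb, v)
            if G.has_node(a) and G.has_node(b) and not G.has_edge(a, b):
                G.add_edge(a, b, weight=float(w), source_layer="bipartite")
    return G, scores


def _node_seed_values(
    g: MultiplexHeterogeneousGraph, seeds: Mapping
) -> dict[Node, float]:
    out: dict[Node, float] = {}
    for c in g.components:
        for l in c.layers:
            vmap = seeds.get((c.component_id, l.layer_id), seeds.get(c.component_id, {}))
            for v in l.graph.nodes:
                key = (c.component_id, v)
                if v in vmap:
                    prev = out.get(key)
                    val = float(vmap[v])
                    out[key] = val if prev is None else 0.5 * (prev + val)
                else:
                    out.setdefault(key, 0.0)
    return out


def amend_run(
    g: MultiplexHeterogeneousGraph,
    seeds: Mapping,
    opts: AmendOptions | None = None,
) -> ModuleResult:
    """Run the full iterative module search on ``g``.

    ``seeds`` maps ``(component_id, layer_id)`` or ``component_id`` to
    ``{node_id: value >= 0}`` (the same convention as
    :func:`~amend.diffusion.build_seed_vector`).  Returns the
    best-scoring iteration's subnetwork as the module.
    """
    opts = opts or AmendOptions()
    if opts.n_target < 1:
        raise ValueError("n_target must be >= 1")
    primary = dict(opts.primary_layers or {})
    for c in g.components:
        primary.setdefault(c.component_id, c.layers[0].layer_id)
        if primary[c.component_id] not in c.layer_ids:
            raise KeyError(
                f"primary layer {primary[c.component_id]!r} not in component "
                f"{c.component_id!r}"
            )

    # distance-decay bias from nodes of interest is computed once, on the
    # full input graph, then broadcast to each iteration's replicas
    bias_node_values: dict[str, float] | None = None
    if opts.noi is not None:
        bv = brw_attribute_from_noi(g, opts.noi, opts.k_scale)
        idx0 = build_index(g)
        acc: dict[str, list[float]] = {}
        for i, (_c, _l, v) in enumerate(idx0.triples):
            acc.setdefault(v, []).append(bv.mu[i])
        bias_node_values = {v: float(np.mean(m)) for v, m in acc.items()}
    elif opts.bias_values is not None:
        bias_node_values = {k: float(v) for k, v in opts.bias_values.items()}

    full_seed_by_node = _node_seed_values(g, seeds)
    vals = np.array(list(full_seed_by_node.values()))
    standardization = (float(vals.mean()), float(vals.std()))

    current = g
    records: list[IterationRecord] = []
    iter_modules: list[set[Node]] = []
    removal_iteration: dict[Node, int] = {}
    stopping = "max_loop_iter"
    reached_target = False
    for it in range(1, opts.max_loop_iter + 1):
        index = build_index(current)
        topts = TransitionOptions(
            lambda_switch=opts.lambda_switch,
            delta_jump=opts.delta_jump,
            normalization=opts.normalization,
            k_pen=opts.k_pen,
            bias=BiasVector.from_node_values(index, bias_node_values)
            if bias_node_values
            else None,
        )
        tm = assemble_transition(current, topts, index=index)
        tm = apply_adjustment(tm, opts.adjustment)
        sv = build_seed_vector(current, seeds, index=index)
        res = rwr(tm, sv, r=opts.restart, tol=opts.seed_tol, max_iter=opts.max_rwr_iter)
        p = res.p
        if opts.adjustment.method == "sds":
            s = stationary_distribution(tm)
            p = np.nan_to_num(sds_adjust(p, s), nan=0.0)
        replica_scores = {t: float(p[i]) for i, t in enumerate(index.triples)}
        agg_graph, agg_scores = _aggregated_view(
            current, replica_scores, primary, opts.summary_fn
        )
        nodes_order = list(agg_graph.nodes)
        n_current = len(nodes_order)
        # the target counts as reached once a decay step would overshoot
        # it; from there, optionally keep shrinking while the module score
        # improves — the returned module is the best-scoring iteration and
        # may be more compact than the target
        if opts.decay * n_current < opts.n_target:
            reached_target = True
        floor = (
            float(opts.min_module_size)
            if (reached_target and opts.refine_below_target)
            else float(opts.n_target)
        )
        target_next = max(floor, opts.decay * n_current)
        rf = min(target_next / n_current, 1.0 - 1e-12)
        weights_arr, degenerate = shift_scores(
            np.array([agg_scores[v] for v in nodes_order]), rf
        )
        weights = dict(zip(nodes_order, weights_arr))
        if degenerate:
            stopping = "degenerate_scores"
            if not records:
                raise GraphConfigError(
                    "diffusion scores are constant on the input graph; "
                    "cannot rank nodes for module extraction"
                )
            break
        module_nodes = mwcs_heuristic(agg_graph, weights)
        if module_nodes and len(module_nodes) >= n_current and rf > opts.decay and floor < n_current:
            # a near-1 retention kept everything; force a full decay step
            # so the loop makes progress instead of stalling at the target
            rf = min(max(floor / n_current, opts.decay), 1.0 - 1e-12)
            weights_arr, degenerate = shift_scores(
                np.array([agg_scores[v] for v in nodes_order]), rf
            )
            weights = dict(zip(nodes_order, weights_arr))
            module_nodes = mwcs_heuristic(agg_graph, weights)
        if not module_nodes:
            stopping = "no_positive_weights"
            if not records:
                raise GraphConfigError(
                    "no positively weighted node at iteration 1: the seed "
                    "support may be disconnected from the rest of the graph"
                )
            break
        exp_t, topo_t, score = score_subnetwork(
            module_nodes,
            full_seed_by_node,
            agg_graph,
            standardization,
            size_target=opts.n_target,
        )
        records.append(
            IterationRecord(
                iteration=it,
                n_subnetwork=n_current,
                n_module=len(module_nodes),
                experimental_term=exp_t,
                topology_term=topo_t,
                score=score,
                retention_fraction=rf,
            )
        )
        iter_modules.append(set(module_nodes))
        for v in nodes_order:
            if v not in module_nodes:
                removal_iteration.setdefault(v, it)
        keep: dict[str, set] = {}
        for cid, nid in module_nodes:
            keep.setdefault(cid, set()).add(nid)
        current = current.subgraph(keep)
        if len(module_nodes) >= n_current:
            stopping = "no_shrinkage"
            break
        if opts.refine_below_target:
            if reached_target and len(records) >= 2 and records[-1].score < records[-2].score:
                stopping = "score_declined"
                break
            if len(module_nodes) <= opts.min_module_size:
                stopping = "minimum_size"
                break
        elif len(module_nodes) <= opts.n_target:
            stopping = "target_size"
            break

    total_iters = len(records)
    best_i = int(np.argmax([r.score for r in records]))
    best_nodes = iter_modules[best_i]
    for v in best_nodes:
        removal_iteration.setdefault(v, total_iters)

    # materialize the selected module: rerun diffusion provenance is not
    # needed; induce aggregated edges on the ORIGINAL graph
    keep = {}
    for cid, nid in best_nodes:
        keep.setdefault(cid, set()).add(nid)
    sel = g.subgraph(keep)
    # aggregated scores for the selected module come from the iteration in
    # which it was extracted; recompute attrs from the original graph
    sel_graph, _ = _aggregated_view(
        sel,
        {
            (c.component_id, l.layer_id, v): 0.0
            for c in sel.components
            for l in c.layers
            for v in l.graph.nodes
        },
        primary,
        opts.summary_fn,
    )
    edges = {
        (u, v): float(d.get("weight", 1.0)) for u, v, d in sel_graph.edges(data=True)
    }
    node_attrs = {}
    for node in best_nodes:
        cid, nid = node
        comp = g.component(cid)
        node_attrs[node] = {
            "layers": [l.layer_id for l in comp.layers if nid in l.graph.nodes],
            "seed_value": full_seed_by_node.get(node, 0.0),
            "score": 0.0,
        }
    layer_subgraphs = {
        c.component_id: expand_module(keep.get(c.component_id, set()), c)
        for c in g.components
    }
    return ModuleResult(
        nodes=best_nodes,
        edges=edges,
        node_attrs=node_attrs,
        records=records,
        selected_iteration=records[best_i].iteration,
        stopping_reason=stopping,
        layer_subgraphs=layer_subgraphs,
        removal_iteration=removal_iteration,
        total_iterations=total_iters,
    )
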