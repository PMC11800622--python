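"""Benchmarking procedures: cross-validated node ranking, score–degree
correlation, and paired biased-vs-unbiased module-search metrics."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

from .degree_bias import AdjustmentSpec, apply_adjustment, sds_adjust
from .diffusion import build_seed_vector, rwr, stationary_distribution
from .graph_model import GraphConfigError, MultiplexHeterogeneousGraph, build_index
from .module_search import AmendOptions, amend_run
from .transition import TransitionOptions, assemble_transition

__all__ = [
    "RankingRun",
    "kfold_rank_eval",
    "score_degree_correlation",
    "brw_impact_eval",
    "read_gmt",
    "ecdf",
    "collapsed_scores",
]


def read_gmt(path: str) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = parts[2:]
    return out


def ecdf(sample: Sequence[float]) -> "np.vectorize":
    """Empirical CDF of ``sample`` as a callable F(x) = P(X <= x)."""
    xs = np.sort(np.asarray(sample, dtype=float))

    def _f(x):
        return np.searchsorted(xs, x, side="right") / len(xs)

    return np.vectorize(_f)


def collapsed_scores(index, p: np.ndarray) -> dict[tuple[str, str], float]:
    """Mean replica score per (component, node) pair."""
    acc: dict[tuple[str, str], list[float]] = {}
    for i, (cid, _lid, nid) in enumerate(index.triples):
        acc.setdefault((cid, nid), []).append(float(p[i]))
    return {k: float(np.mean(v)) for k, v in acc.items()}


def _diffuse(
    g: MultiplexHeterogeneousGraph,
    seed_values: Mapping,
    r: float,
    topts: TransitionOptions,
    adjustment: AdjustmentSpec,
):
    index = build_index(g)
    tm = assemble_transition(g, topts, index=index)
    tm = apply_adjustment(tm, adjustment)
    sv = build_seed_vector(g, seed_values, index=index)
    p = rwr(tm, sv, r=r).p
    if adjustment.method == "sds":
        p = np.nan_to_num(sds_adjust(p, stationary_distribution(tm)), nan=0.0)
    return index, p


@dataclass
class RankingRun:
    """Pooled test-fold ranks from k-fold cross-validated diffusion."""

    ranks: list[int] = field(default_factory=list)
    records: list[dict] = field(default_factory=list)
    n_rankable: int = 0
    skipped_sets: list[str] = field(default_factory=list)

    def rank_ecdf(self, grid: Sequence[int] | None = None) -> pd.DataFrame:
        ranks = np.asarray(self.ranks)
        if grid is None:
            grid = np.unique(ranks)
        f = ecdf(ranks)
        return pd.DataFrame({"rank": grid, "cumulative_probability": f(grid)})


def kfold_rank_eval(
    g: MultiplexHeterogeneousGraph,
    gene_sets: Mapping[str, Sequence[str]],
    k_folds: int = 5,
    r: float = 0.5,
    transition_opts: TransitionOptions | None = None,
    adjustment: AdjustmentSpec | None = None,
    min_set_size: int | None = None,
    fold_seed: int = 0,
) -> RankingRun:
    """Cross-validated guilt-by-association ranking.

    Each gene set is split into ``k_folds`` folds; members of the training
    folds become seeds with equal mass, diffusion runs, and the ranks of
    the held-out members among all non-seed (replica-collapsed) nodes are
    pooled.  Ties share the mean rank.  Sets with fewer than
    ``min_set_size`` (default ``k_folds``) members present in the graph
    are skipped.
    """
    topts = transition_opts or TransitionOptions()
    adj = adjustment or AdjustmentSpec()
    min_size = min_set_size or k_folds
    rng = np.random.default_rng(fold_seed)
    present: dict[tuple[str, str], None] = {}
    for c in g.components:
        for nid in c.node_union:
            present[(c.component_id, nid)] = None
    node_components: dict[str, list[str]] = {}
    for cid, nid in present:
        node_components.setdefault(nid, []).append(cid)

    run = RankingRun()
    for name, members in gene_sets.items():
        mem = sorted({m for m in members if m in node_components})
        if len(mem) < max(min_size, k_folds):
            run.skipped_sets.append(name)
            continue
        order = list(rng.permutation(len(mem)))
        folds = [sorted(mem[i] for i in order[f::k_folds]) for f in range(k_folds)]
        for fi, test in enumerate(folds):
            train = [m for f2, fold in enumerate(folds) if f2 != fi for m in fold]
            seed_values = {m: 1.0 for m in train}
            values = {cid: seed_values for cid in g.component_ids}
            index, p = _diffuse(g, values, r, topts, adj)
            coll = collapsed_scores(index, p)
            seed_keys = {
                (cid, m) for m in train for cid in node_components[m]
            }
            keys = [k for k in coll if k not in seed_keys]
            scores = np.array([coll[k] for k in keys])
            rk = rankdata(-scores, method="average")
            rank_of = dict(zip(keys, rk))
            run.n_rankable = len(keys)
            for m in test:
                node_ranks = [
                    rank_of[(cid, m)]
                    for cid in node_components[m]
                    if (cid, m) in rank_of
                ]
                if node_ranks:
                    best = float(min(node_ranks))
                    run.ranks.append(best)
                    run.records.append(
                        {"set": name, "fold": fi, "node": m, "rank": best}
                    )
    return run


def replica_degrees(g: MultiplexHeterogeneousGraph, index) -> np.ndarray:
    """Unweighted intra-layer degree of every replica."""
    deg = np.zeros(index.n)
    for c in g.components:
        for l in c.layers:
            for v in l.graph.nodes:
                i = index.index(c.component_id, l.layer_id, v)
                deg[i] = l.graph.degree(v)
    return deg


def score_degree_correlation(
    g: MultiplexHeterogeneousGraph,
    seed_sets: Sequence[Mapping],
    r: float = 0.5,
    transition_opts: TransitionOptions | None = None,
    adjustment: AdjustmentSpec | None = None,
) -> pd.DataFrame:
    """Pearson correlation between diffusion score and replica degree, one
    row per seed set plus the mean; constant scores yield NaN."""
    topts = transition_opts or TransitionOptions()
    adj = adjustment or AdjustmentSpec()
    rows = []
    for si, seeds in enumerate(seed_sets):
        values = seeds if _is_keyed_by_component(seeds, g) else {
            cid: seeds for cid in g.component_ids
        }
        index, p = _diffuse(g, values, r, topts, adj)
        deg = replica_degrees(g, index)
        if np.std(p) == 0 or np.std(deg) == 0:
            rows.append({"seed_set": si, "pearson_r": np.nan})
        else:
            rows.append({"seed_set": si, "pearson_r": float(pearsonr(p, deg)[0])})
    df = pd.DataFrame(rows)
    df.loc[len(df)] = {"seed_set": "mean", "pearson_r": df["pearson_r"].mean()}
    return df


def _is_keyed_by_component(seeds: Mapping, g: MultiplexHeterogeneousGraph) -> bool:
    ids = set(g.component_ids)
    return all(isinstance(k, (tuple,)) or k in ids for k in seeds)


def _collapsed_graph(g: MultiplexHeterogeneousGraph) -> nx.Graph:
    """(component, node)-level graph with all edge classes, for distances."""
    G = nx.Graph()
    for c in g.components:
        for nid in c.node_union:
            G.add_node((c.component_id, nid))
        for l in c.layers:
            for u, v in l.graph.edges:
                G.add_edge((c.component_id, u), (c.component_id, v))
    for (ca, cb), edges in g.bipartite_edges.items():
        for u, v, _w in edges:
            G.add_edge((ca, u), (cb, v))
    return G


def brw_impact_eval(
    g: MultiplexHeterogeneousGraph,
    seeds: Mapping,
    noi_sets: Sequence[set],
    k_scale: float = 0.5,
    opts: AmendOptions | None = None,
) -> pd.DataFrame:
    """Paired module searches, unbiased vs distance-decay biased toward
    nodes of interest (NOI).

    Reports, per NOI set: mean scaled iteration-of-removal of the NOI
    (iteration at which a node leaves the shrinking subnetwork, divided by
    the run's total iterations) and mean full-graph distance from module
    nodes to the NOI, for both runs, plus the differences (biased minus
    unbiased for removal; biased minus unbiased for distance, expected
    <= 0 when the bias pulls the module toward the NOI).
    """
    base = opts or AmendOptions()
    known = {nid for c in g.components for nid in c.node_union}
    for noi in noi_sets:
        missing = set(noi) - known
        if missing:
            raise GraphConfigError(f"nodes of interest absent from graph: {sorted(missing)}")
    import dataclasses

    res_plain = amend_run(g, seeds, dataclasses.replace(base, noi=None, bias_values=None))
    G = _collapsed_graph(g)
    rows = []
    for si, noi in enumerate(noi_sets):
        res_bias = amend_run(g, seeds, dataclasses.replace(base, noi=set(noi), k_scale=k_scale))
        rows.append(
            {
                "noi_set": si,
                "removal_unbiased": _scaled_removal(res_plain, g, noi),
                "removal_biased": _scaled_removal(res_bias, g, noi),
                "distance_unbiased": _module_noi_distance(G, res_plain.nodes, noi),
                "distance_biased": _module_noi_distance(G, res_bias.nodes, noi),
            }
        )
    df = pd.DataFrame(rows)
    df["removal_diff"] = df["removal_biased"] - df["removal_unbiased"]
    df["distance_diff"] = df["distance_biased"] - df["distance_unbiased"]
    return df


def _scaled_removal(result, g: MultiplexHeterogeneousGraph, noi: set) -> float:
    vals = []
    for c in g.components:
        for nid in c.node_union:
            if nid in noi:
                it = result.removal_iteration.get(
                    (c.component_id, nid), result.total_iterations
                )
                vals.append(it / max(result.total_iterations, 1))
    return float(np.mean(vals)) if vals else np.nan


def _module_noi_distance(G: nx.Graph, module_nodes: set, noi: set) -> float:
    targets = [v for v in G.nodes if v[1] in noi]
    if not targets or not module_nodes:
        return np.nan
    dist = nx.multi_source_dijkstra_path_length(G, set(targets))
    finite = [d for d in dist.values() if np.isfinite(d)]
    fill = (max(finite) + 1.0) if finite else 1.0
    return float(np.mean([dist.get(v, fill) for v in module_nodes]))
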