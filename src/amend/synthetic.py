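"""Synthetic multiplex-heterogeneous graphs, seed values and planted modules.

The generators emulate the interactome-style inputs the algorithm is built
for: scale-free layers (preferential attachment, reproducing the hub
structure that makes degree-bias adjustment meaningful) or Erdős–Rényi
layers, partial node-set overlap between layers of a multiplex, sparse
bipartite couplings between components, and a connected planted module
whose seed values are drawn from a shifted half-normal against a
half-normal background.  Everything is deterministic given the RNG seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import yaml

from .graph_model import (
    GraphConfigError,
    Layer,
    MultiplexComponent,
    MultiplexHeterogeneousGraph,
)

__all__ = [
    "LayerSpec",
    "ComponentSpec",
    "SyntheticSpec",
    "generate_graph",
    "plant_module",
    "monoplex",
    "seeds_anticorrelated_with_degree",
    "write_synthetic",
]


@dataclass
class LayerSpec:
    layer_id: str
    n_nodes: int
    model: str = "scale_free"  # scale_free (preferential attachment) | erdos_renyi
    m_attach: int = 2  # preferential-attachment edges per new node
    density: float = 0.01  # erdos_renyi edge probability


@dataclass
class ComponentSpec:
    component_id: str
    layers: list[LayerSpec]
    overlap: float = 0.5  # fraction of a secondary layer's nodes shared with layer 1
    tau: list[float] | None = None


@dataclass
class SyntheticSpec:
    components: list[ComponentSpec]
    bipartite_density: float = 0.002
    eta: list[float] | None = None
    lambda_switch: float = 0.5
    delta_jump: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for c in self.components:
            if not 0.0 <= c.overlap <= 1.0:
                raise GraphConfigError(f"overlap must lie in [0, 1], got {c.overlap}")
        if not 0.0 <= self.bipartite_density <= 1.0:
            raise GraphConfigError("bipartite density must lie in [0, 1]")


def _layer_graph(spec: LayerSpec, rng: np.random.Generator) -> nx.Graph:
    seed = int(rng.integers(2**31 - 1))
    if spec.model == "scale_free":
        m = min(spec.m_attach, max(1, spec.n_nodes - 1))
        return nx.barabasi_albert_graph(spec.n_nodes, m, seed=seed)
    if spec.model == "erdos_renyi":
        return nx.gnp_random_graph(spec.n_nodes, spec.density, seed=seed)
    raise GraphConfigError(f"unknown layer model {spec.model!r}")


def generate_graph(spec: SyntheticSpec) -> MultiplexHeterogeneousGraph:
    """Realize a :class:`SyntheticSpec` into a graph.

    Secondary layers of a multiplex share ``round(overlap * n)`` node ids
    with the first layer (sampled uniformly); the rest get fresh ids.
    Bipartite edges are sampled independently between the node unions of
    each component pair at the requested density.
    """
    rng = np.random.default_rng(spec.seed)
    comps = []
    for cspec in spec.components:
        layers = []
        counter = 0
        first_ids: list[str] = []
        for li, lspec in enumerate(cspec.layers):
            raw = _layer_graph(lspec, rng)
            if li == 0:
                ids = [f"{cspec.component_id}_n{counter + i}" for i in range(lspec.n_nodes)]
                counter += lspec.n_nodes
                first_ids = ids
            else:
                n_shared = int(round(cspec.overlap * lspec.n_nodes))
                if n_shared > len(first_ids):
                    raise GraphConfigError(
                        f"layer {lspec.layer_id!r}: overlap requests {n_shared} shared "
                        f"nodes but layer 1 has only {len(first_ids)}"
                    )
                shared = list(rng.choice(first_ids, size=n_shared, replace=False))
                fresh = [
                    f"{cspec.component_id}_n{counter + i}"
                    for i in range(lspec.n_nodes - n_shared)
                ]
                counter += lspec.n_nodes - n_shared
                ids = shared + fresh
                perm = rng.permutation(lspec.n_nodes)
                ids = [ids[i] for i in perm]
            mapping = dict(zip(range(lspec.n_nodes), ids))
            g = nx.relabel_nodes(raw, mapping)
            nx.set_edge_attributes(g, 1.0, "weight")
            layers.append(Layer(lspec.layer_id, g))
        comps.append(
            MultiplexComponent(
                cspec.component_id,
                layers,
                tau=np.asarray(cspec.tau, dtype=float) if cspec.tau else None,
            )
        )

    bip: dict[tuple[str, str], list[tuple[str, str, float]]] = {}
    if spec.bipartite_density > 0:
        for a in range(len(comps)):
            for b in range(a + 1, len(comps)):
                ua = sorted(comps[a].node_union)
                ub = sorted(comps[b].node_union)
                n_edges = int(round(spec.bipartite_density * len(ua) * len(ub)))
                if n_edges == 0:
                    continue
                ia = rng.integers(0, len(ua), size=n_edges)
                ib = rng.integers(0, len(ub), size=n_edges)
                edges = sorted({(ua[i], ub[j], 1.0) for i, j in zip(ia, ib)})
                bip[(comps[a].component_id, comps[b].component_id)] = edges
    return MultiplexHeterogeneousGraph(
        comps,
        bipartite_edges=bip,
        eta=np.asarray(spec.eta, dtype=float) if spec.eta else None,
        lambda_switch=spec.lambda_switch,
        delta_jump=spec.delta_jump,
    )


def plant_module(
    g: MultiplexHeterogeneousGraph,
    size: int,
    effect: float,
    rng: np.random.Generator | int = 0,
    component_id: str | None = None,
    layer_id: str | None = None,
    max_attempts: int = 50,
) -> tuple[set[str], dict[str, dict[str, float]]]:
    """Plant a connected high-seed module and draw seed values.

    A connected subgraph of ``size`` nodes is sampled by a random walk in
    the chosen layer (default: first layer of the first component); its
    nodes get seed values |Normal(effect, 1)| while every other node in the
    graph draws from |Normal(0, 1)|.  Returns ``(truth_nodes,
    seed_value_maps)`` with seed maps keyed by component id.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    comp = g.component(component_id) if component_id else g.components[0]
    layer = comp.layer(layer_id) if layer_id else comp.layers[0]
    if size > layer.n_nodes:
        raise GraphConfigError(
            f"cannot plant a {size}-node module in a {layer.n_nodes}-node layer"
        )
    G = layer.graph
    truth: set[str] = set()
    for _ in range(max_attempts):
        nodes = list(G.nodes)
        start = nodes[int(rng.integers(len(nodes)))]
        truth = {start}
        frontier = [start]
        stalled = 0
        while len(truth) < size and stalled < 10 * size:
            v = frontier[int(rng.integers(len(frontier)))]
            nbrs = [u for u in G.neighbors(v) if u not in truth]
            if not nbrs:
                stalled += 1
                continue
            u = nbrs[int(rng.integers(len(nbrs)))]
            truth.add(u)
            frontier.append(u)
        if len(truth) == size:
            break
    else:
        raise GraphConfigError(
            f"failed to sample a connected {size}-node subgraph in {max_attempts} attempts"
        )
    seeds: dict[str, dict[str, float]] = {}
    for c in g.components:
        vmap = {}
        for v in sorted(c.node_union):
            if c.component_id == comp.component_id and v in truth:
                vmap[v] = float(abs(rng.normal(effect, 1.0)))
            else:
                vmap[v] = float(abs(rng.normal(0.0, 1.0)))
        seeds[c.component_id] = vmap
    return truth, seeds


def powerlaw_ppi_graph(
    n: int,
    seed: int = 0,
    gamma: float = 2.5,
    mean_degree: float = 30.0,
) -> nx.Graph:
    """A PPI-like benchmark graph: Chung–Lu (expected-degree) model with
    power-law weights of exponent ``gamma``, restricted to its giant
    component.

    Interactome graphs are dense (STRING-scale networks average ~30
    interactions per protein) with a continuous spread of degrees; the
    Chung–Lu construction reproduces both, unlike preferential attachment
    whose minimum degree is a constant shared by half the nodes.
    """
    w = np.arange(1, n + 1, dtype=float) ** (-1.0 / (gamma - 1.0))
    w = w / w.mean() * mean_degree
    G = nx.expected_degree_graph(w.tolist(), seed=seed, selfloops=False)
    G = G.subgraph(max(nx.connected_components(G), key=len)).copy()
    return nx.convert_node_labels_to_integers(G)


def monoplex(
    graph: nx.Graph, component_id: str = "c1", layer_id: str = "l1"
) -> MultiplexHeterogeneousGraph:
    """Wrap a plain weighted graph as a one-component, one-layer instance."""
    g = graph.copy()
    for _u, _v, d in g.edges(data=True):
        d.setdefault("weight", 1.0)
    return MultiplexHeterogeneousGraph(
        [MultiplexComponent(component_id, [Layer(layer_id, g)])]
    )


def seeds_anticorrelated_with_degree(
    graph: nx.Graph,
    rng: np.random.Generator | int = 0,
    de_fraction: float = 0.1,
) -> dict[str, float]:
    """Seed values perfectly negatively rank-correlated with degree.

    Values emulate -log10(p) from a differential-expression screen: a
    ``de_fraction`` of genes are truly changed (p uniform on the log scale
    down to 1e-8) and the rest are null (p ~ U(0,1)), giving the heavy
    right tail such seeds have in practice.  Sorted values are assigned so
    the largest lands on the lowest-degree node (degree ties broken by
    node id)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = len(graph)
    n_de = int(round(de_fraction * n))
    neglogp = np.concatenate(
        [rng.uniform(2.0, 8.0, size=n_de), -np.log10(rng.uniform(size=n - n_de))]
    )
    nodes = sorted(graph.nodes, key=lambda v: (graph.degree(v), str(v)))
    vals = np.sort(neglogp)[::-1]
    return {v: float(x) for v, x in zip(nodes, vals)}


def write_synthetic(
    g: MultiplexHeterogeneousGraph,
    seeds: dict[str, dict[str, float]],
    out_dir: str,
) -> str:
    """Write a generated graph to the package's on-disk formats: per-layer
    edge TSVs, per-pair bipartite TSVs, per-component seed tables, and a
    YAML config tying them together.  Returns the config path."""
    os.makedirs(out_dir, exist_ok=True)
    cfg: dict = {"components": [], "bipartite": []}
    for c in g.components:
        cc = {"id": c.component_id, "tau": [float(t) for t in c.tau], "layers": []}
        for l in c.layers:
            fname = f"{c.component_id}__{l.layer_id}.tsv"
            with open(os.path.join(out_dir, fname), "w") as fh:
                fh.write("source\ttarget\tweight\n")
                for u, v, d in sorted(l.graph.edges(data=True)):
                    fh.write(f"{u}\t{v}\t{d.get('weight', 1.0)}\n")
            nodes_fname = f"{c.component_id}__{l.layer_id}.nodes.txt"
            with open(os.path.join(out_dir, nodes_fname), "w") as fh:
                fh.write("\n".join(l.node_ids) + "\n")
            cc["layers"].append({"id": l.layer_id, "edges": fname, "nodes": nodes_fname})
        cfg["components"].append(cc)
    for (ca, cb), edges in g.bipartite_edges.items():
        fname = f"bipartite__{ca}__{cb}.tsv"
        with open(os.path.join(out_dir, fname), "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, w in sorted(edges):
                fh.write(f"{u}\t{v}\t{w}\n")
        cfg["bipartite"].append({"between": [ca, cb], "edges": fname})
    cfg["eta"] = [float(e) for e in g.eta]
    cfg["lambda"] = float(g.lambda_switch)
    cfg["delta"] = float(g.delta_jump)
    for cid, vmap in seeds.items():
        with open(os.path.join(out_dir, f"seeds__{cid}.tsv"), "w") as fh:
            fh.write("node_id\tvalue\n")
            for v in sorted(vmap):
                fh.write(f"{v}\t{vmap[v]}\n")
    path = os.path.join(out_dir, "config.yaml")
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path
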