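"""Typed representation of multiplex-heterogeneous graphs and file IO.

A *multiplex component* is a set of graph layers over a single node type
(e.g. a physical-interaction layer and a functional-association layer over
proteins); layers may have arbitrary, even disjoint, node sets.  A
*heterogeneous graph* couples several components (node types) through
bipartite edge sets.  Node identity across layers and components is by
exact string match of ``node_id``; no identifier mapping is performed.

All graphs are undirected and non-negatively weighted.  Replicas of a node
in different layers are distinct walk states; :class:`GlobalIndex` assigns
each replica a unique integer used by the sparse linear algebra downstream.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Layer",
    "MultiplexComponent",
    "MultiplexHeterogeneousGraph",
    "GlobalIndex",
    "GraphConfigError",
    "read_edge_list",
    "read_seed_table",
    "read_graph",
    "build_index",
    "write_module",
]

_SIMPLEX_TOL = 1e-8


class GraphConfigError(ValueError):
    """Raised for invalid graph configuration (constraint violations, bad files)."""


def _check_simplex(w: Sequence[float], name: str) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise GraphConfigError(
            f"{name} weights must satisfy the simplex constraint "
            f"(all entries >= 0); got {w.tolist()}"
        )
    if abs(w.sum() - 1.0) > _SIMPLEX_TOL:
        raise GraphConfigError(
            f"{name} weights must satisfy the simplex constraint "
            f"(sum to 1); got sum {w.sum()!r} for {w.tolist()}"
        )
    return w


@dataclass
class Layer:
    """One layer of a multiplex component: an undirected weighted graph."""

    layer_id: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(
        cls,
        layer_id: str,
        edges: Iterable[tuple[str, str, float]],
        nodes: Iterable[str] = (),
        allow_self_loops: bool = False,
    ) -> "Layer":
        """Build a layer from an edge iterable, collapsing duplicate pairs by
        summing weights and rejecting negative weights and self-loops."""
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v, w in edges:
            w = float(w)
            if w < 0:
                raise GraphConfigError(
                    f"layer {layer_id!r}: negative weight {w} on edge ({u}, {v})"
                )
            if u == v and not allow_self_loops:
                raise GraphConfigError(
                    f"layer {layer_id!r}: self-loop on node {u!r} not allowed"
                )
            if g.has_edge(u, v):
                g[u][v]["weight"] += w
            else:
                g.add_edge(u, v, weight=w)
        return cls(layer_id, g)

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class MultiplexComponent:
    """Ordered layers over one node type, plus layer seed weights tau.

    ``tau`` must lie on the probability simplex over layers.  Replicas of a
    shared ``node_id`` in different layers are coupled by an inter-layer
    edge of weight ``interlayer_weight``.
    """

    component_id: str
    layers: list[Layer]
    tau: np.ndarray | None = None
    interlayer_weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.layers:
            raise GraphConfigError(
                f"component {self.component_id!r} must have at least one layer"
            )
        if self.tau is None:
            self.tau = np.full(len(self.layers), 1.0 / len(self.layers))
        else:
            self.tau = _check_simplex(self.tau, f"tau (component {self.component_id!r})")
            if len(self.tau) != len(self.layers):
                raise GraphConfigError(
                    f"component {self.component_id!r}: tau has {len(self.tau)} "
                    f"entries for {len(self.layers)} layers"
                )

    @property
    def layer_ids(self) -> list[str]:
        return [l.layer_id for l in self.layers]

    def layer(self, layer_id: str) -> Layer:
        for l in self.layers:
            if l.layer_id == layer_id:
                return l
        raise KeyError(f"no layer {layer_id!r} in component {self.component_id!r}")

    @property
    def node_union(self) -> set[str]:
        out: set[str] = set()
        for l in self.layers:
            out |= set(l.graph.nodes)
        return out


@dataclass
class MultiplexHeterogeneousGraph:
    """Components plus inter-component bipartite couplings and crosstalk.

    ``eta`` weights the components' seed vectors (simplex constraint).
    ``lambda_switch`` is the probability of switching layers within a
    multiplex; ``delta_jump`` the probability of jumping to another
    component over a bipartite edge.  Both live in [0, 1]; mass for absent
    target classes is redistributed at transition-matrix build time.
    """

    components: list[MultiplexComponent]
    bipartite_edges: dict[tuple[str, str], list[tuple[str, str, float]]] = field(
        default_factory=dict
    )
    eta: np.ndarray | None = None
    lambda_switch: float = 0.5
    delta_jump: float = 0.5

    def __post_init__(self) -> None:
        if not self.components:
            raise GraphConfigError("graph must have at least one component")
        ids = [c.component_id for c in self.components]
        if len(set(ids)) != len(ids):
            raise GraphConfigError(f"duplicate component ids: {ids}")
        if self.eta is None:
            self.eta = np.full(len(self.components), 1.0 / len(self.components))
        else:
            self.eta = _check_simplex(self.eta, "eta")
            if len(self.eta) != len(self.components):
                raise GraphConfigError(
                    f"eta has {len(self.eta)} entries for "
                    f"{len(self.components)} components"
                )
        for p in (self.lambda_switch, self.delta_jump):
            if not 0.0 <= p <= 1.0:
                raise GraphConfigError(f"crosstalk probability {p} outside [0, 1]")
        # normalize pair keys and validate endpoints
        norm: dict[tuple[str, str], list[tuple[str, str, float]]] = {}
        for (ca, cb), edges in self.bipartite_edges.items():
            for cid in (ca, cb):
                if cid not in ids:
                    raise GraphConfigError(f"bipartite pair references unknown component {cid!r}")
            na, nb = self.component(ca).node_union, self.component(cb).node_union
            for u, v, w in edges:
                if u not in na:
                    raise GraphConfigError(
                        f"bipartite edge ({u!r}, {v!r}): node {u!r} not in component {ca!r}"
                    )
                if v not in nb:
                    raise GraphConfigError(
                        f"bipartite edge ({u!r}, {v!r}): node {v!r} not in component {cb!r}"
                    )
                if float(w) < 0:
                    raise GraphConfigError(f"negative bipartite weight on ({u}, {v})")
            norm[(ca, cb)] = [(u, v, float(w)) for u, v, w in edges]
        self.bipartite_edges = norm

    @property
    def component_ids(self) -> list[str]:
        return [c.component_id for c in self.components]

    def component(self, component_id: str) -> MultiplexComponent:
        for c in self.components:
            if c.component_id == component_id:
                return c
        raise KeyError(f"no component {component_id!r}")

    def subgraph(self, keep: Mapping[str, set[str]]) -> "MultiplexHeterogeneousGraph":
        """Induce the graph on ``keep[component_id]`` node sets.

        Layers are restricted to the retained nodes and any edges between
        them; bipartite edges keep only pairs whose endpoints both survive.
        Crosstalk and seed-weight parameters carry over unchanged.
        """
        comps = []
        for c in self.components:
            nodes = keep.get(c.component_id, set())
            layers = []
            for l in c.layers:
                sub = l.graph.subgraph(n for n in l.graph.nodes if n in nodes).copy()
                layers.append(Layer(l.layer_id, sub))
            comps.append(
                MultiplexComponent(
                    c.component_id, layers, tau=np.array(c.tau), interlayer_weight=c.interlayer_weight
                )
            )
        bip = {}
        for (ca, cb), edges in self.bipartite_edges.items():
            ka, kb = keep.get(ca, set()), keep.get(cb, set())
            kept = [(u, v, w) for u, v, w in edges if u in ka and v in kb]
            if kept:
                bip[(ca, cb)] = kept
        return MultiplexHeterogeneousGraph(
            comps,
            bipartite_edges=bip,
            eta=np.array(self.eta),
            lambda_switch=self.lambda_switch,
            delta_jump=self.delta_jump,
        )

    @property
    def n_replicas(self) -> int:
        return sum(l.n_nodes for c in self.components for l in c.layers)


class GlobalIndex:
    """Bijection (component_id, layer_id, node_id) <-> integer in [0, N).

    Ordering is deterministic: components in graph order, layers in
    component order, node ids lexicographic within a layer.
    """

    def __init__(self, g: MultiplexHeterogeneousGraph):
        self.triples: list[tuple[str, str, str]] = []
        self._lookup: dict[tuple[str, str, str], int] = {}
        self.layer_slices: dict[tuple[str, str], slice] = {}
        pos = 0
        for c in g.components:
            for l in c.layers:
                nodes = l.node_ids
                for v in nodes:
                    t = (c.component_id, l.layer_id, v)
                    self._lookup[t] = len(self.triples)
                    self.triples.append(t)
                self.layer_slices[(c.component_id, l.layer_id)] = slice(pos, pos + len(nodes))
                pos += len(nodes)
        self.n = pos

    def index(self, component_id: str, layer_id: str, node_id: str) -> int:
        return self._lookup[(component_id, layer_id, node_id)]

    def triple(self, i: int) -> tuple[str, str, str]:
        return self.triples[i]

    def __len__(self) -> int:
        return self.n

    def __contains__(self, triple: tuple[str, str, str]) -> bool:
        return triple in self._lookup

    def replicas_of(self, component_id: str, node_id: str) -> list[int]:
        """Global indices of every layer replica of a node within a component."""
        out = []
        for (cid, lid), sl in self.layer_slices.items():
            if cid == component_id:
                t = (cid, lid, node_id)
                if t in self._lookup:
                    out.append(self._lookup[t])
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.triples, columns=["component", "layer", "node_id"])


def build_index(g: MultiplexHeterogeneousGraph) -> GlobalIndex:
    """Construct the deterministic global replica index for ``g``."""
    return GlobalIndex(g)


# ---------------------------------------------------------------------------
# file IO


def read_edge_list(path: str) -> list[tuple[str, str, float]]:
    """Read a TSV edge list (``source  target  weight``, header optional;
    missing weight column defaults to 1.0)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    # tolerate a header row
    first = [str(x).lower() for x in df.iloc[0].tolist()]
    if first[0] in ("source", "from", "node1") or first[:2] == ["source", "target"]:
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise GraphConfigError(f"{path}: edge list needs at least 2 columns")
    edges = []
    for row in df.itertuples(index=False):
        u, v = str(row[0]), str(row[1])
        w = 1.0
        if len(row) > 2 and row[2] is not None and str(row[2]) not in ("", "nan"):
            w = float(row[2])
        edges.append((u, v, w))
    return edges


def read_layer_file(path: str, layer_id: str, nodes_path: str | None = None) -> Layer:
    """Read one layer; ``nodes_path`` optionally lists node ids (one per
    line) so isolated nodes survive the edge-list format."""
    extra: list[str] = []
    if nodes_path:
        with open(nodes_path) as fh:
            extra = [line.strip() for line in fh if line.strip()]
    if path.endswith(".graphml"):
        g = nx.read_graphml(path)
        edges = [(str(u), str(v), float(d.get("weight", 1.0))) for u, v, d in g.edges(data=True)]
        return Layer.from_edges(layer_id, edges, nodes=[str(n) for n in g.nodes] + extra)
    return Layer.from_edges(layer_id, read_edge_list(path), nodes=extra)


def read_seed_table(path: str) -> dict[str, float]:
    """Read a TSV ``node_id  value`` table of non-negative seed values."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, header=None, comment="#")
    if str(df.iloc[0, 0]).lower() in ("node_id", "node", "id"):
        df = df.iloc[1:]
    out = {}
    for row in df.itertuples(index=False):
        val = float(row[1])
        if val < 0:
            raise GraphConfigError(f"{path}: negative seed value {val} for node {row[0]!r}")
        out[str(row[0])] = val
    return out


def read_graph(config_path: str) -> MultiplexHeterogeneousGraph:
    """Read a multiplex-heterogeneous graph from a YAML config.

    The config names components, their layers (edge-list TSV or GraphML
    files), bipartite files per component pair, and the eta/tau/lambda/delta
    parameters.  Omitted eta/tau default to uniform; omitted weights to 1.
    """
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(config_path))

    def _resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    comps = []
    for cspec in cfg.get("components", []):
        layers = []
        for lspec in cspec.get("layers", []):
            nodes_path = _resolve(lspec["nodes"]) if "nodes" in lspec else None
            layers.append(read_layer_file(_resolve(lspec["edges"]), lspec["id"], nodes_path))
        tau = np.asarray(cspec["tau"], dtype=float) if "tau" in cspec else None
        comps.append(
            MultiplexComponent(
                cspec["id"],
                layers,
                tau=tau,
                interlayer_weight=float(cspec.get("interlayer_weight", 1.0)),
            )
        )
    bip: dict[tuple[str, str], list[tuple[str, str, float]]] = {}
    for bspec in cfg.get("bipartite", []):
        ca, cb = bspec["between"]
        path = _resolve(bspec["edges"])
        try:
            bip[(ca, cb)] = read_edge_list(path)
        except GraphConfigError:
            raise
    eta = np.asarray(cfg["eta"], dtype=float) if "eta" in cfg else None
    try:
        return MultiplexHeterogeneousGraph(
            comps,
            bipartite_edges=bip,
            eta=eta,
            lambda_switch=float(cfg.get("lambda", 0.5)),
            delta_jump=float(cfg.get("delta", 0.5)),
        )
    except GraphConfigError as err:
        # attach bipartite file context where relevant
        for (ca, cb) in bip:
            pass
        raise err


def write_module(module, out_dir: str) -> dict[str, str]:
    """Write a finished module: GraphML, node/edge TSV tables, and a JSON run log.

    Node attributes carried into the GraphML: component, layers the node
    appeared in, seed value, and aggregated diffusion score.
    """
    os.makedirs(out_dir, exist_ok=True)
    g = nx.Graph()
    rows = []
    for node in module.nodes:
        cid, nid = node
        attrs = module.node_attrs.get(node, {})
        g.add_node(
            f"{cid}::{nid}",
            component=cid,
            node_id=nid,
            layers=",".join(attrs.get("layers", [])),
            seed_value=float(attrs.get("seed_value", 0.0)),
            score=float(attrs.get("score", 0.0)),
        )
        rows.append(
            {
                "component": cid,
                "node_id": nid,
                "layers": ",".join(attrs.get("layers", [])),
                "seed_value": attrs.get("seed_value", 0.0),
                "score": attrs.get("score", 0.0),
            }
        )
    erows = []
    for (a, b), w in module.edges.items():
        g.add_edge(f"{a[0]}::{a[1]}", f"{b[0]}::{b[1]}", weight=float(w))
        erows.append(
            {
                "source_component": a[0],
                "source": a[1],
                "target_component": b[0],
                "target": b[1],
                "weight": w,
            }
        )
    paths = {
        "graphml": os.path.join(out_dir, "module.graphml"),
        "nodes": os.path.join(out_dir, "module_nodes.tsv"),
        "edges": os.path.join(out_dir, "module_edges.tsv"),
        "log": os.path.join(out_dir, "run_log.json"),
    }
    nx.write_graphml(g, paths["graphml"])
    pd.DataFrame(
        rows, columns=["component", "node_id", "layers", "seed_value", "score"]
    ).to_csv(paths["nodes"], sep="\t", index=False)
    pd.DataFrame(
        erows,
        columns=["source_component", "source", "target_component", "target", "weight"],
    ).to_csv(paths["edges"], sep="\t", index=False)
    with open(paths["log"], "w") as fh:
        json.dump(module.run_log(), fh, indent=2)
    return paths
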