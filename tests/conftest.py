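import networkx as nx
import numpy as np
import pytest

from amend.graph_model import Layer, MultiplexComponent, MultiplexHeterogeneousGraph
from amend.synthetic import monoplex


def path_graph(n: int) -> nx.Graph:
    g = nx.path_graph([f"n{i}" for i in range(n)])
    nx.set_edge_attributes(g, 1.0, "weight")
    return g


@pytest.fixture
def path3() -> MultiplexHeterogeneousGraph:
    return monoplex(path_graph(3))


@pytest.fixture
def two_component_graph() -> MultiplexHeterogeneousGraph:
    """Deterministic multiplex-heterogeneous fixture: component c1 with two
    partially overlapping layers, monoplex component c2, bipartite coupling."""
    l1 = Layer.from_edges("l1", [("a", "b", 1.0), ("b", "c", 2.0), ("c", "d", 1.0)])
    l2 = Layer.from_edges("l2", [("b", "c", 1.0), ("c", "e", 1.0)])
    c1 = MultiplexComponent("c1", [l1, l2])
    m1 = Layer.from_edges("l1", [("x", "y", 1.0), ("y", "z", 1.0)])
    c2 = MultiplexComponent("c2", [m1])
    return MultiplexHeterogeneousGraph(
        [c1, c2],
        bipartite_edges={("c1", "c2"): [("b", "x", 1.0), ("d", "z", 2.0)]},
        lambda_switch=0.4,
        delta_jump=0.3,
    )


def random_weighted_graph(n: int, p: float, rng: np.random.Generator) -> nx.Graph:
    """Connected random weighted graph (ER plus a random spanning path)."""
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
    order = list(rng.permutation(n))
    for a, b in zip(order, order[1:]):
        g.add_edge(a, b)
    for _u, _v, d in g.edges(data=True):
        d["weight"] = float(rng.uniform(0.2, 2.0))
    return g


def mwcs_exact(graph: nx.Graph, w: dict) -> tuple[float, set]:
    """Exhaustive maximum-weight connected subgraph for graphs with <= ~16
    nodes: enumerate every vertex subset, keep connected ones (bitmask
    BFS), maximize total weight.  Independent brute-force oracle."""
    nodes = list(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    nbr = [0] * n
    for u, v in graph.edges:
        nbr[idx[u]] |= 1 << idx[v]
        nbr[idx[v]] |= 1 << idx[u]
    weights = [float(w[v]) for v in nodes]
    best, best_mask = -np.inf, 0
    for mask in range(1, 1 << n):
        lowest = mask & -mask
        seen = lowest
        frontier = lowest
        while frontier:
            nxt = 0
            m = frontier
            while m:
                b = m & -m
                nxt |= nbr[b.bit_length() - 1]
                m ^= b
            nxt &= mask & ~seen
            seen |= nxt
            frontier = nxt
        if seen != mask:
            continue
        total = 0.0
        m = mask
        while m:
            b = m & -m
            total += weights[b.bit_length() - 1]
            m ^= b
        if total > best:
            best, best_mask = total, mask
    chosen = {nodes[i] for i in range(n) if best_mask >> i & 1}
    return best, chosen
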