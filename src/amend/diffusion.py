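"""Seed-vector construction, RWR fixed-point iteration, and stationary
distributions.

The seed vector ``p0`` is assembled hierarchically: each layer's raw
non-negative values are normalized to sum 1, scaled by the layer weight
``tau`` within its component, then by the component weight ``eta``; both
weight vectors live on probability simplices, so ``p0`` is stochastic.
Diffusion iterates ``p <- (1 - r) M p + r p0`` to a fixed point; the
restart probability ``r`` controls how far seed mass smooths into the
network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graph_model import GlobalIndex, GraphConfigError, MultiplexHeterogeneousGraph, build_index
from .transition import BiasVector, TransitionMatrix

__all__ = [
    "SeedVector",
    "DiffusionResult",
    "build_seed_vector",
    "rwr",
    "stationary_distribution",
    "stationary_from_adjacency",
    "brw_attribute_from_noi",
    "build_replica_graph",
    "scores_frame",
]


class ConvergenceError(RuntimeError):
    """RWR failed to reach tolerance within the iteration budget."""

    def __init__(self, msg: str, residual_trace: list[float]):
        super().__init__(msg)
        self.residual_trace = residual_trace


@dataclass
class SeedVector:
    """Global stochastic prior over replicas plus its per-layer provenance."""

    p0: np.ndarray
    index: GlobalIndex
    layer_weights: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.p0.sum() - 1.0) > 1e-9:
            raise ValueError(f"seed vector must be stochastic, sums to {self.p0.sum()}")


@dataclass
class DiffusionResult:
    p: np.ndarray
    r: float
    iterations: int
    residual_trace: list[float]
    converged: bool = True


def build_seed_vector(
    g: MultiplexHeterogeneousGraph,
    values: Mapping,
    tau: Mapping[str, np.ndarray] | None = None,
    eta: np.ndarray | None = None,
    index: GlobalIndex | None = None,
) -> SeedVector:
    """Assemble the global seed vector from per-layer value maps.

    ``values`` maps either ``(component_id, layer_id)`` or ``component_id``
    (broadcast to all its layers) to ``{node_id: value >= 0}``.  Nodes
    absent from a value map get seed 0 — molecules not captured in an
    assay contribute no prior mass.  A layer whose value map is all zero
    contributes a zero block; its tau weight is redistributed
    proportionally among the component's other layers, and likewise eta
    across components if an entire component is zero.
    """
    index = index or build_index(g)
    eta_vec = np.array(eta if eta is not None else g.eta, dtype=float)
    if abs(eta_vec.sum() - 1.0) > 1e-8 or np.any(eta_vec < 0):
        raise GraphConfigError(f"eta must lie on the simplex, got {eta_vec.tolist()}")

    # resolve raw per-layer vectors and sums
    layer_vecs: dict[tuple[str, str], np.ndarray] = {}
    for c in g.components:
        for l in c.layers:
            key = (c.component_id, l.layer_id)
            vmap = values.get(key, values.get(c.component_id, {}))
            u = np.array([float(vmap.get(v, 0.0)) for v in l.node_ids])
            if np.any(u < 0):
                raise GraphConfigError(
                    f"negative seed value in layer {l.layer_id!r} of component "
                    f"{c.component_id!r}"
                )
            layer_vecs[key] = u

    p0 = np.zeros(index.n)
    comp_mass = np.zeros(len(g.components))
    layer_weights: dict[tuple[str, str], float] = {}
    for ci, c in enumerate(g.components):
        t = np.array(
            tau[c.component_id] if tau is not None and c.component_id in tau else c.tau,
            dtype=float,
        )
        if abs(t.sum() - 1.0) > 1e-8 or np.any(t < 0):
            raise GraphConfigError(
                f"tau for component {c.component_id!r} must lie on the simplex, got {t.tolist()}"
            )
        sums = np.array([layer_vecs[(c.component_id, l.layer_id)].sum() for l in c.layers])
        live = sums > 0
        if live.any():
            t_eff = np.where(live, t, 0.0)
            if t_eff.sum() == 0:  # all mass was on dead layers: uniform over live
                t_eff = live.astype(float)
            t_eff = t_eff / t_eff.sum()
            comp_mass[ci] = 1.0
        else:
            t_eff = np.zeros_like(t)
        for li, l in enumerate(c.layers):
            key = (c.component_id, l.layer_id)
            layer_weights[key] = float(t_eff[li])
            if t_eff[li] > 0:
                sl = index.layer_slices[key]
                p0[sl] = layer_vecs[key] / sums[li] * t_eff[li]

    live_c = comp_mass > 0
    if not live_c.any():
        raise GraphConfigError("all seed values are zero; cannot form a seed vector")
    eta_eff = np.where(live_c, eta_vec, 0.0)
    if eta_eff.sum() == 0:
        eta_eff = live_c.astype(float)
    eta_eff = eta_eff / eta_eff.sum()
    for ci, c in enumerate(g.components):
        for l in c.layers:
            sl = index.layer_slices[(c.component_id, l.layer_id)]
            p0[sl] *= eta_eff[ci]
            layer_weights[(c.component_id, l.layer_id)] *= float(eta_eff[ci])
    return SeedVector(p0=p0, index=index, layer_weights=layer_weights)


def rwr(
    tm: TransitionMatrix | sp.spmatrix,
    p0: SeedVector | np.ndarray,
    r: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> DiffusionResult:
    """Random walk with restart: iterate ``p <- (1-r) M p + r p0`` to an L1
    fixed point.

    Mass that falls into dangling (all-zero) columns is rerouted to the
    restart distribution each step, so ``sum(p) == 1`` is conserved
    exactly.  Raises :class:`ConvergenceError` (with the residual trace)
    if ``tol`` is not reached within ``max_iter``.
    """
    if not 0.0 < r < 1.0:
        raise ValueError(f"restart probability must lie in (0, 1), got {r}")
    M = tm.M if isinstance(tm, TransitionMatrix) else sp.csc_matrix(tm)
    v0 = p0.p0 if isinstance(p0, SeedVector) else np.asarray(p0, dtype=float)
    if abs(v0.sum() - 1.0) > 1e-8:
        raise ValueError("p0 must be stochastic")
    p = v0.copy()
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        q = M @ p
        lost = 1.0 - q.sum()  # mass swallowed by dangling columns
        p_next = (1.0 - r) * q + (r + (1.0 - r) * lost) * v0
        resid = float(np.abs(p_next - p).sum())
        trace.append(resid)
        p = p_next
        if resid < tol:
            return DiffusionResult(p=p, r=r, iterations=it, residual_trace=trace)
    raise ConvergenceError(
        f"RWR did not converge in {max_iter} iterations (last residual {trace[-1]:.3e})",
        trace,
    )


def stationary_from_adjacency(A: sp.spmatrix) -> np.ndarray:
    """Closed-form stationary distribution of the degree-normalized walk on
    a symmetric adjacency: ``s_j = sum_i a_ij / sum_ik a_ik`` — i.e.
    proportional to (weighted) degree."""
    A = sp.csc_matrix(A)
    s = np.asarray(A.sum(axis=0)).ravel()
    total = s.sum()
    if total == 0:
        raise ValueError("empty adjacency has no stationary distribution")
    return s / total


def stationary_distribution(
    M: TransitionMatrix | sp.spmatrix,
    tol: float = 1e-12,
    max_iter: int = 10000,
) -> np.ndarray:
    """Principal eigenvector of a column-stochastic matrix, normalized to
    sum 1.

    Uses lazy power iteration (``s <- (M s + s) / 2``), which shares fixed
    points with ``M`` but is aperiodic, so bipartite chains converge too.
    When the spectral gap is tiny and the iteration stalls (e.g. on
    near-bistochastic matrices), the principal eigenvector is computed
    with an Arnoldi/dense eigensolver instead; reducible chains for which
    neither route yields a valid fixed point fall back to damped iteration
    (damping 0.999) with a warning.
    """
    M = M.M if isinstance(M, TransitionMatrix) else sp.csc_matrix(M)
    n = M.shape[0]
    s = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        s_next = 0.5 * (M @ s + s)
        tot = s_next.sum()
        if tot > 0:
            s_next = s_next / tot
        if np.abs(s_next - s).sum() < tol:
            return s_next
        s = s_next
    v = _principal_eigenvector(M)
    if v is not None:
        return v
    warnings.warn(
        "power iteration did not converge (reducible chain?); retrying with damping 0.999"
    )
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        s_next = 0.999 * (M @ s) + 0.001 * u
        s_next = s_next / s_next.sum()
        if np.abs(s_next - s).sum() < tol:
            break
        s = s_next
    return s


def _principal_eigenvector(M: sp.csc_matrix) -> np.ndarray | None:
    """Eigenvector of eigenvalue 1, or None if no valid fixed point found."""
    n = M.shape[0]
    try:
        if n <= 300:
            vals, vecs = np.linalg.eig(M.toarray())
            k = int(np.argmin(np.abs(vals - 1.0)))
            v = np.abs(np.real(vecs[:, k]))
        else:
            vals, vecs = sp.linalg.eigs(M.astype(float), k=1, which="LM", maxiter=10000)
            v = np.abs(np.real(vecs[:, 0]))
        if v.sum() <= 0:
            return None
        v = v / v.sum()
        if np.abs(M @ v - v).sum() < 1e-8:
            return v
    except Exception:
        pass
    return None


def build_replica_graph(
    g: MultiplexHeterogeneousGraph, index: GlobalIndex | None = None
) -> nx.Graph:
    """The full heterogeneous graph at replica resolution with every edge
    class (intra-layer, inter-layer coupling, bipartite) as an unweighted
    edge; used for distance computations."""
    index = index or build_index(g)
    G = nx.Graph()
    G.add_nodes_from(range(index.n))
    for c in g.components:
        for l in c.layers:
            for u, v in l.graph.edges:
                G.add_edge(
                    index.index(c.component_id, l.layer_id, u),
                    index.index(c.component_id, l.layer_id, v),
                )
        for a in range(len(c.layers)):
            for b in range(a + 1, len(c.layers)):
                la, lb = c.layers[a], c.layers[b]
                for v in set(la.graph.nodes) & set(lb.graph.nodes):
                    G.add_edge(
                        index.index(c.component_id, la.layer_id, v),
                        index.index(c.component_id, lb.layer_id, v),
                    )
    for (ca, cb), edges in g.bipartite_edges.items():
        for u, v, _w in edges:
            for iu in index.replicas_of(ca, u):
                for iv in index.replicas_of(cb, v):
                    G.add_edge(iu, iv)
    return G


def brw_attribute_from_noi(
    g: MultiplexHeterogeneousGraph,
    noi: Mapping[str, set[str]] | set[str],
    k_scale: float,
    index: GlobalIndex | None = None,
) -> BiasVector:
    """Distance-decay bias attribute ``mu_i = exp(-k_scale * d_i)`` where
    ``d_i`` is the mean unweighted shortest-path distance from replica i to
    the nodes of interest, measured on the full heterogeneous graph.

    ``noi`` is either a set of node ids (matched in every component) or a
    mapping ``component_id -> set of node ids``.  Unreachable replica–NOI
    pairs contribute the largest observed finite distance plus one.
    """
    if k_scale < 0:
        raise ValueError("k_scale must be non-negative")
    index = index or build_index(g)
    if not isinstance(noi, Mapping):
        noi = {c.component_id: set(noi) for c in g.components}
    targets: list[list[int]] = []
    for cid, nodes in noi.items():
        for v in nodes:
            reps = index.replicas_of(cid, v)
            if reps:
                targets.append(reps)
    if not targets:
        raise GraphConfigError("no node of interest is present in the graph")
    G = build_replica_graph(g, index)
    dist = np.full((len(targets), index.n), np.inf)
    for t, reps in enumerate(targets):
        lengths = nx.multi_source_dijkstra_path_length(G, set(reps))
        for i, d in lengths.items():
            dist[t, i] = d
    finite = dist[np.isfinite(dist)]
    fill = (finite.max() + 1.0) if finite.size else 1.0
    dist[~np.isfinite(dist)] = fill
    d_mean = dist.mean(axis=0)
    return BiasVector(mu=np.exp(-k_scale * d_mean))


def scores_frame(index: GlobalIndex, p: np.ndarray) -> pd.DataFrame:
    """Per-replica scores as a ``component / layer / node_id / score`` table."""
    df = index.to_frame()
    df["score"] = np.asarray(p, dtype=float)
    return df
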