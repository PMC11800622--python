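"""Global transition-matrix construction for multiplex-heterogeneous RWR.

The walk's state space is the set of node *replicas* (one per layer a node
appears in).  The transition matrix is left-stochastic: ``m[i, j]`` is the
probability of stepping from replica ``j`` to replica ``i``.  Construction
proceeds in two stages:

1. every adjacency block — intra-layer, inter-layer (replica couplings
   within a multiplex), and inter-component (bipartite) — is column-
   normalized *independently*, optionally after degree-penalized and/or
   biased reweighting of rows;
2. crosstalk parameters mix the normalized blocks so that a source column
   distributes mass (1-delta)(1-lambda) to intra-layer targets,
   (1-delta)*lambda to inter-layer targets, and delta to inter-component
   targets, with proportional redistribution when a target class is absent.

Normalizing blocks before mixing makes each class's column mass an affine
function of its crosstalk parameter, unlike parameterizations that
normalize the mixed adjacency as a whole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import scipy.sparse as sp

from .graph_model import GlobalIndex, GraphConfigError, MultiplexHeterogeneousGraph, build_index

__all__ = [
    "BiasVector",
    "TransitionOptions",
    "TransitionMatrix",
    "column_normalize",
    "penalized_normalize",
    "apply_bias",
    "assemble_transition",
]

STOCHASTIC_TOL = 1e-12


def _colsums(A: sp.spmatrix) -> np.ndarray:
    return np.asarray(A.sum(axis=0)).ravel()


def column_normalize(A: sp.spmatrix) -> sp.csc_matrix:
    """Divide each column by its sum (``M = A D^-1``).

    Zero columns are left zero; callers detect them via a zero column sum
    (the dangling rule is applied by the diffusion engine).
    """
    A = sp.csc_matrix(A, dtype=float)
    if A.nnz and A.data.min() < 0:
        raise ValueError("adjacency must be non-negative")
    s = _colsums(A)
    inv = np.divide(1.0, s, out=np.zeros_like(s), where=s > 0)
    return (A @ sp.diags(inv)).tocsc()


def penalized_normalize(A: sp.spmatrix, k_pen: float) -> sp.csc_matrix:
    """Degree-penalized normalization: scale row i by ``d_i**-k_pen``, then
    column-normalize, so entry (i, j) is
    ``d_i**-k * a_ij / sum_l d_l**-k * a_lj``.

    ``k_pen = 0`` reduces to plain degree normalization; larger values
    penalize transitions into high-degree nodes.
    """
    if k_pen < 0:
        raise ValueError(f"penalization factor must be >= 0, got {k_pen}")
    A = sp.csc_matrix(A, dtype=float)
    d = _colsums(A)  # symmetric adjacency: column sums equal degrees
    scale = np.divide(1.0, np.power(d, k_pen), out=np.ones_like(d), where=d > 0)
    return column_normalize(sp.diags(scale) @ A)


def apply_bias(A: sp.spmatrix, mu: np.ndarray) -> sp.csc_matrix:
    """Left-multiply by diag(mu): row i of the adjacency is scaled by mu_i,
    so after column normalization ``m_ij = mu_i a_ij / sum_l mu_l a_lj``.

    Columns whose entire biased neighborhood would vanish (all-zero mu over
    the neighbors) fall back to the unbiased adjacency for that column,
    with a warning: negative evidence must not create sinks.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("bias attribute mu must be non-negative")
    A = sp.csc_matrix(A, dtype=float)
    B = (sp.diags(mu) @ A).tocsc()
    before, after = _colsums(A), _colsums(B)
    dead = (before > 0) & (after == 0)
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} column(s) had an all-zero biased neighborhood; "
            "falling back to unbiased transition rates there"
        )
        B = sp.lil_matrix(B)
        A_lil = sp.lil_matrix(A)
        for j in np.flatnonzero(dead):
            B[:, j] = A_lil[:, j]
        B = B.tocsc()
    return B


@dataclass
class BiasVector:
    """Per-replica biased-random-walk attribute mu (>= 0, default 1)."""

    mu: np.ndarray

    @classmethod
    def ones(cls, n: int) -> "BiasVector":
        return cls(np.ones(n))

    @classmethod
    def from_node_values(
        cls, index: GlobalIndex, values: Mapping[str, float], default: float = 1.0
    ) -> "BiasVector":
        """Broadcast node-keyed values to every replica of that node."""
        mu = np.full(index.n, float(default))
        for i, (_c, _l, v) in enumerate(index.triples):
            if v in values:
                mu[i] = float(values[v])
        if np.any(mu < 0):
            raise ValueError("bias attribute mu must be non-negative")
        return cls(mu)


@dataclass
class TransitionOptions:
    """Knobs for transition assembly.

    ``normalization`` is ``"degree"`` or ``"penalized"`` (with ``k_pen``),
    applied to intra-layer blocks; per-layer overrides via
    ``normalization_overrides[(component_id, layer_id)] = (kind, k_pen)``.
    ``lambda_switch``/``delta_jump`` default to the graph's values.
    """

    lambda_switch: float | None = None
    delta_jump: float | None = None
    normalization: str = "degree"
    k_pen: float = 0.5
    normalization_overrides: dict[tuple[str, str], tuple[str, float]] = field(
        default_factory=dict
    )
    bias: BiasVector | None = None


@dataclass
class TransitionMatrix:
    """Assembled left-stochastic matrix plus the normalized class blocks.

    Keeping the per-class blocks (already column-normalized, global shape)
    allows scoped degree-bias adjustment to rewrite a block and re-mix
    without rebuilding from the graph.
    """

    M: sp.csc_matrix
    index: GlobalIndex
    intra: sp.csc_matrix
    inter: sp.csc_matrix
    pairs: dict[tuple[str, str], sp.csc_matrix]
    lambda_switch: float
    delta_jump: float
    dangling: np.ndarray  # bool per column: no targets of any class
    params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.index.n

    def column_class_mass(self, j: int) -> dict[str, float]:
        """Total column-j mass per target class of the mixed matrix."""
        col = self.M[:, [j]].toarray().ravel()
        intra_rows = self.intra[:, [j]].toarray().ravel() > 0
        inter_rows = self.inter[:, [j]].toarray().ravel() > 0
        pair_rows = np.zeros(self.n, dtype=bool)
        for P in self.pairs.values():
            pair_rows |= P[:, [j]].toarray().ravel() > 0
        return {
            "intra": float(col[intra_rows].sum()),
            "inter_layer": float(col[inter_rows].sum()),
            "inter_component": float(col[pair_rows].sum()),
        }

    def remix(self) -> None:
        """Recompute ``M`` from the stored class blocks (used after scoped
        degree-bias adjustment rewrote a block)."""
        self.M, self.dangling = _mix(
            self.intra, self.inter, self.pairs, self.lambda_switch, self.delta_jump
        )


def _layer_adjacency(layer, order: list[str]) -> sp.csc_matrix:
    import networkx as nx

    if not order:
        return sp.csc_matrix((0, 0))
    A = nx.to_scipy_sparse_array(layer.graph, nodelist=order, weight="weight", format="csc")
    return sp.csc_matrix(A, dtype=float)


def _build_blocks(
    g: MultiplexHeterogeneousGraph, index: GlobalIndex, opts: TransitionOptions
) -> tuple[sp.csc_matrix, sp.csc_matrix, dict[tuple[str, str], sp.csc_matrix]]:
    """Per-class adjacency blocks at global shape, each column-normalized
    independently after penalization/bias reweighting."""
    N = index.n
    mu = opts.bias.mu if opts.bias is not None else None
    if mu is not None and len(mu) != N:
        raise ValueError(f"bias vector length {len(mu)} != replica count {N}")

    # --- intra-layer: block-diagonal over layers, each normalized on its own
    intra_parts = []
    for c in g.components:
        for l in c.layers:
            sl = index.layer_slices[(c.component_id, l.layer_id)]
            A = _layer_adjacency(l, l.node_ids)
            kind, k = opts.normalization, opts.k_pen
            if (c.component_id, l.layer_id) in opts.normalization_overrides:
                kind, k = opts.normalization_overrides[(c.component_id, l.layer_id)]
            if kind == "penalized":
                d = _colsums(A)
                scale = np.divide(1.0, np.power(d, k), out=np.ones_like(d), where=d > 0)
                A = sp.csc_matrix(sp.diags(scale) @ A)
            elif kind != "degree":
                raise GraphConfigError(f"unknown normalization kind {kind!r}")
            if mu is not None:
                A = apply_bias(A, mu[sl])
            intra_parts.append(column_normalize(A))
    intra = sp.block_diag(intra_parts, format="csc") if intra_parts else sp.csc_matrix((N, N))
    intra.resize((N, N))

    # --- inter-layer: couple replicas of shared node ids within a multiplex
    rows, cols, vals = [], [], []
    for c in g.components:
        if len(c.layers) < 2:
            continue
        w = float(c.interlayer_weight)
        for a in range(len(c.layers)):
            for b in range(len(c.layers)):
                if a == b:
                    continue
                la, lb = c.layers[a], c.layers[b]
                shared = set(la.graph.nodes) & set(lb.graph.nodes)
                for v in shared:
                    rows.append(index.index(c.component_id, la.layer_id, v))
                    cols.append(index.index(c.component_id, lb.layer_id, v))
                    vals.append(w)
    inter_adj = sp.csc_matrix((vals, (rows, cols)), shape=(N, N))
    if mu is not None and inter_adj.nnz:
        inter_adj = apply_bias(inter_adj, mu)
    inter = column_normalize(inter_adj)

    # --- inter-component: one block per unordered pair, both directions,
    # each direction column-normalized on its own
    pairs: dict[tuple[str, str], sp.csc_matrix] = {}
    for (ca, cb), edges in g.bipartite_edges.items():
        for src, dst in ((ca, cb), (cb, ca)):
            rows, cols, vals = [], [], []
            for u, v, w in edges:
                un, vn = (u, v) if src == ca else (v, u)
                # connect every replica of the source node to every replica
                # of the target node
                for jc in _replica_indices(index, src, un):
                    for ir in _replica_indices(index, dst, vn):
                        rows.append(ir)
                        cols.append(jc)
                        vals.append(float(w))
            B = sp.csc_matrix((vals, (rows, cols)), shape=(N, N))
            if mu is not None and B.nnz:
                B = apply_bias(B, mu)
            key = (src, dst)
            if key in pairs:
                pairs[key] = sp.csc_matrix(pairs[key] + B)
            else:
                pairs[key] = B
    pairs = {k: column_normalize(v) for k, v in pairs.items()}
    return intra, inter, pairs


def _replica_indices(index: GlobalIndex, component_id: str, node_id: str) -> list[int]:
    return index.replicas_of(component_id, node_id)


def _mix(
    intra: sp.csc_matrix,
    inter: sp.csc_matrix,
    pairs: dict[tuple[str, str], sp.csc_matrix],
    lam: float,
    delta: float,
) -> tuple[sp.csc_matrix, np.ndarray]:
    """Crosstalk mixing of normalized class blocks with redistribution.

    Nominal per-column masses: intra (1-d)(1-l), inter-layer (1-d)l,
    inter-component d (split equally among partner components with targets).
    Masses of absent classes are redistributed proportionally to the
    remaining present classes; a lone class gets mass 1.  Columns with no
    targets at all are dangling (all-zero).
    """
    N = intra.shape[0]
    has_intra = _colsums(intra) > 0
    has_inter = _colsums(inter) > 0
    pair_presence = {k: _colsums(P) > 0 for k, P in pairs.items()}
    n_partners = np.zeros(N)
    for pres in pair_presence.values():
        n_partners += pres
    has_pair = n_partners > 0

    nominal = np.vstack(
        [
            np.where(has_intra, (1 - delta) * (1 - lam), 0.0),
            np.where(has_inter, (1 - delta) * lam, 0.0),
            np.where(has_pair, delta, 0.0),
        ]
    )
    present = np.vstack([has_intra, has_inter, has_pair])
    tot = nominal.sum(axis=0)
    n_present = present.sum(axis=0)
    masses = np.zeros_like(nominal)
    ok = tot > 0
    masses[:, ok] = nominal[:, ok] / tot[ok]
    # all nominal masses zero but classes exist (e.g. lam=1 with no
    # inter-layer targets): split uniformly over present classes
    degen = (~ok) & (n_present > 0)
    if degen.any():
        masses[:, degen] = present[:, degen] / n_present[degen]

    M = intra @ sp.diags(masses[0]) + inter @ sp.diags(masses[1])
    if pairs:
        per_partner = np.divide(
            masses[2], n_partners, out=np.zeros(N), where=n_partners > 0
        )
        for k, P in pairs.items():
            M = M + P @ sp.diags(np.where(pair_presence[k], per_partner, 0.0))
    dangling = n_present == 0
    return sp.csc_matrix(M), dangling


def assemble_transition(
    g: MultiplexHeterogeneousGraph,
    opts: TransitionOptions | None = None,
    index: GlobalIndex | None = None,
) -> TransitionMatrix:
    """Build the global left-stochastic transition matrix for ``g``.

    Every non-dangling column of the result sums to 1 (to 1e-12); dangling
    columns are all-zero and flagged for the diffusion engine's
    restart-on-dangling rule.
    """
    opts = opts or TransitionOptions()
    index = index or build_index(g)
    lam = g.lambda_switch if opts.lambda_switch is None else opts.lambda_switch
    delta = g.delta_jump if opts.delta_jump is None else opts.delta_jump
    for name, p in (("lambda", lam), ("delta", delta)):
        if not 0.0 <= p <= 1.0:
            raise GraphConfigError(f"{name} must lie in [0, 1], got {p}")
    intra, inter, pairs = _build_blocks(g, index, opts)
    M, dangling = _mix(intra, inter, pairs, lam, delta)
    return TransitionMatrix(
        M=M,
        index=index,
        intra=intra,
        inter=inter,
        pairs=pairs,
        lambda_switch=lam,
        delta_jump=delta,
        dangling=dangling,
        params={
            "normalization": opts.normalization,
            "k_pen": opts.k_pen,
            "biased": opts.bias is not None,
        },
    )


def export_matrix(tm: TransitionMatrix, prefix: str) -> None:
    """Debug export: Matrix Market file plus an index TSV."""
    import scipy.io

    scipy.io.mmwrite(prefix + ".mtx", tm.M)
    tm.index.to_frame().to_csv(prefix + "_index.tsv", sep="\t", index=True, index_label="i")
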