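"""Degree-bias adjustment: SDS, bistochastic scaling, inflation-normalization.

All three treat the stationary distribution of the transition matrix as a
proxy for how much node degree drives diffusion scores.  SDS rescales
scores after diffusion; BS and IN rewrite the transition matrix before
diffusion so that the entropy of its stationary distribution increases,
squeezing degree influence toward a common level.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .diffusion import stationary_distribution
from .transition import TransitionMatrix, column_normalize

__all__ = [
    "AdjustmentSpec",
    "sds_adjust",
    "bistochastic_scale",
    "inflate_normalize",
    "apply_adjustment",
    "stationary_entropy",
]


@dataclass
class AdjustmentSpec:
    """Which adjustment to run and where.

    scope is "all" (whole matrix) or a set of (component_id, layer_id)
    blocks; scoped BS/IN rewrite those intra-layer blocks and re-run the
    crosstalk mixing so global column stochasticity is preserved by
    construction.
    """

    method: str = "none"  # none | sds | bs | in
    scope: str | set[tuple[str, str]] = "all"
    ipf_tol: float = 1e-6
    ipf_max_iter: int = 1000
    gamma: float = 1.0
    rounds: int = 1

    def __post_init__(self) -> None:
        if self.method not in ("none", "sds", "bs", "in"):
            raise ValueError(f"unknown degree-bias method {self.method!r}")


def stationary_entropy(M: sp.spmatrix | TransitionMatrix) -> float:
    """Shannon entropy (nats) of the stationary distribution of ``M``."""
    s = stationary_distribution(M)
    s = s[s > 0]
    return float(-(s * np.log(s)).sum())


def sds_adjust(p: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Stationary-distribution scaling: ``p'_i = p_i / s_i``.

    Nodes with ``s_i = 0`` get NaN (excluded from rank-based use) with a
    warning.  The result is not renormalized — only ranks are meaningful.
    """
    p = np.asarray(p, dtype=float)
    s = np.asarray(s, dtype=float)
    out = np.divide(p, s, out=np.full_like(p, np.nan), where=s > 0)
    if np.any((s <= 0) & (p > 0)):
        warnings.warn("scores with zero stationary probability are undefined under SDS")
    return out


def _ipf(
    M: sp.csc_matrix, tol: float, max_iter: int, stall_tol: float = 5e-3
) -> tuple[sp.csc_matrix, float]:
    """Iterative proportional fitting toward a bistochastic matrix.

    Alternates row and column rescalings.  Matrices without total support
    (ubiquitous for interaction networks: any hub with two degree-1
    neighbors breaks it) cannot reach exact bistochasticity, and pushing
    IPF onward concentrates mass on a matching-like pattern, which
    *collapses* stationary entropy — the opposite of the adjustment's
    goal.  We therefore stop early once the per-sweep relative improvement
    of the worst row/column deviation falls below ``stall_tol``, returning
    an approximately bistochastic matrix near the entropy peak.
    """
    M = sp.csr_matrix(M, dtype=float, copy=True)
    dev = np.inf
    prev = np.inf
    for sweep in range(max_iter):
        rs = np.asarray(M.sum(axis=1)).ravel()
        rinv = np.divide(1.0, rs, out=np.ones_like(rs), where=rs > 0)
        M = sp.diags(rinv) @ M
        cs = np.asarray(M.sum(axis=0)).ravel()
        cinv = np.divide(1.0, cs, out=np.ones_like(cs), where=cs > 0)
        M = M @ sp.diags(cinv)
        rs = np.asarray(M.sum(axis=1)).ravel()
        cs = np.asarray(M.sum(axis=0)).ravel()
        dev = max(
            float(np.abs(rs[rs > 0] - 1).max(initial=0.0)),
            float(np.abs(cs[cs > 0] - 1).max(initial=0.0)),
        )
        if dev <= tol:
            break
        if sweep >= 10 and prev > 0 and (prev - dev) / prev < stall_tol:
            break
        prev = dev
    return sp.csc_matrix(M), dev


def bistochastic_scale(
    M: sp.spmatrix | TransitionMatrix,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> sp.csc_matrix | TransitionMatrix:
    """Scale a column-stochastic matrix toward unit row *and* column sums
    (IPF / Sinkhorn–Knopp), then renormalize columns exactly.

    A bistochastic matrix has the maximum-entropy (uniform) stationary
    distribution, so this adjustment homogenizes degree influence.  The
    stationary entropy of the output is checked against the input's and a
    warning is emitted if it decreased (possible on pathological inputs).
    """
    if isinstance(M, TransitionMatrix):
        out = copy.copy(M)
        out.M = bistochastic_scale(M.M, tol=tol, max_iter=max_iter)
        return out
    M = sp.csc_matrix(M)
    scaled, dev = _ipf(M, tol, max_iter)
    if dev > tol:
        warnings.warn(
            f"IPF stopped at deviation {dev:.2e} > tol {tol:.0e} "
            "(structural zeros prevent exact bistochasticity)"
        )
    out = column_normalize(scaled)
    if M.nnz:
        h_in, h_out = stationary_entropy(M), stationary_entropy(out)
        if h_out < h_in - 1e-9:
            warnings.warn(
                f"bistochastic scaling decreased stationary entropy "
                f"({h_in:.6f} -> {h_out:.6f})"
            )
    return out


def inflate_normalize(
    M: sp.spmatrix | TransitionMatrix,
    gamma: float = 1.0,
    rounds: int = 1,
) -> sp.csc_matrix | TransitionMatrix:
    """Inflation-normalization: raise each row entrywise to an exponent
    that grows with that row's stationary probability, then renormalize
    columns.

    The exponent is affine in the min–max-normalized stationary
    distribution, ``alpha_i = 1 + gamma * (s_i - min s) / (max s - min s)``
    — so alpha >= 1 everywhere, regular graphs (constant s) are fixed
    points, and incoming mass is displaced away from high-s rows.
    ``gamma = 0`` is the identity.
    """
    if gamma < 0:
        raise ValueError("inflation strength gamma must be >= 0")
    if isinstance(M, TransitionMatrix):
        out = copy.copy(M)
        out.M = inflate_normalize(M.M, gamma=gamma, rounds=rounds)
        return out
    M = sp.csc_matrix(M, dtype=float, copy=True)
    if gamma == 0 or M.nnz == 0:
        return M
    for _ in range(rounds):
        s = stationary_distribution(M)
        lo, hi = float(s.min()), float(s.max())
        if hi - lo <= 1e-15:
            break  # regular structure: alpha == 1 everywhere
        alpha = 1.0 + gamma * (s - lo) / (hi - lo)
        R = sp.csr_matrix(M)
        for i in range(R.shape[0]):
            a, b = R.indptr[i], R.indptr[i + 1]
            R.data[a:b] = R.data[a:b] ** alpha[i]
        M = column_normalize(R)
    return M


def apply_adjustment(tm: TransitionMatrix, spec: AdjustmentSpec) -> TransitionMatrix:
    """Apply a BS/IN adjustment to a transition matrix, globally or scoped.

    Global scope transforms the mixed matrix.  A scoped spec transforms
    only the named intra-layer blocks of the *pre-crosstalk* normalized
    block matrix, then re-runs the crosstalk mixing, which preserves the
    global stochasticity contract by construction.  ``method`` "none" and
    "sds" return the matrix unchanged (SDS acts on scores, not on the
    matrix).
    """
    if spec.method in ("none", "sds"):
        return tm
    if spec.scope == "all":
        if spec.method == "bs":
            return bistochastic_scale(tm, tol=spec.ipf_tol, max_iter=spec.ipf_max_iter)
        return inflate_normalize(tm, gamma=spec.gamma, rounds=spec.rounds)

    missing = [b for b in spec.scope if b not in tm.index.layer_slices]
    if missing:
        raise ValueError(f"adjustment scope names unknown blocks: {missing}")
    out = copy.copy(tm)
    intra = sp.lil_matrix(tm.intra)
    for cid, lid in spec.scope:
        sl = tm.index.layer_slices[(cid, lid)]
        block = sp.csc_matrix(tm.intra[sl, sl])
        if spec.method == "bs":
            adj = bistochastic_scale(block, tol=spec.ipf_tol, max_iter=spec.ipf_max_iter)
        else:
            adj = inflate_normalize(block, gamma=spec.gamma, rounds=spec.rounds)
        intra[sl, sl] = adj
    out.intra = sp.csc_matrix(intra)
    out.remix()
    return out
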