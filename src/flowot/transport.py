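"""Optimal transport between weighted cluster sets and the similarity distance.

The transport program moves the mass ``p^i_k`` of each cluster of one
cytometry onto the clusters of another at cost ``c_kl`` per unit, giving the
optimal cost d_OT.  The naive cost d_NT uses the product coupling instead.
Their quotient d_S = d_OT / d_NT lies in [0, 1]: 0 means both cytometries are
the same weighted cluster set, 1 means transport can do no better than
spreading every cluster proportionally over all the others.  The optimal plan
also drives fuzzy and hard relabelling of one clustering by another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment, linprog

from .costs import ClusterDistanceSpec
from .model import DimensionMismatchError, MixtureClustering


@dataclass
class Coupling:
    """An optimal transport plan between two weighted cluster sets."""

    plan: np.ndarray  # (k_i, k_j), entries w*_kl
    row_weights: np.ndarray  # p^i_k
    col_weights: np.ndarray  # p^j_l
    cost: float  # optimal objective, d_OT

    def __post_init__(self) -> None:
        self.plan = np.asarray(self.plan, dtype=float)
        self.row_weights = np.asarray(self.row_weights, dtype=float)
        self.col_weights = np.asarray(self.col_weights, dtype=float)
        if np.any(self.plan < -1e-12):
            raise ValueError("coupling has negative entries")
        if np.abs(self.plan.sum(axis=1) - self.row_weights).max() > 1e-9:
            raise ValueError("row marginals violated")
        if np.abs(self.plan.sum(axis=0) - self.col_weights).max() > 1e-9:
            raise ValueError("column marginals violated")
        if abs(self.plan.sum() - 1.0) > 1e-9:
            raise ValueError("total mass is not 1")


@dataclass
class RelabelScores:
    """Fuzzy relabelling scores derived from an optimal coupling.

    ``s[k, l] = w*_kl / p^j_l`` is the share of target cluster ``l``'s mass
    that arrived from source cluster ``k`` (each column sums to 1).
    ``s_tilde[k, l] = s[k, l] * w*_kl / p^i_k`` additionally down-weights a
    small contribution from a big source cluster relative to a big
    contribution from a small one.
    """

    s: np.ndarray
    s_tilde: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.s_tilde = np.asarray(self.s_tilde, dtype=float)
        if np.any(self.s < -1e-12) or np.any(self.s > 1 + 1e-9):
            raise ValueError("s scores outside [0, 1]")
        if np.abs(self.s.sum(axis=0) - 1.0).max() > 1e-9:
            raise ValueError("columns of s must sum to 1")


def _check_weights(w: np.ndarray, name: str) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError(f"{name} contains a negative weight")
    total = w.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"{name} sums to {total}, more than 1e-6 from 1")
    return w / total


def solve_ot(
    row_weights: np.ndarray,
    col_weights: np.ndarray,
    cost_matrix: np.ndarray,
) -> Coupling:
    """Solve the transportation linear program exactly.

    Minimises ``sum_kl w_kl c_kl`` over nonnegative plans with prescribed
    row and column marginals.  Solved with the HiGHS simplex (deterministic
    pivoting), so repeated calls on the same input return the same plan.
    """
    p = _check_weights(row_weights, "row_weights")
    q = _check_weights(col_weights, "col_weights")
    C = np.asarray(cost_matrix, dtype=float)
    ki, kj = C.shape
    if p.shape[0] != ki or q.shape[0] != kj:
        raise ValueError("cost matrix shape does not match the weights")
    if not np.all(np.isfinite(C)):
        raise ValueError("cost matrix has non-finite entries")

    # equality constraints: row sums, then column sums (drop the last,
    # redundant, column constraint to keep the system full rank)
    A_eq = np.zeros((ki + kj - 1, ki * kj))
    for k in range(ki):
        A_eq[k, k * kj : (k + 1) * kj] = 1.0
    for l in range(kj - 1):
        A_eq[ki + l, l::kj] = 1.0
    b_eq = np.concatenate([p, q[:-1]])
    res = linprog(
        C.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs"
    )
    if not res.success:  # pragma: no cover - guarded by input validation
        raise RuntimeError(f"transport LP failed: {res.message}")
    plan = np.clip(res.x.reshape(ki, kj), 0.0, None)
    # tidy tiny solver round-off so the Coupling invariants hold exactly
    plan *= 1.0 / plan.sum()
    cost = float((plan * C).sum())
    return Coupling(plan=plan, row_weights=p, col_weights=q, cost=cost)


def naive_cost(
    row_weights: np.ndarray,
    col_weights: np.ndarray,
    cost_matrix: np.ndarray,
) -> float:
    """Product-coupling transport cost ``sum_kl p_k q_l c_kl`` (d_NT)."""
    p = _check_weights(row_weights, "row_weights")
    q = _check_weights(col_weights, "col_weights")
    C = np.asarray(cost_matrix, dtype=float)
    if not np.all(np.isfinite(C)):
        raise ValueError("cost matrix has non-finite entries")
    return float(p @ C @ q)


def cost_matrix(
    a: MixtureClustering, b: MixtureClustering, spec: ClusterDistanceSpec
) -> np.ndarray:
    """Pairwise cluster-distance matrix between two mixtures under ``spec``."""
    if a.dim != b.dim:
        raise DimensionMismatchError("mixtures differ in dimension")
    C = np.empty((a.n_components, b.n_components))
    for k, ca in enumerate(a.components):
        for l, cb in enumerate(b.components):
            C[k, l] = spec.component_cost(ca, cb)
    return C


def similarity_distance(
    a: MixtureClustering,
    b: MixtureClustering,
    spec: ClusterDistanceSpec | None = None,
) -> float:
    """Similarity distance d_S = d_OT / d_NT between two mixture clusterings.

    Lies in [0, 1] and is parameter-free once the cluster cost (default:
    Gaussian W2) is chosen.  When d_NT = 0 both cytometries consist of
    identical clusters and 0 is returned with a warning.
    """
    spec = spec or ClusterDistanceSpec()
    C = cost_matrix(a, b, spec)
    p, q = a.weights, b.weights
    d_nt = naive_cost(p, q, C)
    if d_nt == 0.0:
        warnings.warn(
            "all clusters identical across both cytometries (d_NT = 0); "
            "similarity distance defined as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    d_ot = solve_ot(p, q, C).cost
    return float(min(max(d_ot / d_nt, 0.0), 1.0))


def fuzzy_relabel(coupling: Coupling) -> RelabelScores:
    """Fuzzy relabelling scores s and s~ from an optimal coupling."""
    if np.any(coupling.col_weights <= 0):
        raise ValueError("zero column weight; scores undefined")
    if np.any(coupling.row_weights <= 0):
        raise ValueError("zero row weight; scores undefined")
    s = coupling.plan / coupling.col_weights[None, :]
    s_tilde = s * coupling.plan / coupling.row_weights[:, None]
    return RelabelScores(s=np.clip(s, 0.0, 1.0), s_tilde=s_tilde)


def hard_relabel(scores: RelabelScores, mode: str = "argmax_s") -> dict[int, int]:
    """Hard map from each target cluster index to a source cluster index.

    ``argmax_s`` / ``argmax_s_tilde`` pick per-column maxima (ties broken by
    larger s~, then lower source index).  ``hungarian`` solves the assignment
    problem on ``-s_tilde``; with more target than source clusters the
    unmatched columns fall back to their argmax of s~.
    """
    s, st = scores.s, scores.s_tilde
    ki, kj = s.shape
    if mode in ("argmax_s", "argmax_s_tilde"):
        primary = s if mode == "argmax_s" else st
        mapping = {}
        for l in range(kj):
            col = primary[:, l]
            best = col.max()
            cands = np.flatnonzero(np.isclose(col, best, rtol=0, atol=1e-15))
            if len(cands) > 1:
                tie = st[cands, l]
                cands = cands[np.isclose(tie, tie.max(), rtol=0, atol=1e-15)]
            mapping[l] = int(cands[0])
        return mapping
    if mode == "hungarian":
        rows, cols = linear_sum_assignment(-st)
        mapping = {int(l): int(k) for k, l in zip(rows, cols)}
        for l in range(kj):  # rectangular case: unmatched target clusters
            if l not in mapping:
                mapping[l] = int(np.argmax(st[:, l]))
        return mapping
    raise ValueError(f"unknown mode {mode!r}")
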