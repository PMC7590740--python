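"""Wasserstein barycenters of Gaussians and trimmed k-barycenter clustering.

The W2 barycenter of Gaussians ``N(m_i, S_i)`` with weights ``lambda_i`` is
the Gaussian with mean ``sum lambda_i m_i`` and covariance the fixed point of

    S  ->  S^{-1/2} ( sum_i lambda_i (S^{1/2} S_i S^{1/2})^{1/2} )^2 S^{-1/2}.

Trimmed k-barycenters run a Lloyd-style alternation in Wasserstein space:
assign components to their nearest barycenter by squared W2, trim the worst
fraction, recompute barycenters, repeat.  This is the consensus machinery
behind template formation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._linalg import spd_inv_sqrt, spd_sqrt, sym
from .costs import gaussian_w2
from .model import GaussianComponent

logger = logging.getLogger(__name__)


class BarycenterNonConvergence(RuntimeError):
    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"barycenter fixed point not reached after {max_iter} iterations "
            f"(residual {residual:.3e})"
        )


@dataclass
class KBaryResult:
    """Result of trimmed k-barycenter clustering of Gaussian components.

    ``assignment[i]`` is the group of component ``i`` in ``{0, ..., K}`` with
    0 meaning trimmed; ``barycenters`` holds one consensus component per
    group; ``objective`` is the mass-weighted sum of squared W2 distances of
    untrimmed components to their assigned barycenter.
    """

    assignment: np.ndarray
    barycenters: list[GaussianComponent]
    objective: float
    objective_history: list[float] = field(default_factory=list)


def w2_barycenter(
    components: list[GaussianComponent],
    lambdas: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    weight: float | None = None,
    label: str | None = None,
) -> GaussianComponent:
    """W2 barycenter of Gaussian components via the covariance fixed point.

    ``lambdas`` default to uniform; they are renormalised to sum to 1.  The
    iteration starts at the Euclidean average ``sum lambda_i S_i`` and stops
    when successive covariance iterates differ by less than ``tol`` in
    Frobenius norm.  The output weight defaults to the mean of the input
    component weights.
    """
    if not components:
        raise ValueError("need at least one component")
    d = components[0].dim
    if any(c.dim != d for c in components):
        raise ValueError("components must share a dimension")
    if lambdas is None:
        lam = np.full(len(components), 1.0 / len(components))
    else:
        lam = np.asarray(lambdas, dtype=float)
        if lam.shape[0] != len(components) or np.any(lam < 0):
            raise ValueError("lambdas must be nonnegative, one per component")
        lam = lam / lam.sum()
    mean = sum(l * c.mean for l, c in zip(lam, components))
    covs = [c.cov for c in components]
    S = sym(sum(l * c for l, c in zip(lam, covs)))
    residual = np.inf
    for _ in range(max_iter):
        root = spd_sqrt(S)
        inner = sum(l * spd_sqrt(root @ c @ root) for l, c in zip(lam, covs))
        S_next = spd_inv_sqrt(S) @ (inner @ inner) @ spd_inv_sqrt(S)
        S_next = sym(S_next)
        residual = float(np.linalg.norm(S_next - S, "fro"))
        S = S_next
        if residual < tol:
            break
    else:
        raise BarycenterNonConvergence(residual, max_iter)
    if weight is None:
        weight = float(np.mean([c.weight for c in components]))
    return GaussianComponent(mean=mean, cov=S, weight=weight, label=label)


def trimmed_kbarycenters(
    components: list[GaussianComponent],
    K: int,
    trim: float = 0.0,
    seed: int | None = None,
    n_restarts: int = 10,
    max_iter: int = 100,
) -> KBaryResult:
    """Trimmed k-barycenters of a pooled collection of Gaussian components.

    Lloyd alternation: each component joins its nearest barycenter under
    squared W2; the ``ceil(N * trim)`` components farthest from their
    assigned barycenter are trimmed; each group's barycenter is recomputed
    with lambda proportional to the component weights.  The best of
    ``n_restarts`` seeded initialisations (random K-subsets of the
    components) by final objective is returned.
    """
    N = len(components)
    if not (0.0 <= trim < 1.0):
        raise ValueError("trim must be in [0, 1)")
    if K < 1 or N < K:
        raise ValueError(f"need at least K={K} components, got {N}")
    n_trim = math.ceil(N * trim)
    if N - n_trim < K:
        raise ValueError("trimming leaves fewer components than groups")
    rng = np.random.default_rng(seed)
    best: KBaryResult | None = None
    for _ in range(n_restarts):
        init_idx = rng.choice(N, size=K, replace=False)
        result = _kbary_once(components, K, n_trim, init_idx, max_iter)
        if best is None or result.objective < best.objective:
            best = result
    assert best is not None
    return best


def _kbary_once(
    components: list[GaussianComponent],
    K: int,
    n_trim: int,
    init_idx: np.ndarray,
    max_iter: int,
) -> KBaryResult:
    N = len(components)
    centers = [
        GaussianComponent(
            mean=components[i].mean.copy(),
            cov=components[i].cov.copy(),
            weight=components[i].weight,
        )
        for i in init_idx
    ]
    masses = np.array([c.weight for c in components])
    prev_assign = None
    assignment = np.zeros(N, dtype=int)
    objective = np.inf
    history: list[float] = []
    for _ in range(max_iter):
        # assignment step: squared W2 to nearest center
        D2 = np.empty((N, K))
        for i, comp in enumerate(components):
            for j, cen in enumerate(centers):
                D2[i, j] = gaussian_w2(comp, cen) ** 2
        nearest = D2.argmin(axis=1)
        d_assigned = D2[np.arange(N), nearest]
        assignment = nearest + 1
        if n_trim > 0:
            # trim the components farthest from their assigned center
            order = np.argsort(-d_assigned, kind="stable")
            assignment[order[:n_trim]] = 0
        objective = float(
            (masses * d_assigned)[assignment > 0].sum()
        )
        history.append(objective)
        if prev_assign is not None and np.array_equal(assignment, prev_assign):
            break
        prev_assign = assignment.copy()
        # update step
        for j in range(K):
            idx = np.flatnonzero(assignment == j + 1)
            if idx.size == 0:
                # respawn an emptied group at the farthest untrimmed component
                untrimmed = np.flatnonzero(assignment > 0)
                far = untrimmed[np.argmax(d_assigned[untrimmed])]
                logger.info("k-barycenters: respawning empty group %d", j + 1)
                centers[j] = GaussianComponent(
                    mean=components[far].mean.copy(),
                    cov=components[far].cov.copy(),
                    weight=components[far].weight,
                )
                continue
            lam = masses[idx] / masses[idx].sum()
            centers[j] = w2_barycenter(
                [components[i] for i in idx], lambdas=lam
            )
    return KBaryResult(
        assignment=assignment,
        barycenters=centers,
        objective=objective,
        objective_history=history,
    )
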