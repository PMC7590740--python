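"""Distances between individual clusters.

These are the ground costs ``d(C^i_k, C^j_l)`` plugged into the optimal
transport program behind the similarity distance, plus the averaged
dissimilarities used by the flowMatch baseline.  Clusters are treated either
as Gaussians (W2, symmetric KL, Mahalanobis) or as empirical point sets
(entropy-regularised OT, mean pairwise squared distance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import check_spd, logdet_spd, spd_sqrt, sym
from .model import DimensionMismatchError, GaussianComponent, MixtureClustering


@dataclass
class ClusterDistanceSpec:
    """Choice of cluster-level cost for the similarity distance.

    kind : one of ``w2_gaussian``, ``kl_symmetric``, ``sinkhorn_empirical``,
        ``mean_pairwise_sq``.
    squared : use the squared cost in the transport program (only meaningful
        for ``w2_gaussian``; the unsquared W2 is the default).
    gamma : entropy regularisation strength for ``sinkhorn_empirical``.
    subsample_cap : subsampling threshold for ``mean_pairwise_sq``.
    """

    kind: str = "w2_gaussian"
    squared: bool = False
    gamma: float = 0.1
    subsample_cap: int = 10_000

    def __post_init__(self) -> None:
        kinds = {"w2_gaussian", "kl_symmetric", "sinkhorn_empirical", "mean_pairwise_sq"}
        if self.kind not in kinds:
            raise ValueError(f"unknown cluster distance kind {self.kind!r}")
        if self.kind == "sinkhorn_empirical" and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.subsample_cap < 2:
            raise ValueError("subsample_cap must be at least 2")

    def component_cost(self, a: GaussianComponent, b: GaussianComponent) -> float:
        if self.kind == "w2_gaussian":
            d = gaussian_w2(a, b)
            return d * d if self.squared else d
        if self.kind == "kl_symmetric":
            return kl_symmetric(a, b)
        raise ValueError(
            f"{self.kind!r} needs point sets; use it on raw events, not summaries"
        )


def gaussian_w2(a: GaussianComponent, b: GaussianComponent) -> float:
    """2-Wasserstein distance between two Gaussian distributions.

    ``W2^2 = ||m_a - m_b||^2 + tr(S_a + S_b - 2 (S_a^{1/2} S_b S_a^{1/2})^{1/2})``.
    """
    if a.dim != b.dim:
        raise DimensionMismatchError("components differ in dimension")
    check_spd(a.cov)
    check_spd(b.cov)
    if np.array_equal(a.mean, b.mean) and np.array_equal(a.cov, b.cov):
        return 0.0  # exact zero on identical parameters
    dm = a.mean - b.mean
    ra = spd_sqrt(a.cov)
    cross = spd_sqrt(ra @ b.cov @ ra)
    bures = np.trace(a.cov) + np.trace(b.cov) - 2.0 * np.trace(cross)
    return float(np.sqrt(max(dm @ dm + bures, 0.0)))


def kl_symmetric(a: GaussianComponent, b: GaussianComponent) -> float:
    """Symmetrised Kullback-Leibler divergence between two Gaussians.

    Returns ``(KL(N_a || N_b) + KL(N_b || N_a)) / 2`` in closed form.
    """
    if a.dim != b.dim:
        raise DimensionMismatchError("components differ in dimension")
    return 0.5 * (_kl_gauss(a, b) + _kl_gauss(b, a))


def _kl_gauss(a: GaussianComponent, b: GaussianComponent) -> float:
    d = a.dim
    sb_inv = np.linalg.inv(sym(b.cov))
    dm = b.mean - a.mean
    val = (
        np.trace(sb_inv @ a.cov)
        + dm @ sb_inv @ dm
        - d
        + logdet_spd(b.cov)
        - logdet_spd(a.cov)
    )
    return 0.5 * float(val)


class SinkhornNonConvergence(RuntimeError):
    def __init__(self, iterations: int, residual: float):
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"Sinkhorn did not reach tolerance after {iterations} iterations "
            f"(marginal residual {residual:.3e})"
        )


def sinkhorn_empirical(
    points_a: np.ndarray,
    points_b: np.ndarray,
    gamma: float,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> float:
    """Entropy-regularised OT cost between two uniform empirical measures.

    Squared Euclidean ground cost; the entropic penalty is
    ``gamma * KL(plan || product)``.  Returns the transport part
    ``<plan, cost>`` of the optimum, found by log-domain Sinkhorn iterations
    run until the marginal residual drops below ``tol``.
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise DimensionMismatchError("point sets differ in dimension")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    n, m = a.shape[0], b.shape[0]
    C = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=-1)
    log_mu = np.full(n, -np.log(n))
    log_nu = np.full(m, -np.log(m))
    f = np.zeros(n)
    g = np.zeros(m)
    residual = np.inf
    for _ in range(max_iter):
        # log-domain Sinkhorn updates on the dual potentials f, g
        f = gamma * log_mu - gamma * _lse((-C + g[None, :]) / gamma, axis=1)
        g = gamma * log_nu - gamma * _lse((-C + f[:, None]) / gamma, axis=0)
        plan = np.exp((-C + f[:, None] + g[None, :]) / gamma)
        residual = max(
            np.abs(plan.sum(axis=1) - np.exp(log_mu)).max(),
            np.abs(plan.sum(axis=0) - np.exp(log_nu)).max(),
        )
        if residual < tol:
            return float((plan * C).sum())
    raise SinkhornNonConvergence(max_iter, residual)


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    amax = a.max(axis=axis, keepdims=True)
    return amax.squeeze(axis) + np.log(np.exp(a - amax).sum(axis=axis))


def mean_pairwise_sq(
    points_a: np.ndarray,
    points_b: np.ndarray,
    subsample_cap: int = 10_000,
    seed: int | None = None,
) -> float:
    """Mean squared Euclidean distance over all point pairs.

    ``(1/|A||B|) sum_x sum_y ||x - y||^2``.  Any set larger than
    ``subsample_cap`` is first replaced by a seeded uniform subsample, which
    keeps the cost usable for very large clusters while still allowing the
    labelling of small ones.
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise DimensionMismatchError("point sets differ in dimension")
    rng = np.random.default_rng(seed)
    if a.shape[0] > subsample_cap:
        a = a[rng.choice(a.shape[0], subsample_cap, replace=False)]
    if b.shape[0] > subsample_cap:
        b = b[rng.choice(b.shape[0], subsample_cap, replace=False)]
    # E||x-y||^2 = E||x||^2 + E||y||^2 - 2 <mean_a, mean_b>, exact rewrite of
    # the double sum without the n*m memory.
    sq_a = (a**2).sum(axis=1).mean()
    sq_b = (b**2).sum(axis=1).mean()
    return float(sq_a + sq_b - 2.0 * a.mean(axis=0) @ b.mean(axis=0))


def mahalanobis_gaussians(a: GaussianComponent, b: GaussianComponent) -> float:
    """Mahalanobis distance between two Gaussians, pooled-covariance form.

    ``d^2 = (m_a - m_b)' ((S_a + S_b)/2)^{-1} (m_a - m_b)``.
    """
    if a.dim != b.dim:
        raise DimensionMismatchError("components differ in dimension")
    pooled = sym((a.cov + b.cov) / 2.0)
    check_spd(pooled, "pooled covariance")
    dm = a.mean - b.mean
    return float(np.sqrt(max(dm @ np.linalg.solve(pooled, dm), 0.0)))


def flowmatch_dissimilarity(
    a: MixtureClustering, b: MixtureClustering, kind: str = "kl"
) -> float:
    """flowMatch-style averaged pairwise dissimilarity between two mixtures.

    ``(1/(k_a k_b)) sum_k sum_l d(C^a_k, C^b_l)`` with ``d`` either the
    symmetrised KL divergence or the pooled-covariance Mahalanobis distance.
    Note this averages *all* pairs, so it is strictly positive even between a
    mixture and itself when components are separated.
    """
    if a.dim != b.dim:
        raise DimensionMismatchError("mixtures differ in dimension")
    if kind == "kl":
        pair = kl_symmetric
    elif kind == "mahalanobis":
        pair = mahalanobis_gaussians
    else:
        raise ValueError(f"unknown kind {kind!r}")
    total = 0.0
    for ca in a.components:
        for cb in b.components:
            total += pair(ca, cb)
    return total / (a.n_components * b.n_components)
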