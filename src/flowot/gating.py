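"""Trimmed model-based gating (tclust) and template-guided classification.

tclust searches for a partition ``{C_0, ..., C_k}`` of the events, with
``|C_0| = ceil(n * alpha)`` trimmed, that approximately maximises the trimmed
classification pseudo-likelihood

    sum_j sum_{i in C_j} log( p_j * phi(x_i; m_j, S_j) )

subject to an eigenvalue-ratio restriction: across all cluster scatter
matrices, max eigenvalue / min eigenvalue <= c.  The restriction is enforced
after every M-step by the finite-candidate-set truncation construction, which
picks the truncation level maximising the restricted objective.

The end-to-end classifier clusters a new cytometry with tclust initialised
from every template, keeps the best fit by pseudo-likelihood, assigns the
fitted mixture to its nearest template in similarity distance, and labels the
events by OT label transfer, QDA from the template, or a supervised learner
trained on the most similar database cytometry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

from ._linalg import sym
from .costs import ClusterDistanceSpec
from .model import (
    DimensionMismatchError,
    EventTable,
    GatedCytometry,
    GaussianComponent,
    MixtureClustering,
    summarize,
)
from .templates import CytometryTemplates, MetaPartition, Template
from .transport import (
    cost_matrix,
    fuzzy_relabel,
    hard_relabel,
    similarity_distance,
    solve_ot,
)

logger = logging.getLogger(__name__)


@dataclass
class TclustParams:
    """Tuning parameters for trimmed model-based clustering."""

    k: int
    alpha: float = 0.05
    restr_factor: float = 1e6
    max_iter: int = 100
    tol: float = 1e-9
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError("alpha must be in [0, 1)")
        if self.restr_factor < 1.0:
            raise ValueError("restr_factor must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class TclustInit:
    """Initial weights, means and covariances for the CEM iterations."""

    weights: np.ndarray
    means: np.ndarray  # (k, d)
    covs: np.ndarray  # (k, d, d)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covs = np.asarray(self.covs, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("initial weights must sum to 1")
        self.weights = self.weights / self.weights.sum()

    @classmethod
    def from_mixture(cls, mixture: MixtureClustering) -> "TclustInit":
        return cls(
            weights=mixture.weights,
            means=np.stack([c.mean for c in mixture.components]),
            covs=np.stack([c.cov for c in mixture.components]),
        )


@dataclass
class TclustResult:
    """A trimmed hard clustering: assignment 0 marks the trimmed set C_0."""

    assignment: np.ndarray
    components: list[GaussianComponent]
    loglik: float
    objective_history: list[float] = field(default_factory=list)
    eig_ratio_history: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def _restrict_eigenvalues(
    eigs: np.ndarray, sizes: np.ndarray, c: float
) -> np.ndarray:
    """Truncate cluster eigenvalues so max/min <= c, maximising the objective.

    ``eigs`` is (k, d) of raw scatter eigenvalues, ``sizes`` the untrimmed
    cluster counts.  The optimal common truncation interval ``[t, c t]`` is
    found over the finite candidate set built from the eigenvalues and the
    per-interval stationary points; each eigenvalue is clamped into it.
    """
    eigs = np.asarray(eigs, dtype=float)
    pos = eigs[eigs > 0]
    if pos.size and eigs.min() > 0 and pos.max() / eigs.min() <= c + 1e-12:
        return eigs
    n = sizes.sum()
    if n == 0 or not np.any(eigs > 0):
        return np.ones_like(eigs)
    bounds = np.unique(np.concatenate([eigs.ravel(), eigs.ravel() / c]))
    bounds = bounds[bounds > 0]
    # within each interval between consecutive bounds the truncated sets are
    # constant, so the objective has one stationary point there: evaluate the
    # set membership at the interval midpoint and solve in closed form
    probes = np.concatenate(
        [bounds, (bounds[:-1] + bounds[1:]) / 2.0, [bounds[-1] * 2.0],
         [bounds[0] / 2.0]]
    )
    extra = []
    for e in probes:
        below = eigs < e
        above = eigs > c * e
        r = (below | above).sum(axis=1).astype(float)
        s = np.where(below, eigs, 0.0).sum(axis=1)
        t = np.where(above, eigs, 0.0).sum(axis=1)
        denom = (sizes * r).sum()
        if denom > 0:
            extra.append((sizes * (s + t / c)).sum() / denom)
    candidates = np.unique(np.concatenate([bounds, np.array(extra)]))
    candidates = candidates[candidates > 0]

    def objective(t: float) -> float:
        trunc = np.clip(eigs, t, c * t)
        return float(
            (sizes[:, None] * (np.log(trunc) + eigs / trunc)).sum() / n
        )

    best = min(candidates, key=objective)
    return np.clip(eigs, best, c * best)


def tclust_fit(
    events: EventTable | np.ndarray,
    params: TclustParams,
    init: TclustInit,
) -> TclustResult:
    """Run classification-EM for the trimmed pseudo-likelihood.

    Per iteration: compute ``D_j = p_j * phi(x; m_j, S_j)`` for every event,
    trim the ``ceil(n * alpha)`` events with the smallest best posterior mass,
    assign the rest to their argmax cluster (ties to the lower index), update
    weights (over the untrimmed count), means and covariances, and enforce the
    eigenvalue-ratio restriction.  Stops at an assignment fixed point or
    ``max_iter``.  The recorded objective is the trimmed pseudo-likelihood and
    is non-decreasing across iterations.
    """
    X = events.values if isinstance(events, EventTable) else np.asarray(events, float)
    n, d = X.shape
    k = params.k
    if init.means.shape != (k, d):
        raise ValueError("init size does not match k and the event dimension")
    if n <= k * (d + 1):
        raise ValueError(f"too few events ({n}) for k={k} clusters in {d}-D")
    n_trim = math.ceil(n * params.alpha)
    if n_trim >= n:
        raise ValueError("alpha trims every event")

    p = init.weights.copy()
    means = init.means.copy()
    covs = np.array([sym(c) for c in init.covs])
    sizes = np.maximum(np.round(p * (n - n_trim)), 1.0)
    covs = _apply_restriction(covs, sizes, params.restr_factor)

    assignment = np.full(n, -1, dtype=int)
    history: list[float] = []
    ratio_history: list[float] = []
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        logD = np.full((n, k), -np.inf)
        for j in range(k):
            if p[j] <= 0:
                continue
            logD[:, j] = np.log(p[j]) + _gauss_logpdf(X, means[j], covs[j])
        best_j = logD.argmax(axis=1)  # ties -> lower index
        best_val = logD[np.arange(n), best_j]
        new_assignment = best_j + 1
        if n_trim > 0:
            trim_idx = np.argsort(best_val, kind="stable")[:n_trim]
            new_assignment[trim_idx] = 0
        objective = float(best_val[new_assignment > 0].sum())
        history.append(objective)
        if np.array_equal(new_assignment, assignment):
            converged = True
            assignment = new_assignment
            break
        assignment = new_assignment
        # M-step
        untrimmed = assignment > 0
        n_eff = int(untrimmed.sum())
        sizes = np.zeros(k)
        for j in range(k):
            idx = np.flatnonzero(assignment == j + 1)
            if idx.size == 0:
                # re-seed the emptied cluster at the worst-fit untrimmed event
                worst = np.flatnonzero(untrimmed)[
                    np.argmin(best_val[untrimmed])
                ]
                logger.info("tclust: re-seeding empty cluster %d", j + 1)
                means[j] = X[worst]
                sizes[j] = 1.0
                continue
            sizes[j] = idx.size
            means[j] = X[idx].mean(axis=0)
            diff = X[idx] - means[j]
            covs[j] = sym(diff.T @ diff / idx.size)
        p = sizes / n_eff
        covs = _apply_restriction(covs, sizes, params.restr_factor)
        ratio_history.append(_eig_ratio(covs))

    components = []
    total_w = 0.0
    for j in range(k):
        w = float((assignment == j + 1).sum())
        total_w += w
    for j in range(k):
        w = float((assignment == j + 1).sum()) / max(total_w, 1.0)
        if w <= 0:
            continue
        components.append(
            GaussianComponent(mean=means[j].copy(), cov=covs[j].copy(), weight=w)
        )
    loglik = _pseudo_likelihood(X, assignment, p, means, covs)
    return TclustResult(
        assignment=assignment,
        components=components,
        loglik=loglik,
        objective_history=history,
        eig_ratio_history=ratio_history,
        n_iter=it,
        converged=converged,
    )


def _eig_ratio(covs: np.ndarray) -> float:
    eigs = np.concatenate([np.linalg.eigvalsh(sym(c)) for c in covs])
    return float(eigs.max() / eigs.min())


def _apply_restriction(covs: np.ndarray, sizes: np.ndarray, c: float) -> np.ndarray:
    k = covs.shape[0]
    eigs = np.empty((k, covs.shape[1]))
    vecs = []
    for j in range(k):
        w, v = np.linalg.eigh(sym(covs[j]))
        eigs[j] = w
        vecs.append(v)
    trunc = _restrict_eigenvalues(eigs, np.asarray(sizes, float), c)
    out = np.empty_like(covs)
    for j in range(k):
        out[j] = sym((vecs[j] * trunc[j]) @ vecs[j].T)
    return out


def _gauss_logpdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    d = X.shape[1]
    chol = np.linalg.cholesky(sym(cov))
    z = solve_triangular(chol, (X - mean).T, lower=True)
    maha = (z**2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _pseudo_likelihood(X, assignment, p, means, covs) -> float:
    total = 0.0
    for j in range(len(p)):
        idx = np.flatnonzero(assignment == j + 1)
        if idx.size == 0 or p[j] <= 0:
            continue
        total += float(
            (np.log(p[j]) + _gauss_logpdf(X[idx], means[j], covs[j])).sum()
        )
    return total


class TrimmedGaussianMixture(BaseEstimator, ClusterMixin):
    """scikit-learn estimator wrapping the trimmed CEM clusterer.

    ``fit(X)`` exposes ``labels_`` with sklearn's outlier convention
    (``-1`` for trimmed events, ``0..k-1`` for clusters) and ``result_``
    holding the full :class:`TclustResult` (whose assignment uses 0 for the
    trimmed set).  Without an explicit ``init`` the CEM is restarted
    ``n_init`` times from random event subsets and the best fit by trimmed
    pseudo-likelihood is kept.
    """

    def __init__(
        self,
        k: int = 2,
        alpha: float = 0.05,
        restr_factor: float = 1e6,
        max_iter: int = 100,
        n_init: int = 5,
        init: TclustInit | None = None,
        random_state: int | None = None,
    ):
        self.k = k
        self.alpha = alpha
        self.restr_factor = restr_factor
        self.max_iter = max_iter
        self.n_init = n_init
        self.init = init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        params = TclustParams(
            k=self.k,
            alpha=self.alpha,
            restr_factor=self.restr_factor,
            max_iter=self.max_iter,
        )
        if self.init is not None:
            self.result_ = tclust_fit(X, params, self.init)
        else:
            rng = np.random.default_rng(self.random_state)
            best = None
            global_cov = sym(np.cov(X, rowvar=False).reshape(X.shape[1], -1))
            for _ in range(self.n_init):
                idx = rng.choice(X.shape[0], size=self.k, replace=False)
                init = TclustInit(
                    weights=np.full(self.k, 1.0 / self.k),
                    means=X[idx],
                    covs=np.stack([global_cov / self.k] * self.k),
                )
                res = tclust_fit(X, params, init)
                if best is None or res.loglik > best.loglik:
                    best = res
            self.result_ = best
        self.labels_ = self.result_.assignment - 1
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def best_unsupervised_partition(
    target: EventTable,
    templates: Sequence[Template],
    params: TclustParams,
    external_partition: np.ndarray | None = None,
) -> tuple[TclustResult | None, MixtureClustering]:
    """Cluster a target cytometry with tclust initialised from each template.

    Each template supplies an initial mixture (k = its component count); the
    fit with the highest trimmed pseudo-likelihood wins.  ``C^u``, the
    mixture summary over the untrimmed events of the winning fit, is what
    gets compared with the templates downstream.  An externally supplied
    per-event partition bypasses tclust entirely.
    """
    if external_partition is not None:
        gated = GatedCytometry(events=target, labels=np.asarray(
            [str(v) for v in external_partition], dtype=object))
        return None, summarize(gated)
    if not templates:
        raise ValueError("need at least one template")
    failures = []
    best: TclustResult | None = None
    for tpl in templates:
        if tpl.mixture.dim != target.dim:
            raise DimensionMismatchError("template and target dimensions differ")
        init = TclustInit.from_mixture(tpl.mixture)
        p = TclustParams(
            k=tpl.mixture.n_components,
            alpha=params.alpha,
            restr_factor=params.restr_factor,
            max_iter=params.max_iter,
            tol=params.tol,
        )
        try:
            res = tclust_fit(target, p, init)
        except (ValueError, np.linalg.LinAlgError) as exc:
            failures.append(f"{tpl.mixture.id}: {exc}")
            continue
        if best is None or res.loglik > best.loglik:
            best = res
    if best is None:
        raise RuntimeError("all template-initialised fits failed: " + "; ".join(failures))
    cu = _summarize_result(target, best)
    return best, cu


def _summarize_result(target: EventTable, result: TclustResult) -> MixtureClustering:
    labels = np.array(
        [f"c{j}" if j > 0 else "trimmed" for j in result.assignment], dtype=object
    )
    keep = result.assignment > 0
    gated = GatedCytometry(
        events=EventTable(
            values=target.values[keep],
            markers=target.markers,
            id=target.id,
        ),
        labels=labels[keep],
    )
    mix = summarize(gated)
    # order components by cluster index so positions align with the sorted
    # cluster ids of the assignment vector
    order = sorted(range(mix.n_components), key=lambda i: int(mix.components[i].label[1:]))
    return MixtureClustering(
        components=[mix.components[i] for i in order], id=target.id
    )


def assign_to_template(
    cu: MixtureClustering,
    templates: Sequence[Template],
    spec: ClusterDistanceSpec | None = None,
) -> tuple[int, np.ndarray]:
    """Index of the template nearest to ``C^u`` in d_S, plus all distances."""
    if not templates:
        raise ValueError("need at least one template")
    spec = spec or ClusterDistanceSpec()
    dists = np.array(
        [similarity_distance(cu, t.mixture, spec) for t in templates]
    )
    return int(dists.argmin()), dists  # argmin ties -> lower index


def classify_events(
    target: EventTable,
    cu: MixtureClustering,
    template: Template,
    assignment: np.ndarray | None = None,
    group: Sequence[GatedCytometry] | None = None,
    strategy: str = "label_transfer",
    backend=None,
    spec: ClusterDistanceSpec | None = None,
    relabel_mode: str = "hungarian",
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Assign a cell-type label to every target event.

    Strategies:

    ``label_transfer``
        solve the OT program between the labelled template (source) and
        ``C^u`` (target), derive fuzzy scores, harden them (Hungarian by
        default) and propagate each cluster's transferred label to its
        events.  Trimmed events get the label of their nearest component of
        ``C^u`` in Mahalanobis distance and are flagged.
    ``qda_template``
        per-event ``argmax_j log p_j + log phi(x; m_j, S_j)`` over the
        labelled template components (quadratic discriminant rule).
    ``qda_nearest`` / ``backend_nearest``
        pick the group member closest to ``C^u`` in d_S, train QDA or the
        injected backend (``fit(X, y)`` / ``predict(X)``) on its events and
        predict the target.

    Returns ``(labels, trimmed_flags, info)``.
    """
    spec = spec or ClusterDistanceSpec()
    n = target.n_events
    trimmed = np.zeros(n, dtype=bool)
    if assignment is not None:
        assignment = np.asarray(assignment, dtype=int)
        trimmed = assignment == 0
    info: dict = {"strategy": strategy}

    if strategy == "label_transfer":
        src_labels = template.mixture.labels
        if any(l is None for l in src_labels):
            raise ValueError("label transfer needs a labelled template")
        if assignment is None:
            raise ValueError("label transfer needs the per-event assignment")
        C = cost_matrix(template.mixture, cu, spec)
        coupling = solve_ot(template.mixture.weights, cu.weights, C)
        scores = fuzzy_relabel(coupling)
        mapping = hard_relabel(scores, mode=relabel_mode)
        cluster_labels = [src_labels[mapping[l]] for l in range(cu.n_components)]
        info["cluster_labels"] = cluster_labels
        info["scores"] = scores
        labels = np.empty(n, dtype=object)
        cluster_ids = [j for j in np.unique(assignment) if j > 0]
        id_to_pos = {j: pos for pos, j in enumerate(cluster_ids)}
        for j in cluster_ids:
            labels[assignment == j] = cluster_labels[id_to_pos[j]]
        if trimmed.any():
            nearest = _nearest_component_mahalanobis(
                target.values[trimmed], cu
            )
            labels[np.flatnonzero(trimmed)] = np.array(
                [cluster_labels[j] for j in nearest], dtype=object
            )
        return labels, trimmed, info

    if strategy == "qda_template":
        src_labels = template.mixture.labels
        if any(l is None for l in src_labels):
            raise ValueError("template QDA needs a labelled template")
        logD = np.stack(
            [
                np.log(c.weight) + _gauss_logpdf(target.values, c.mean, c.cov)
                for c in template.mixture.components
            ],
            axis=1,
        )
        labels = np.array(
            [src_labels[j] for j in logD.argmax(axis=1)], dtype=object
        )
        return labels, trimmed, info

    if strategy in ("qda_nearest", "backend_nearest"):
        if not group:
            raise ValueError(f"{strategy} needs a non-empty group of cytometries")
        for g in group:
            if g.events.dim != target.dim:
                raise DimensionMismatchError("group member dimension mismatch")
        dists = np.array(
            [similarity_distance(cu, summarize(g), spec) for g in group]
        )
        best = int(dists.argmin())
        info["assigned_cytometry"] = group[best].id
        info["member_distances"] = dists
        learner = (
            QuadraticDiscriminantAnalysis(reg_param=1e-6)
            if strategy == "qda_nearest"
            else backend
        )
        if learner is None:
            raise ValueError("backend_nearest needs an injected backend")
        member = group[best]
        learner.fit(member.events.values, np.asarray(member.labels, dtype=object))
        labels = np.asarray(learner.predict(target.values), dtype=object)
        return labels, trimmed, info

    raise ValueError(f"unknown strategy {strategy!r}")


def _nearest_component_mahalanobis(points: np.ndarray, cu: MixtureClustering) -> np.ndarray:
    d2 = np.empty((points.shape[0], cu.n_components))
    for j, c in enumerate(cu.components):
        diff = points - c.mean
        d2[:, j] = (diff * np.linalg.solve(sym(c.cov), diff.T).T).sum(axis=1)
    return d2.argmin(axis=1)


class TemplateGatingClassifier(BaseEstimator):
    """End-to-end supervised gating: fit on a database, predict a cytometry.

    ``fit`` runs the template pipeline on the gated database.  ``predict``
    clusters the target with template-initialised tclust, assigns it to the
    nearest template in similarity distance and labels every event with the
    configured strategy.  The per-run report (assigned template, distances,
    assigned cytometry when applicable) lands in ``report_``.

    Parameters are the union of the template-building knobs (see
    :class:`~flowot.templates.CytometryTemplates`) and the gating knobs
    ``alpha`` (trimming level), ``restr_factor`` (eigenvalue-ratio bound) and
    ``strategy``.
    """

    def __init__(
        self,
        cluster_method: str = "complete",
        n_groups: int | None = None,
        cut_height: float | None = None,
        template_method: str = "pooling",
        k: int | None = None,
        trim: float = 0.0,
        alpha: float = 0.05,
        restr_factor: float = 1e6,
        max_iter: int = 100,
        strategy: str = "label_transfer",
        backend=None,
        cost: ClusterDistanceSpec | None = None,
        min_cluster_size: int | None = None,
        random_state: int | None = None,
    ):
        self.cluster_method = cluster_method
        self.n_groups = n_groups
        self.cut_height = cut_height
        self.template_method = template_method
        self.k = k
        self.trim = trim
        self.alpha = alpha
        self.restr_factor = restr_factor
        self.max_iter = max_iter
        self.strategy = strategy
        self.backend = backend
        self.cost = cost
        self.min_cluster_size = min_cluster_size
        self.random_state = random_state

    def fit(self, X: Sequence[GatedCytometry], y=None):
        if not X:
            raise ValueError("empty database")
        markers = X[0].events.markers
        for g in X:
            if g.events.markers != markers:
                raise DimensionMismatchError(
                    "database cytometries disagree on marker names"
                )
        self.markers_ = markers
        self.database_ = list(X)
        builder = CytometryTemplates(
            cluster_method=self.cluster_method,
            n_groups=self.n_groups,
            cut_height=self.cut_height,
            template_method=self.template_method,
            k=self.k,
            trim=self.trim,
            cost=self.cost,
            min_cluster_size=self.min_cluster_size,
            random_state=self.random_state,
        ).fit(X)
        self.meta_partition_ = builder.meta_partition_
        self.templates_ = builder.templates_
        self.distance_matrix_ = builder.distance_matrix_
        return self

    def predict(self, X: EventTable | np.ndarray) -> np.ndarray:
        labels, _, report = self._classify(X)
        self.report_ = report
        return labels

    def predict_with_report(self, X: EventTable | np.ndarray):
        labels, trimmed, report = self._classify(X)
        self.report_ = report
        return labels, trimmed, report

    def _classify(self, X):
        if isinstance(X, EventTable):
            target = X
            if target.markers != self.markers_:
                raise DimensionMismatchError(
                    f"target markers {target.markers} do not match the "
                    f"database markers {self.markers_}"
                )
        else:
            target = EventTable(
                values=np.asarray(X, dtype=float),
                markers=self.markers_,
                id="target",
            )
        params = TclustParams(
            k=1,  # per-template k is taken from each template
            alpha=self.alpha,
            restr_factor=self.restr_factor,
            max_iter=self.max_iter,
        )
        result, cu = best_unsupervised_partition(target, self.templates_, params)
        spec = self.cost or ClusterDistanceSpec()
        best_idx, dists = assign_to_template(cu, self.templates_, spec)
        chosen = self.templates_[best_idx]
        by_id = {g.id: g for g in self.database_}
        group = [by_id[i] for i in chosen.members if i in by_id]
        labels, trimmed, info = classify_events(
            target,
            cu,
            chosen,
            assignment=None if result is None else result.assignment,
            group=group,
            strategy=self.strategy,
            backend=self.backend,
            spec=spec,
        )
        report = {
            "assigned_template": best_idx,
            "assigned_members": list(chosen.members),
            "template_distances": dists,
            "strategy": self.strategy,
            "trimmed_count": int(trimmed.sum()),
        }
        report.update(
            {k: v for k, v in info.items() if k in ("assigned_cytometry",)}
        )
        return labels, trimmed, report


def optimal_flow_classification(
    target: EventTable,
    db: Sequence[GatedCytometry],
    **config,
) -> tuple[np.ndarray, dict]:
    """Functional one-call wrapper over :class:`TemplateGatingClassifier`."""
    clf = TemplateGatingClassifier(**config).fit(db)
    labels = clf.predict(target)
    return labels, clf.report_
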