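"""Template building: meta-clustering a database and forming prototypes.

A database of gated cytometries is summarised into mixtures, compared with
the similarity distance d_S, and meta-clustered (hierarchical linkage or a
density method on the precomputed d_S matrix).  Each resulting group of
cytometries is condensed into one prototype cytometry by one of three
consensus methods:

pooling
    needs cell-type labels: each label's components across members are merged
    into their W2 barycenter, so the template keeps the labels;
density
    pools all member components, clusters them by W2 proximity (HDBSCAN or a
    linkage cut) and takes one barycenter per component-cluster;
kbarycenter
    pools all member components and runs trimmed k-barycenters for a chosen
    number K of cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.cluster import DBSCAN, HDBSCAN

from .barycenter import trimmed_kbarycenters, w2_barycenter
from .costs import ClusterDistanceSpec, gaussian_w2
from .model import (
    DimensionMismatchError,
    GatedCytometry,
    GaussianComponent,
    MixtureClustering,
    summarize,
)
from .transport import similarity_distance

HIERARCHICAL_METHODS = ("single", "average", "complete")
DENSITY_METHODS = ("dbscan", "hdbscan")


@dataclass
class MetaPartition:
    """A partition of database cytometry ids into groups plus optional noise."""

    groups: list[list[str]]
    noise: list[str] = field(default_factory=list)
    method: dict = field(default_factory=dict)
    merge_list: list | None = None  # hierarchical dendrogram, scipy linkage rows

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            if not g:
                raise ValueError("empty meta-cluster group")
            if seen & set(g):
                raise ValueError("groups must be disjoint")
            seen |= set(g)
        if seen & set(self.noise):
            raise ValueError("noise overlaps a group")

    @property
    def all_ids(self) -> list[str]:
        out = [i for g in self.groups for i in g]
        out.extend(self.noise)
        return out


@dataclass
class Template:
    """A prototype cytometry for a group of similar cytometries."""

    mixture: MixtureClustering
    members: list[str]
    method: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("template must have at least one member")


def distance_matrix(
    db: Sequence[MixtureClustering],
    spec: ClusterDistanceSpec | None = None,
) -> np.ndarray:
    """Symmetric matrix of pairwise similarity distances over a database."""
    if len(db) < 2:
        raise ValueError("need at least two cytometries")
    d = db[0].dim
    if any(c.dim != d for c in db):
        raise DimensionMismatchError("database mixtures differ in dimension")
    spec = spec or ClusterDistanceSpec()
    N = len(db)
    D = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            D[i, j] = D[j, i] = similarity_distance(db[i], db[j], spec)
    return D


def meta_cluster(
    D: np.ndarray,
    ids: Sequence[str],
    method: str = "complete",
    n_groups: int | None = None,
    cut_height: float | None = None,
    eps: float = 0.1,
    min_cluster_size: int = 2,
    min_samples: int | None = None,
) -> MetaPartition:
    """Cluster cytometries from a precomputed d_S matrix.

    Hierarchical linkages (``single``/``average``/``complete``) cut the
    dendrogram at ``n_groups`` or ``cut_height`` and return the merge list
    for inspection.  ``dbscan``/``hdbscan`` run on the precomputed matrix and
    may leave noise cytometries, which are reported separately.
    """
    D = np.asarray(D, dtype=float)
    N = D.shape[0]
    if D.shape != (N, N) or len(ids) != N:
        raise ValueError("distance matrix and ids are inconsistent")
    ids = [str(i) for i in ids]
    if method in HIERARCHICAL_METHODS:
        if (n_groups is None) == (cut_height is None):
            raise ValueError("give exactly one of n_groups or cut_height")
        if n_groups is not None and n_groups > N:
            raise ValueError(f"n_groups={n_groups} exceeds database size {N}")
        Z = linkage(squareform(D, checks=False), method=method)
        if n_groups is not None:
            flat = fcluster(Z, t=n_groups, criterion="maxclust")
        else:
            flat = fcluster(Z, t=cut_height, criterion="distance")
        groups = _groups_from_flat(flat, ids)
        return MetaPartition(
            groups=groups,
            method={"method": method, "n_groups": n_groups, "cut_height": cut_height},
            merge_list=Z.tolist(),
        )
    if method == "dbscan":
        labels = DBSCAN(eps=eps, min_samples=min_samples or min_cluster_size,
                        metric="precomputed").fit_predict(D.copy())
    elif method == "hdbscan":
        # copy: sklearn's precomputed path may overwrite the input matrix
        labels = HDBSCAN(
            min_cluster_size=min_cluster_size,
            min_samples=min_samples,
            metric="precomputed",
        ).fit_predict(D.copy())
    else:
        raise ValueError(f"unknown meta-clustering method {method!r}")
    noise = [ids[i] for i in np.flatnonzero(labels < 0)]
    groups = _groups_from_flat(labels, ids, skip_negative=True)
    return MetaPartition(
        groups=groups,
        noise=noise,
        method={"method": method, "eps": eps, "min_cluster_size": min_cluster_size},
    )


def _groups_from_flat(flat, ids, skip_negative: bool = False) -> list[list[str]]:
    order: dict[int, list[str]] = {}
    for lab, ident in zip(flat, ids):
        if skip_negative and lab < 0:
            continue
        order.setdefault(int(lab), []).append(ident)
    return [order[k] for k in sorted(order)]


def template_pooling(group: Sequence[MixtureClustering]) -> Template:
    """Consensus template from labelled members, one barycenter per cell type.

    For each label seen in any member, the components carrying it are merged
    into their W2 barycenter with lambda proportional to the member cluster
    weights; the template proportion of the label is the mean of the member
    proportions, renormalised over all labels.
    """
    if not group:
        raise ValueError("empty group")
    for m in group:
        if any(c.label is None for c in m.components):
            raise ValueError(
                "pooling needs labelled components; use the density or "
                "k-barycenter template methods for unlabelled members"
            )
    label_order: dict[str, None] = {}
    for m in group:
        for c in m.components:
            label_order.setdefault(c.label, None)
    comps = []
    raw_weights = []
    for lab in label_order:
        members = [c for m in group for c in m.components if c.label == lab]
        lam = np.array([c.weight for c in members])
        bary = w2_barycenter(members, lambdas=lam, label=lab)
        comps.append(bary)
        raw_weights.append(float(np.mean([c.weight for c in members])))
    w = np.array(raw_weights)
    w = w / w.sum()
    comps = [
        GaussianComponent(mean=c.mean, cov=c.cov, weight=wi, label=c.label)
        for c, wi in zip(comps, w)
    ]
    members_ids = [m.id for m in group]
    return Template(
        mixture=MixtureClustering(components=comps, id="+".join(members_ids)),
        members=members_ids,
        method="pooling",
    )


def template_density(
    group: Sequence[MixtureClustering],
    method: str = "hdbscan",
    min_cluster_size: int | None = None,
    cut_height: float | None = None,
    n_groups: int | None = None,
    linkage_method: str = "average",
) -> Template:
    """Consensus template by density-clustering the pooled components.

    All member components are pooled and clustered by their pairwise W2
    distances; each component-cluster is replaced by its barycenter.
    ``min_cluster_size`` defaults to about half the group size: a genuine
    cell type recurs in most members, so smaller agglomerations are treated
    as structure inside one cell type, not as separate types.  Components
    assigned to noise are excluded; if everything is noise no consensus
    structure exists and an error is raised.  A singleton group is its own
    consensus and is copied through.
    """
    if not group:
        raise ValueError("empty group")
    if len(group) == 1:
        only = group[0]
        return Template(
            mixture=MixtureClustering(
                components=list(only.components), id=only.id
            ),
            members=[only.id],
            method="density",
        )
    pool = [c for m in group for c in m.components]
    n = len(pool)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = gaussian_w2(pool[i], pool[j])
    if min_cluster_size is None:
        min_cluster_size = max(2, (len(group) + 1) // 2)
    if method == "hdbscan":
        mcs = max(2, min(min_cluster_size, n))
        if n < 2:
            labels = np.zeros(n, dtype=int)
        else:
            # min_samples=1: with a few dozen pooled components each point
            # carries density on its own, so merging stays single-linkage-like
            labels = HDBSCAN(
                min_cluster_size=mcs, min_samples=1, metric="precomputed"
            ).fit_predict(D.copy())
    elif method in HIERARCHICAL_METHODS or method == "hierarchical":
        link = method if method in HIERARCHICAL_METHODS else linkage_method
        Z = linkage(squareform(D, checks=False), method=link)
        if n_groups is not None:
            labels = fcluster(Z, t=n_groups, criterion="maxclust") - 1
        elif cut_height is not None:
            labels = fcluster(Z, t=cut_height, criterion="distance") - 1
        else:
            raise ValueError("hierarchical component clustering needs a cut")
    else:
        raise ValueError(f"unknown component clustering method {method!r}")
    if np.all(labels < 0):
        raise ValueError("no consensus structure: all components are noise")
    comps = []
    weights = []
    for lab in sorted(set(labels[labels >= 0])):
        idx = np.flatnonzero(labels == lab)
        members = [pool[i] for i in idx]
        lam = np.array([c.weight for c in members])
        comps.append(w2_barycenter(members, lambdas=lam))
        weights.append(lam.sum())
    w = np.array(weights)
    w = w / w.sum()
    comps = [
        GaussianComponent(mean=c.mean, cov=c.cov, weight=wi)
        for c, wi in zip(comps, w)
    ]
    members_ids = [m.id for m in group]
    return Template(
        mixture=MixtureClustering(components=comps, id="+".join(members_ids)),
        members=members_ids,
        method="density",
    )


def template_kbarycenter(
    group: Sequence[MixtureClustering],
    K: int,
    trim: float = 0.0,
    seed: int | None = None,
) -> Template:
    """Consensus template via trimmed k-barycenters of the pooled components."""
    if not group:
        raise ValueError("empty group")
    pool = [c for m in group for c in m.components]
    result = trimmed_kbarycenters(pool, K=K, trim=trim, seed=seed)
    masses = np.array([c.weight for c in pool])
    weights = np.array(
        [masses[result.assignment == j + 1].sum() for j in range(K)]
    )
    weights = weights / weights.sum()
    comps = [
        GaussianComponent(mean=b.mean, cov=b.cov, weight=wi)
        for b, wi in zip(result.barycenters, weights)
    ]
    members_ids = [m.id for m in group]
    return Template(
        mixture=MixtureClustering(components=comps, id="+".join(members_ids)),
        members=members_ids,
        method="kbarycenter",
    )


class CytometryTemplates(BaseEstimator):
    """Meta-cluster a database of gated cytometries and build templates.

    scikit-learn-style estimator: ``fit`` takes a list of
    :class:`GatedCytometry` (or ready :class:`MixtureClustering` summaries)
    and exposes ``distance_matrix_``, ``meta_partition_`` and ``templates_``.

    Parameters
    ----------
    cluster_method : linkage name, ``dbscan`` or ``hdbscan``.
    n_groups, cut_height : dendrogram cut (exactly one for linkages).
    template_method : ``pooling``, ``density`` or ``kbarycenter``.
    k : number of template components for ``kbarycenter``.
    trim : trimming fraction for ``kbarycenter``.
    cost : cluster-level cost spec for d_S (default Gaussian W2).
    min_cluster_size, eps : density meta-clustering parameters.
    random_state : seed for the k-barycenter restarts.
    """

    def __init__(
        self,
        cluster_method: str = "complete",
        n_groups: int | None = None,
        cut_height: float | None = None,
        template_method: str = "pooling",
        k: int | None = None,
        trim: float = 0.0,
        cost: ClusterDistanceSpec | None = None,
        min_cluster_size: int | None = None,
        eps: float = 0.1,
        random_state: int | None = None,
    ):
        self.cluster_method = cluster_method
        self.n_groups = n_groups
        self.cut_height = cut_height
        self.template_method = template_method
        self.k = k
        self.trim = trim
        self.cost = cost
        self.min_cluster_size = min_cluster_size
        self.eps = eps
        self.random_state = random_state

    def fit(self, X: Sequence[GatedCytometry | MixtureClustering], y=None):
        summaries = [
            x if isinstance(x, MixtureClustering) else summarize(x) for x in X
        ]
        ids = [s.id or str(i) for i, s in enumerate(summaries)]
        spec = self.cost or ClusterDistanceSpec()
        self.summaries_ = summaries
        self.ids_ = ids
        self.distance_matrix_ = distance_matrix(summaries, spec)
        kwargs: dict = {}
        if self.cluster_method in HIERARCHICAL_METHODS:
            kwargs = {"n_groups": self.n_groups, "cut_height": self.cut_height}
        else:
            kwargs = {"eps": self.eps,
                      "min_cluster_size": self.min_cluster_size or 2}
        self.meta_partition_ = meta_cluster(
            self.distance_matrix_, ids, method=self.cluster_method, **kwargs
        )
        by_id = dict(zip(ids, summaries))
        self.templates_ = []
        group_lists = list(self.meta_partition_.groups) + [
            [i] for i in self.meta_partition_.noise  # noise -> singleton templates
        ]
        for group_ids in group_lists:
            group = [by_id[i] for i in group_ids]
            if self.template_method == "pooling":
                tpl = template_pooling(group)
            elif self.template_method == "density":
                tpl = template_density(
                    group, min_cluster_size=self.min_cluster_size
                )
            elif self.template_method == "kbarycenter":
                k = self.k or max(m.n_components for m in group)
                tpl = template_kbarycenter(
                    group, K=k, trim=self.trim, seed=self.random_state
                )
            else:
                raise ValueError(
                    f"unknown template method {self.template_method!r}"
                )
            self.templates_.append(tpl)
        return self


def optimal_flow_templates(
    db: Sequence[GatedCytometry | MixtureClustering],
    **config,
) -> tuple[MetaPartition, list[Template]]:
    """One-call template pipeline: summarise, compare, meta-cluster, condense.

    Thin functional wrapper over :class:`CytometryTemplates`; see that class
    for the configuration keys.
    """
    if len(db) < 2:
        raise ValueError("need at least two cytometries")
    est = CytometryTemplates(**config).fit(db)
    return est.meta_partition_, est.templates_
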