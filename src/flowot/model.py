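"""Core data model: event tables, gated cytometries and their mixture summaries.

A gated cytometry admits three equivalent views: a set of labelled points,
a partition of the points into cell-type clusters with weights, and a weighted
mixture of Gaussian components whose parameters are the empirical moments of
each cluster.  The mixture view is what every downstream distance, barycenter
and template computation operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CytometryError(ValueError):
    """Base class for data-model validation failures."""


class NonFiniteValueError(CytometryError):
    """An event matrix contains NaN or infinite entries."""


class DimensionMismatchError(CytometryError):
    """Operands do not share a common marker dimension."""


@dataclass
class EventTable:
    """A cytometry as an ``n x d`` matrix of marker intensities.

    Parameters
    ----------
    values : ndarray of shape (n, d)
        Marker intensities, arbitrary fluorescence units.
    markers : list of str
        The ``d`` marker (channel) names, unique, in column order.
    id : str
        Opaque sample identifier.
    """

    values: np.ndarray
    markers: list[str]
    id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise CytometryError("event values must be a 2-D matrix")
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise CytometryError("need at least one event and one marker")
        if not np.all(np.isfinite(self.values)):
            raise NonFiniteValueError(f"non-finite value in events of {self.id!r}")
        self.markers = [str(m) for m in self.markers]
        if len(self.markers) != d:
            raise CytometryError(
                f"{len(self.markers)} marker names for {d} columns"
            )
        if len(set(self.markers)) != d:
            raise CytometryError("marker names must be unique")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class GatedCytometry:
    """An :class:`EventTable` together with a per-event cell-type label."""

    events: EventTable
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 1 or len(self.labels) != self.events.n_events:
            raise CytometryError("labels must be one per event")

    @property
    def label_set(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    @property
    def id(self) -> str:
        return self.events.id


@dataclass
class GaussianComponent:
    """One mixture component: mean ``m``, covariance ``S``, weight ``p``."""

    mean: np.ndarray
    cov: np.ndarray
    weight: float
    label: str | None = None

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        d = self.mean.shape[0]
        if self.cov.shape != (d, d):
            raise DimensionMismatchError("cov shape does not match mean")
        if not np.allclose(self.cov, self.cov.T, atol=1e-9):
            raise CytometryError("covariance must be symmetric (tol 1e-9)")
        if not (0.0 < self.weight <= 1.0 + 1e-12):
            raise CytometryError(f"weight {self.weight} outside (0, 1]")
        self.weight = float(self.weight)

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


@dataclass
class MixtureClustering:
    """A gated cytometry summarised as a weighted list of Gaussian components."""

    components: list[GaussianComponent]
    id: str = ""

    def __post_init__(self) -> None:
        if not self.components:
            raise CytometryError("mixture needs at least one component")
        d = self.components[0].dim
        if any(c.dim != d for c in self.components):
            raise DimensionMismatchError("components must share a dimension")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise CytometryError(f"component weights sum to {total}, not 1")

    @property
    def dim(self) -> int:
        return self.components[0].dim

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def labels(self) -> list[str | None]:
        return [c.label for c in self.components]

    @property
    def n_components(self) -> int:
        return len(self.components)


def summarize(
    gated: GatedCytometry,
    min_points: int | None = None,
    ridge: float = 1e-6,
) -> MixtureClustering:
    """Summarise a gated cytometry as one Gaussian component per cell type.

    Each component's mean and covariance are the empirical moments of the
    events sharing that label (covariance with the unbiased ``n_k - 1``
    denominator); its weight is the label's empirical proportion ``n_k / n``.
    Components appear in first-appearance order of their labels.

    A scaled ridge ``ridge * (trace / d) * I`` (or ``ridge * I`` if the trace
    is zero) is added whenever a label has at most ``min_points`` events
    (default ``d + 1``) or the raw covariance is not positive definite, so the
    SPD invariant holds even for singleton cell types.
    """
    X = gated.events.values
    n, d = X.shape
    if min_points is None:
        min_points = d + 1
    if ridge < 0:
        raise CytometryError("ridge must be nonnegative")
    components = []
    for lab in gated.label_set:
        mask = gated.labels == lab
        pts = X[mask]
        n_k = pts.shape[0]
        mean = pts.mean(axis=0)
        if n_k > 1:
            cov = np.cov(pts, rowvar=False).reshape(d, d)
        else:
            cov = np.zeros((d, d))
        needs_ridge = n_k <= min_points or _min_eig(cov) <= 0.0
        if needs_ridge:
            tr = np.trace(cov)
            scale = tr / d if tr > 0 else 1.0
            cov = cov + ridge * scale * np.eye(d)
        components.append(
            GaussianComponent(mean=mean, cov=cov, weight=n_k / n, label=lab)
        )
    return MixtureClustering(components=components, id=gated.id)


def _min_eig(cov: np.ndarray) -> float:
    return float(np.linalg.eigvalsh((cov + cov.T) / 2.0)[0])
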