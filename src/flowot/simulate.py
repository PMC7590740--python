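"""Synthetic cytometry databases with controlled sources of variability.

The generator emulates the structure of a real multi-centre collection:
a small number of generative *conditions* (groups), each a mixture of
well-separated Gaussian cell types; per-individual mean shifts (biological
variability); per-cytometry diagonal affine distortions (technical
variability); Dirichlet-resampled cell-type proportions; optionally a
missing cell type; and a configurable fraction of uniform background events
labelled ``outlier``.  Everything is driven by a single seed and is
reproducible bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import EventTable, GatedCytometry


@dataclass
class SynthConfig:
    """Study conditions for the synthetic database.

    Default scales: cell-type means at pairwise distance >= ``separation``
    (unit-order covariances), group bases displaced by ``between_group_shift``
    per cell type, individual means jittered with sd ``within_group_jitter``,
    and per-cytometry axis scalings of sd ``tech_scale_jitter`` around 1.
    """

    n_groups: int = 3
    cytometries_per_group: int = 5
    n_cell_types: int = 4
    dim: int = 2
    events_per_cytometry: int = 1000
    separation: float = 8.0
    between_group_shift: float = 6.0
    within_group_jitter: float = 0.3
    tech_scale_jitter: float = 0.02
    proportion_concentration: float = 50.0
    outlier_frac: float = 0.05
    missing_type_prob: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cell_types < 1 or self.n_groups < 1:
            raise ValueError("need at least one group and one cell type")
        if not (0.0 <= self.outlier_frac < 0.5):
            raise ValueError("outlier_frac must be in [0, 0.5)")
        for name in ("separation", "between_group_shift", "within_group_jitter",
                     "tech_scale_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.within_group_jitter > 0 and self.separation < 3 * self.within_group_jitter:
            warnings.warn(
                "cell-type separation below 3x the within-group jitter; "
                "groups may be unrecoverable",
                RuntimeWarning,
                stacklevel=2,
            )


@dataclass
class GroupParams:
    """Ground-truth mixture of one generative condition."""

    means: np.ndarray  # (K, d)
    covs: np.ndarray  # (K, d, d)
    proportions: np.ndarray  # (K,)
    labels: list[str] = field(default_factory=list)


def _separated_means(rng: np.random.Generator, k: int, d: int, sep: float) -> np.ndarray:
    """k points with pairwise distance >= sep: jittered scaled lattice."""
    side = int(np.ceil(k ** (1.0 / min(d, 3))))
    pts = []
    # lattice in the first min(d, 3) axes, spacing 1.5*sep for slack
    for idx in range(k):
        coord = np.zeros(d)
        rem = idx
        for axis in range(min(d, 3)):
            coord[axis] = rem % side
            rem //= side
        pts.append(coord * 1.5 * sep)
    pts = np.array(pts)
    pts += rng.normal(scale=0.1 * sep, size=pts.shape)
    # center at the origin so the multiplicative technical distortion acts on
    # deviations of comparable magnitude for every cell type
    return pts - pts.mean(axis=0)


def _random_spd(rng: np.random.Generator, d: int) -> np.ndarray:
    """Unit-scale SPD covariance with eigenvalues in roughly [0.5, 2]."""
    q, _ = np.linalg.qr(rng.normal(size=(d, d)))
    eigs = rng.uniform(0.5, 2.0, size=d)
    return (q * eigs) @ q.T


def _make_group_params(rng: np.random.Generator, config: SynthConfig) -> list[GroupParams]:
    K, d = config.n_cell_types, config.dim
    base_means = _separated_means(rng, K, d, config.separation)
    labels = [f"ct{k + 1}" for k in range(K)]
    groups = []
    for _ in range(config.n_groups):
        shift_dirs = rng.normal(size=(K, d))
        norms = np.linalg.norm(shift_dirs, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        means = base_means + config.between_group_shift * shift_dirs / norms
        covs = np.stack([_random_spd(rng, d) for _ in range(K)])
        props = rng.dirichlet(np.full(K, 10.0))
        groups.append(
            GroupParams(means=means, covs=covs, proportions=props, labels=list(labels))
        )
    return groups


def _draw_cytometry(
    rng: np.random.Generator,
    group: GroupParams,
    config: SynthConfig,
    sample_id: str,
) -> tuple[GatedCytometry, dict]:
    K, d = group.means.shape
    n = config.events_per_cytometry
    if n < 1:
        raise ValueError("events_per_cytometry must be at least 1")
    # biological variability: per-individual mean shift per cell type
    indiv_means = group.means + rng.normal(
        scale=config.within_group_jitter, size=(K, d)
    )
    # technical variability: per-cytometry diagonal affine distortion
    scale = 1.0 + rng.normal(scale=config.tech_scale_jitter, size=d)
    # biological variability in composition
    props = rng.dirichlet(config.proportion_concentration * group.proportions)
    present = np.ones(K, dtype=bool)
    if K > 1 and rng.uniform() < config.missing_type_prob:
        present[rng.integers(K)] = False
        props = np.where(present, props, 0.0)
        props = props / props.sum()
    n_outliers = int(round(config.outlier_frac * n))
    n_signal = n - n_outliers
    counts = rng.multinomial(n_signal, props)
    events = []
    labels = []
    for k in range(K):
        if counts[k] == 0:
            continue
        x = rng.multivariate_normal(indiv_means[k], group.covs[k], size=counts[k])
        events.append(x)
        labels.extend([group.labels[k]] * counts[k])
    signal = np.vstack(events) if events else np.empty((0, d))
    if n_outliers > 0:
        lo = signal.min(axis=0) if len(signal) else -np.ones(d)
        hi = signal.max(axis=0) if len(signal) else np.ones(d)
        span = hi - lo
        out = rng.uniform(lo - 0.25 * span, hi + 0.25 * span, size=(n_outliers, d))
        all_events = np.vstack([signal, out])
        labels.extend(["outlier"] * n_outliers)
    else:
        all_events = signal
    all_events = all_events * scale  # the affine distortion hits every event
    perm = rng.permutation(len(all_events))
    all_events = all_events[perm]
    labels = np.asarray(labels, dtype=object)[perm]
    markers = [f"M{i + 1}" for i in range(d)]
    gated = GatedCytometry(
        events=EventTable(values=all_events, markers=markers, id=sample_id),
        labels=labels,
    )
    truth = {
        "individual_means": indiv_means,
        "scale": scale,
        "proportions": props,
        "counts": counts,
        "present": present,
    }
    return gated, truth


def generate_database(
    config: SynthConfig,
) -> tuple[list[GatedCytometry], np.ndarray, dict]:
    """Generate a gated database of ``n_groups * cytometries_per_group`` samples.

    Returns ``(cytometries, group_index, params)`` where ``params`` holds the
    ground-truth group mixtures and per-cytometry realisations, enough for
    parameter-recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    groups = _make_group_params(rng, config)
    cytometries = []
    membership = []
    realised = []
    for g, gp in enumerate(groups):
        for r in range(config.cytometries_per_group):
            sample_id = f"g{g + 1}s{r + 1}"
            gated, truth = _draw_cytometry(rng, gp, config, sample_id)
            cytometries.append(gated)
            membership.append(g)
            realised.append(truth)
    params = {"groups": groups, "realised": realised, "config": config}
    return cytometries, np.asarray(membership), params


def generate_target(
    params: dict,
    group: int,
    config: SynthConfig | None = None,
    seed: int | None = None,
) -> tuple[EventTable, np.ndarray]:
    """Draw one fresh cytometry from a known group, labels held out.

    Returns the unlabelled :class:`EventTable` (what a classifier sees) and
    the withheld truth labels, in event order.
    """
    groups = params["groups"]
    if not (0 <= group < len(groups)):
        raise ValueError(f"group {group} does not exist")
    config = config or params["config"]
    rng = np.random.default_rng(seed)
    gated, _ = _draw_cytometry(rng, groups[group], config, "target")
    return gated.events, gated.labels
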