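"""Clustering evaluation: F-measure, median F-measure, per-label reports.

The F-measure scores a predicted partition against a reference partition of
the same events: each reference cluster contributes, weighted by its size,
the best harmonic mean of recall and precision over all predicted clusters.
The median F-measure compares label-matched cluster pairs only (labels
missing on one side score 0) and takes the median, so small but diagnostic
cell types count as much as dominant ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _clusters(labels: np.ndarray) -> dict[str, np.ndarray]:
    labels = np.asarray(labels, dtype=object)
    out: dict[str, np.ndarray] = {}
    for lab in labels:
        if lab not in out:
            out[lab] = None
    for lab in out:
        out[lab] = np.flatnonzero(labels == lab)
    return out


def cluster_recall(ref_idx: np.ndarray, pred_idx: np.ndarray) -> float:
    """Recall |ref ∩ pred| / |ref|, with R(∅, ·) = 1 and R(·, ∅) = 0."""
    if len(ref_idx) == 0:
        return 1.0
    if len(pred_idx) == 0:
        return 0.0
    return len(np.intersect1d(ref_idx, pred_idx, assume_unique=True)) / len(ref_idx)


def cluster_precision(ref_idx: np.ndarray, pred_idx: np.ndarray) -> float:
    """Precision |ref ∩ pred| / |pred|, with P(·, ∅) = 1 and P(∅, ·) = 0."""
    if len(pred_idx) == 0:
        return 1.0
    if len(ref_idx) == 0:
        return 0.0
    return len(np.intersect1d(ref_idx, pred_idx, assume_unique=True)) / len(pred_idx)


def cluster_f(ref_idx: np.ndarray, pred_idx: np.ndarray) -> float:
    """Harmonic mean of recall and precision for one cluster pair."""
    r = cluster_recall(ref_idx, pred_idx)
    p = cluster_precision(ref_idx, pred_idx)
    if r + p == 0:
        return 0.0
    return 2.0 * r * p / (r + p)


def f_measure(truth: np.ndarray, pred: np.ndarray) -> float:
    """Size-weighted best-match F-measure of ``pred`` against ``truth``.

    ``sum_k (|C_k| / M) max_l F(C_k, C'_l)`` over the reference clusters.
    Invariant under renaming of predicted clusters.
    """
    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction must label the same events")
    M = len(truth)
    ref = _clusters(truth)
    hyp = _clusters(pred)
    total = 0.0
    for ref_idx in ref.values():
        best = max(cluster_f(ref_idx, p_idx) for p_idx in hyp.values())
        total += len(ref_idx) / M * best
    return total


def median_f_measure(truth: np.ndarray, pred: np.ndarray) -> float:
    """Median of label-matched per-cluster F values.

    Clusters are paired by equal label; every label present on only one side
    contributes a 0.  Ties at an even count take the mean of the two central
    values.
    """
    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction must label the same events")
    ref = _clusters(truth)
    hyp = _clusters(pred)
    shared = [lab for lab in ref if lab in hyp]
    only = [lab for lab in ref if lab not in hyp]
    only += [lab for lab in hyp if lab not in ref]
    values = [cluster_f(ref[lab], hyp[lab]) for lab in shared]
    values += [0.0] * len(only)
    if not values:
        raise ValueError("no labels to compare")
    return float(np.median(values))


def per_label_report(truth: np.ndarray, pred: np.ndarray) -> pd.DataFrame:
    """Per-label F, precision and recall of the equal-label cluster pairs.

    Labels present on only one side get a (0, 0, 0) row.
    """
    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction must label the same events")
    ref = _clusters(truth)
    hyp = _clusters(pred)
    rows = []
    empty = np.array([], dtype=int)
    all_labels = list(ref) + [lab for lab in hyp if lab not in ref]
    for lab in all_labels:
        r_idx = ref.get(lab, empty)
        p_idx = hyp.get(lab, empty)
        if lab in ref and lab in hyp:
            rows.append(
                (
                    lab,
                    cluster_f(r_idx, p_idx),
                    cluster_precision(r_idx, p_idx),
                    cluster_recall(r_idx, p_idx),
                )
            )
        else:
            rows.append((lab, 0.0, 0.0, 0.0))
    return pd.DataFrame(rows, columns=["label", "F", "precision", "recall"])
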