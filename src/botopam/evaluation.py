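"""Segment scoring (Q75), precision-recall evaluation and threshold choice.

The classifier emits 16 scores per class per 5-s segment.  The segment-level
score, Q75, is the mean of the values lying between the 75th and 100th
percentile — for 16 values, the mean of the top 4.  Target sounds repeat
within a segment (click trains, rain, engine throb), so pooling several high
columns suppresses single-column spurious peaks.

Precision-recall machinery follows the step-curve convention: thresholds are
the ascending unique scores, predicted-positive means score >= threshold,
and with T thresholds the boundary terms TPR(T) = 0, PPV(T) = 1 close the
curve.  Average precision is the step sum
``AP = sum_t [TPR(t) - TPR(t+1)] * PPV(t)``; micro mAP pools all classes'
decisions into one curve.  The operating threshold is chosen where precision
and recall are equal (minimum |PPV - TPR|, ties toward the higher
threshold).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

Q75_FRACTION = 0.25


def q75_summarize(raw: np.ndarray, fraction: float = Q75_FRACTION) -> float:
    """Mean of the top ``ceil(n * fraction)`` values of ``raw``.

    For the classifier's 16 columns and the default fraction this is the
    mean of the 4 largest scores (the values between the 75th and 100th
    percentile, boundary included).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size == 0:
        raise ValueError("q75_summarize expects a non-empty 1-D array")
    if not np.all(np.isfinite(raw)):
        raise ValueError("q75_summarize expects finite values")
    k = math.ceil(raw.size * fraction)
    top = np.sort(raw)[-k:]
    return float(top.mean())


def q75_scores(per_column: np.ndarray, fraction: float = Q75_FRACTION) -> np.ndarray:
    """Vectorized Q75 over ``(n_segments, 16, n_classes)`` score arrays."""
    arr = np.asarray(per_column, dtype=float)
    k = math.ceil(arr.shape[1] * fraction)
    top = np.sort(arr, axis=1)[:, -k:, :]
    return top.mean(axis=1)


@dataclass
class PRCurve:
    """Precision/recall per ascending threshold, with closing boundary terms.

    ``thresholds`` holds the T ascending unique scores; ``ppv`` and ``tpr``
    have length T + 1, the final entries being the convention PPV(T) = 1,
    TPR(T) = 0.
    """

    thresholds: np.ndarray
    ppv: np.ndarray
    tpr: np.ndarray
    class_name: str = ""

    def __post_init__(self) -> None:
        if len(self.ppv) != len(self.thresholds) + 1:
            raise ValueError("ppv/tpr must include the closing boundary term")
        if np.any(np.diff(self.tpr) > 1e-12):
            raise ValueError("TPR must be non-increasing in the threshold")


def pr_curve(labels: np.ndarray, scores: np.ndarray, class_name: str = "") -> PRCurve:
    """Precision-recall curve over the ascending unique scores.

    A segment is predicted positive when its score is >= the threshold
    (closed lower bound, the convention used throughout the package).
    Requires at least one positive label, otherwise recall is undefined.
    """
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-D arrays")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("pr_curve needs at least one positive label")

    order = np.argsort(scores, kind="mergesort")[::-1]  # descending scores
    sorted_scores = scores[order]
    tp_cum = np.cumsum(labels[order])
    pred_cum = np.arange(1, len(scores) + 1)
    # last index of each distinct score value in the descending ordering
    # gives the confusion counts for "score >= that value"
    is_last = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    uniq_desc = sorted_scores[is_last]
    tp = tp_cum[is_last].astype(float)
    pred = pred_cum[is_last].astype(float)
    ppv = tp / pred
    tpr = tp / n_pos
    # ascending thresholds => reverse; then TPR is non-increasing
    thresholds = uniq_desc[::-1]
    ppv = np.r_[ppv[::-1], 1.0]
    tpr = np.r_[tpr[::-1], 0.0]
    return PRCurve(thresholds=thresholds, ppv=ppv, tpr=tpr, class_name=class_name)


def average_precision(curve: PRCurve) -> float:
    """Step-sum AP: ``sum_t [TPR(t) - TPR(t+1)] * PPV(t)`` over T thresholds."""
    tpr, ppv = curve.tpr, curve.ppv
    ap = float(np.sum((tpr[:-1] - tpr[1:]) * ppv[:-1]))
    return ap


def micro_map(labels_per_class: dict, scores_per_class: dict) -> float:
    """Micro-averaged mAP: pool every class's decisions into one PR curve."""
    if not labels_per_class:
        raise ValueError("micro_map needs at least one class")
    labels = np.concatenate([np.asarray(labels_per_class[c]) for c in sorted(labels_per_class)])
    scores = np.concatenate([np.asarray(scores_per_class[c]) for c in sorted(labels_per_class)])
    return average_precision(pr_curve(labels, scores, class_name="micro"))


def select_threshold(curve: PRCurve) -> float:
    """Operating point where precision equals recall.

    Returns the threshold minimizing |PPV(t) - TPR(t)| over the curve's real
    thresholds (the boundary term is not a decision point); ties break
    toward the higher threshold.
    """
    if len(curve.thresholds) == 0:
        raise ValueError("cannot select a threshold from an empty curve")
    gap = np.abs(curve.ppv[:-1] - curve.tpr[:-1])
    best = np.flatnonzero(gap == gap.min())[-1]  # ascending: last == highest
    return float(curve.thresholds[best])


def tpr_tnr_at(
    labels: np.ndarray,
    scores: np.ndarray,
    threshold: float,
    n_sample: int = 60,
    seed: int = 0,
    stratify: tuple[int, int] | None = None,
) -> tuple[float | None, float | None]:
    """TPR and TNR on a random validation sample at a decision threshold.

    ``n_sample`` segments are drawn stratified between predicted positives
    and predicted negatives (default half/half, i.e. 30/30 for the standard
    60-segment check); a stratum smaller than requested is taken whole with
    a warning.  Returns ``(TPR, TNR)`` computed from the sampled true
    labels; a rate whose denominator is empty is returned as ``None``.
    """
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    pred_pos = scores >= threshold
    if stratify is None:
        stratify = (n_sample // 2, n_sample - n_sample // 2)
    rng = np.random.default_rng(seed)

    chosen = []
    for want, mask in zip(stratify, (pred_pos, ~pred_pos)):
        idx = np.flatnonzero(mask)
        if len(idx) < want:
            warnings.warn(
                f"stratum has {len(idx)} segments, fewer than the requested "
                f"{want}; using all of them",
                stacklevel=2,
            )
            chosen.append(idx)
        else:
            chosen.append(rng.choice(idx, size=want, replace=False))
    sample = np.concatenate(chosen)

    y = labels[sample]
    p = pred_pos[sample]
    tp = int(np.sum(y & p))
    fn = int(np.sum(y & ~p))
    tn = int(np.sum(~y & ~p))
    fp = int(np.sum(~y & p))
    tpr = tp / (tp + fn) if (tp + fn) else None
    tnr = tn / (tn + fp) if (tn + fp) else None
    if tpr is None or tnr is None:
        warnings.warn("degenerate validation sample: a rate is undefined", stacklevel=2)
    return tpr, tnr


@dataclass
class EvalReport:
    """Per-class AP, micro mAP and per-site operating-point rates."""

    ap_per_class: dict
    micro_map: float
    thresholds: dict = field(default_factory=dict)
    site_rates: dict = field(default_factory=dict)  # (site, class) -> {tpr, tnr}

    def to_dict(self) -> dict:
        return {
            "ap_per_class": self.ap_per_class,
            "micro_map": self.micro_map,
            "thresholds": self.thresholds,
            "site_rates": {f"{s}/{c}": v for (s, c), v in self.site_rates.items()},
        }


def evaluate_scores(
    labels_per_class: dict, scores_per_class: dict
) -> EvalReport:
    """Full evaluation: per-class PR/AP, micro mAP and PPV=TPR thresholds."""
    ap = {}
    thresholds = {}
    for c in sorted(labels_per_class):
        curve = pr_curve(labels_per_class[c], scores_per_class[c], class_name=c)
        ap[c] = average_precision(curve)
        thresholds[c] = select_threshold(curve)
    return EvalReport(
        ap_per_class=ap,
        micro_map=micro_map(labels_per_class, scores_per_class),
        thresholds=thresholds,
    )
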