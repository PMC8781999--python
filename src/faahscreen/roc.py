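"""Receiver-operating-characteristic utilities shared across the pipeline.

The AUC is computed by the Mann-Whitney rank statistic; ties between a
positive and a negative score count half. A brute-force pairwise concordance
count gives the identical value and serves as the independent check in the
test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

log = logging.getLogger(__name__)


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if not (labels == 1).any() or not (labels == 0).any():
        raise ValueError("both classes must be present")
    return scores, labels


def rank_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney U) statistic."""
    scores, labels = _as_arrays(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # average ranks handle ties -> half credit
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def sens_spec_at(scores, labels, threshold: float, strict: bool = True):
    """Sensitivity/specificity classifying positive iff score > threshold.

    With ``strict=False`` the rule is score >= threshold.
    """
    scores, labels = _as_arrays(scores, labels)
    calls = scores > threshold if strict else scores >= threshold
    sens = float(calls[labels == 1].mean())
    spec = float((~calls[labels == 0]).mean())
    return sens, spec


@dataclass(frozen=True)
class ThresholdReport:
    threshold: float
    sensitivity: float
    specificity: float
    auc: float


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores, plus outer sentinels."""
    unique = np.unique(scores)
    mids = (unique[:-1] + unique[1:]) / 2.0
    return np.concatenate(([unique[0] - 1.0], mids, [unique[-1] + 1.0]))


def threshold_at_sensitivity(
    scores, labels, target_sensitivity: float = 0.9
) -> ThresholdReport:
    """Largest threshold keeping sensitivity at or above a target.

    Classification is strict (positive iff score > threshold); candidate
    thresholds are midpoints between consecutive distinct pooled scores.
    If even the lowest threshold cannot reach the target (only possible for
    targets of exactly 1.0 broken by the convention below, or degenerate
    inputs), the threshold just below the minimum positive score is
    returned with a warning.
    """
    scores, labels = _as_arrays(scores, labels)
    auc = rank_auc(scores, labels)
    best = None
    for t in _candidate_thresholds(scores):
        sens, spec = sens_spec_at(scores, labels, t)
        if sens >= target_sensitivity and (best is None or t > best.threshold):
            best = ThresholdReport(float(t), sens, spec, auc)
    if best is None:
        t = float(scores[labels == 1].min()) - 1e-9
        sens, spec = sens_spec_at(scores, labels, t)
        log.warning(
            "target sensitivity %.3f unreachable; falling back to threshold %.6g",
            target_sensitivity, t,
        )
        best = ThresholdReport(t, sens, spec, auc)
    return best


def youden_cutoff(
    scores, labels, min_sens: float = 0.0, min_spec: float = 0.0
) -> ThresholdReport | None:
    """Cutoff maximizing sensitivity+specificity subject to floor constraints.

    Classification is score >= cutoff (the flag-transform convention).
    Returns ``None`` when no candidate satisfies both floors.
    """
    scores, labels = _as_arrays(scores, labels)
    auc = rank_auc(scores, labels)
    best = None
    for t in _candidate_thresholds(scores):
        sens, spec = sens_spec_at(scores, labels, t, strict=False)
        if sens < min_sens or spec < min_spec:
            continue
        if best is None or sens + spec > best.sensitivity + best.specificity:
            best = ThresholdReport(float(t), sens, spec, auc)
    return best
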