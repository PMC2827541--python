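"""Masking experiments and ranking metrics.

Evaluation follows an out-of-bag masking design: a stratified sample of the
annotated proteins is relabeled UNKNOWN (preserving the positive:negative
ratio), the method under test predicts posterior probabilities for them, and
the masked proteins form the test set.  Originally-unannotated proteins are
never masked (they have no ground truth) but stay in the network.

Metrics: AUC by the Mann-Whitney pair-counting identity (ties count one
half), the full ROC curve by a descending threshold sweep, and the
(non-interpolated) precision at the smallest cutoff where recall first
reaches a target, by default 20% ("PR20R").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .network_io import NEG, POS, UNKNOWN

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


class UndefinedMetricError(ValueError):
    """The test set lacks one of the two classes."""


@dataclass
class MaskedExperiment:
    """A label vector with part of the annotation hidden, plus the truth."""

    working_labels: np.ndarray
    test_set: list[tuple[int, int]]  # (node index, true state POS/NEG)
    seed: int


@dataclass
class EvaluationResult:
    auc: float
    roc_points: list[tuple[float, float]]
    pr20r: float
    n_pos: int
    n_neg: int


def stratified_mask(
    labels: np.ndarray, n_mask: int, seed: int
) -> MaskedExperiment:
    """Hide ``n_mask`` annotated labels, stratified by label state.

    Sampling is without replacement within each stratum, with quotas
    proportional to the stratum sizes (largest-remainder rounding), so the
    POS:NEG ratio of the masked set matches the annotated ratio to within
    rounding.  Deterministic given *seed*.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == POS)
    neg_idx = np.flatnonzero(labels == NEG)
    n_ann = pos_idx.size + neg_idx.size
    if n_mask > n_ann:
        raise ValueError(f"n_mask={n_mask} exceeds {n_ann} annotated nodes")
    quota_pos_exact = n_mask * pos_idx.size / n_ann if n_ann else 0.0
    quota_pos = int(np.floor(quota_pos_exact))
    quota_neg = n_mask - quota_pos
    # largest-remainder: give the leftover unit to the stratum it came from
    if quota_neg > neg_idx.size:
        quota_pos += quota_neg - neg_idx.size
        quota_neg = neg_idx.size
    if quota_pos > pos_idx.size:
        logger.warning("POS stratum smaller than its quota; shrinking")
        quota_neg += quota_pos - pos_idx.size
        quota_pos = pos_idx.size
    masked_pos = rng.choice(pos_idx, size=quota_pos, replace=False)
    masked_neg = rng.choice(neg_idx, size=quota_neg, replace=False)
    working = labels.copy()
    test_set: list[tuple[int, int]] = []
    for i in np.sort(np.concatenate([masked_pos, masked_neg])):
        test_set.append((int(i), int(labels[i])))
        working[i] = UNKNOWN
    return MaskedExperiment(working_labels=working, test_set=test_set, seed=seed)


def _scores_and_truth(scores, test_set):
    y = np.array([true for _, true in test_set], dtype=int)
    if isinstance(scores, dict):
        s = np.array([scores[node] for node, _ in test_set], dtype=float)
    else:
        s = np.array([scores[node] for node, _ in test_set], dtype=float)
    return s, y


def mann_whitney_auc(s: np.ndarray, y: np.ndarray) -> float:
    """P(random positive outscores random negative), ties counting one half."""
    n_pos = int(np.sum(y == POS))
    n_neg = y.size - n_pos
    ranks = rankdata(s)  # midranks handle ties
    r_pos = float(np.sum(ranks[y == POS]))
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def roc_points(s: np.ndarray, y: np.ndarray) -> list[tuple[float, float]]:
    """ROC curve by sweeping all distinct score thresholds, (0,0) to (1,1)."""
    n_pos = int(np.sum(y == POS))
    n_neg = y.size - n_pos
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = s.size
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            tp += int(y_sorted[j] == POS)
            fp += int(y_sorted[j] != POS)
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return points


def roc_auc(scores, test_set) -> EvaluationResult:
    """AUC + ROC + PR20R for a masked test set.

    *scores* maps node (index or identifier, matching the test set's first
    elements) to a real score; higher means more likely positive.
    """
    s, y = _scores_and_truth(scores, test_set)
    n_pos = int(np.sum(y == POS))
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("test set needs both a positive and a negative")
    auc = mann_whitney_auc(s, y)
    return EvaluationResult(
        auc=auc,
        roc_points=roc_points(s, y),
        pr20r=precision_at_recall(scores, test_set, 0.20),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def precision_at_recall(scores, test_set, recall_target: float = 0.20) -> float:
    """Precision at the smallest cutoff where recall first reaches the target.

    The score axis is swept in descending order; all items tied at the cutoff
    are included.  Non-interpolated.
    """
    if not (0.0 < recall_target <= 1.0):
        raise ConfigurationError("recall_target must be in (0, 1]")
    s, y = _scores_and_truth(scores, test_set)
    n_pos = int(np.sum(y == POS))
    if n_pos == 0:
        raise UndefinedMetricError("test set has no positives")
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    tp = retrieved = 0
    i = 0
    n = s.size
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            tp += int(y_sorted[j] == POS)
            retrieved += 1
            j += 1
        if tp / n_pos >= recall_target:
            return tp / retrieved
        i = j
    return tp / retrieved  # recall target unreachable only if target > 1
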