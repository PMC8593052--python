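"""Discrimination and calibration metrics for imbalanced binary risk models.

The class-imbalance-aware pieces are the stratified Brier score (mean squared
probability error computed separately within the positive and the negative
class, reported x100) and the average calibration error (ACE): predicted
probabilities are discretized into equal-width bins, the absolute gap between
observed event fraction and mean predicted probability is computed per
non-empty bin, and the gaps are combined by an unweighted average, so sparse
high-probability bins weigh as much as the crowded low-probability ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass(frozen=True)
class CalibrationBins:
    """Equal-width, right-closed probability bins (a, b] over [0, 1];
    probability 0 falls in the first bin."""

    n_bins: int = 10

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_bins + 1)

    def assign(self, probs: np.ndarray) -> np.ndarray:
        probs = np.asarray(probs, dtype=float)
        idx = np.searchsorted(self.edges, probs, side="left") - 1
        return np.clip(idx, 0, self.n_bins - 1)


def _check(labels, probs) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if labels.shape != probs.shape:
        raise ValueError("labels and probs must have equal length")
    if len(labels) == 0:
        raise ValueError("empty input")
    if np.any((probs < 0) | (probs > 1)) or not np.isfinite(probs).all():
        raise ValueError("probabilities must lie in [0, 1]")
    if np.any((labels != 0) & (labels != 1)):
        raise ValueError("labels must be binary")
    return labels, probs


def stratified_brier(labels, probs) -> tuple[float, float]:
    """Per-class Brier scores x100: (positive class, negative class).

    An absent class yields NaN for its score.  The overall Brier score is the
    prevalence-weighted combination of the two.
    """
    labels, probs = _check(labels, probs)
    pos = labels == 1
    brier_pos = float(np.mean((1.0 - probs[pos]) ** 2) * 100.0) if pos.any() else float("nan")
    neg = ~pos
    brier_neg = float(np.mean(probs[neg] ** 2) * 100.0) if neg.any() else float("nan")
    return brier_pos, brier_neg


def ace(labels, probs, bins: CalibrationBins = CalibrationBins()) -> float:
    """Average calibration error in percent (unweighted over non-empty bins)."""
    labels, probs = _check(labels, probs)
    idx = bins.assign(probs)
    gaps = []
    for b in range(bins.n_bins):
        sel = idx == b
        if not sel.any():
            continue
        gaps.append(abs(labels[sel].mean() - probs[sel].mean()))
    return float(np.mean(gaps) * 100.0)


def discrimination(labels, probs) -> tuple[float, float]:
    """(AUROC, AUPRC).  AUROC uses the midrank tie convention; AUPRC is the
    step-integrated precision-recall curve.  Raises on single-class input."""
    labels, probs = _check(labels, probs)
    if labels.min() == labels.max():
        raise ValueError("discrimination undefined for single-class labels")
    return float(roc_auc_score(labels, probs)), float(average_precision_score(labels, probs))


@dataclass(frozen=True)
class FoldSummary:
    mean: float
    ci_low: float
    ci_high: float
    values: tuple[float, ...]


def summarize_folds(values) -> FoldSummary:
    """Mean and 95% t-interval (k-1 df) over per-fold metric values."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 fold values to summarize")
    k = len(values)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    half = float(stats.t.ppf(0.975, k - 1) * sd / np.sqrt(k))
    return FoldSummary(mean, mean - half, mean + half, tuple(values.tolist()))
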