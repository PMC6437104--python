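"""Diagnostic evaluation battery for the trained classifiers.

Covers the full reporting chain: confusion matrices with row-percent
views, validity metrics (accuracy, sensitivity, effectiveness — i.e.
specificity — and precision), network performance metrics (MSE, NMSE,
Pearson r, % error) with the AIC/MDL model-selection scores, ROC curves,
and the input-sensitivity analysis that ranks input channels by how much
they move the network output.

Naming note: "effectiveness" is the true-negative rate (specificity); the
term is kept because it is the established one in this screening
literature, and the implementation is the numeric reading that makes the
published confusion-matrix and validity tables consistent.

AIC/MDL follow the classic neural-network conventions:

    AIC = n ln(MSE) + 2k        MDL = n ln(MSE) + (k/2) ln(n)

with k the total count of trainable weights and biases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.metrics import auc as _sk_auc, roc_curve as _sk_roc_curve

from .acoustic_features import FeatureMatrix
from .neural_models import predict_class

__all__ = [
    "ConfusionMatrix",
    "ValidityReport",
    "PerformanceReport",
    "ROCResult",
    "SensitivityReport",
    "EvalReport",
    "confusion",
    "validity_metrics",
    "performance_metrics",
    "roc",
    "input_sensitivity",
    "evaluate_network",
]


# ---------------------------------------------------------------------------
# Confusion matrix and validity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; depression (+1) is the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def row_percent(self) -> Dict[str, Tuple[float, float]]:
        """Per observed class: (% predicted depression, % predicted control)."""
        out: Dict[str, Tuple[float, float]] = {}
        dep = self.tp + self.fn
        out["depression_observed"] = (
            (100.0 * self.tp / dep, 100.0 * self.fn / dep) if dep else (0.0, 0.0))
        ctl = self.fp + self.tn
        out["controls_observed"] = (
            (100.0 * self.fp / ctl, 100.0 * self.tn / ctl) if ctl else (0.0, 0.0))
        return out


def confusion(labels_true: Sequence[float], labels_pred: Sequence[float]
              ) -> ConfusionMatrix:
    yt = np.asarray(labels_true, dtype=np.float64)
    yp = np.asarray(labels_pred, dtype=np.float64)
    if yt.size == 0:
        raise ValueError("confusion of empty label vectors")
    if yt.shape != yp.shape:
        raise ValueError("label vectors must have equal length")
    for v in (yt, yp):
        if not np.isin(v, [-1.0, 1.0]).all():
            raise ValueError("labels must be +1/-1")
    return ConfusionMatrix(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == -1))),
        fp=int(np.sum((yt == -1) & (yp == 1))),
        tn=int(np.sum((yt == -1) & (yp == -1))),
    )


@dataclass(frozen=True)
class ValidityReport:
    accuracy: float
    sensitivity: Optional[float]   # tp / (tp + fn); None if no positives
    effectiveness: Optional[float]  # specificity tn / (tn + fp); None if no negatives
    precision: Optional[float]      # tp / (tp + fp); None if nothing predicted positive
    flags: Tuple[str, ...] = ()


def validity_metrics(cm: ConfusionMatrix) -> ValidityReport:
    """Accuracy, sensitivity, effectiveness (specificity), precision.

    Undefined ratios (empty denominators) come back as None with a flag —
    they are never silently NaN-propagated.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    flags: List[str] = []
    accuracy = (cm.tp + cm.tn) / cm.n
    sensitivity = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else None
    if sensitivity is None:
        flags.append("sensitivity_undefined")
    effectiveness = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else None
    if effectiveness is None:
        flags.append("effectiveness_undefined")
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) else None
    if precision is None:
        flags.append("precision_undefined")
    return ValidityReport(accuracy=accuracy, sensitivity=sensitivity,
                          effectiveness=effectiveness, precision=precision,
                          flags=tuple(flags))


# ---------------------------------------------------------------------------
# Performance and model selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerformanceReport:
    mse: float
    nmse: Optional[float]
    r: Optional[float]
    pct_error: float
    aic: float
    mdl: float
    n_parameters: int
    flags: Tuple[str, ...] = ()


def performance_metrics(scores: Sequence[float], targets: Sequence[float],
                        model, threshold: float = 0.0) -> PerformanceReport:
    """MSE, NMSE, Pearson r, % error, AIC and MDL for a trained network.

    ``model`` supplies the trainable-parameter count k.  MSE = 0 makes the
    log-based AIC/MDL degenerate (-inf, flagged).
    """
    s = np.asarray(scores, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if s.shape != t.shape or s.size == 0:
        raise ValueError("scores and targets must be equal-length and non-empty")
    flags: List[str] = []
    n = s.size
    k = int(model.n_parameters)
    mse = float(np.mean((s - t) ** 2))
    tvar = float(np.var(t))
    if tvar > 0:
        nmse: Optional[float] = mse / tvar
    else:
        nmse = None
        flags.append("nmse_undefined_zero_target_variance")
    if np.std(s) > 0 and np.std(t) > 0:
        r: Optional[float] = float(np.corrcoef(s, t)[0, 1])
    else:
        r = None
        flags.append("r_undefined_constant_input")
    pred = np.where(s > threshold, 1.0, -1.0)
    pct_error = float(100.0 * np.mean(pred != t))
    if mse > 0:
        aic = n * math.log(mse) + 2.0 * k
        mdl = n * math.log(mse) + 0.5 * k * math.log(n)
    else:
        aic = mdl = float("-inf")
        flags.append("aic_mdl_degenerate_zero_mse")
    return PerformanceReport(mse=mse, nmse=nmse, r=r, pct_error=pct_error,
                             aic=aic, mdl=mdl, n_parameters=k, flags=tuple(flags))


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc(scores: Sequence[float], labels_true: Sequence[float]) -> ROCResult:
    """ROC sweep over the unique scores, AUC by the trapezoid rule.

    Ties share one threshold.  Raises on single-class input — a ROC curve
    needs both depressed and control exemplars.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels_true, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s, pos_label=1, drop_intermediate=False)
    return ROCResult(thresholds=thr, tpr=tpr, fpr=fpr,
                     auc=float(_sk_auc(fpr, tpr)))


# ---------------------------------------------------------------------------
# Input sensitivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensitivityReport:
    channel_names: Tuple[str, ...]
    scores: np.ndarray       # output dispersion per channel
    ranks: np.ndarray        # rank 1 = most influential
    flags: Tuple[str, ...] = ()

    def top(self, k: int) -> List[str]:
        order = np.argsort(self.ranks)
        return [self.channel_names[i] for i in order[:k]]


def input_sensitivity(model, X_train: np.ndarray, n_steps: int = 50,
                      span_sd: float = 1.0,
                      channel_names: Optional[Sequence[str]] = None
                      ) -> SensitivityReport:
    """Which input channels move the network output the most?

    Channel j is swept over its training mean +/- ``span_sd`` standard
    deviations in ``n_steps`` equal steps while every other channel sits
    at its mean; the channel's sensitivity is the standard deviation of
    the network output along the sweep.  Channels are ranked by
    descending dispersion; constant channels get sensitivity 0, flagged.
    """
    X = np.asarray(X_train, dtype=np.float64)
    p = X.shape[1]
    names = tuple(channel_names) if channel_names else tuple(f"x{j}" for j in range(p))
    if len(names) != p:
        raise ValueError("channel_names length must match input dimensionality")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    scores = np.zeros(p)
    flags: List[str] = []
    for j in range(p):
        if sd[j] == 0:
            flags.append(f"constant_channel:{names[j]}")
            continue
        sweep = np.tile(mean, (n_steps, 1))
        sweep[:, j] = np.linspace(mean[j] - span_sd * sd[j],
                                  mean[j] + span_sd * sd[j], n_steps)
        scores[j] = float(np.std(model.forward(sweep)))
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(p, dtype=int)
    ranks[order] = np.arange(1, p + 1)
    return SensitivityReport(channel_names=names, scores=scores, ranks=ranks,
                             flags=tuple(flags))


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class LevelReport:
    confusion: ConfusionMatrix
    validity: ValidityReport
    roc: Optional[ROCResult] = None


@dataclass
class EvalReport:
    laugh: LevelReport
    subject: LevelReport
    performance: PerformanceReport


def _majority_vote(subject_ids: np.ndarray, labels: np.ndarray,
                   scores: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject prediction by majority over laughs; ties go to depression
    (screening posture: a missed patient costs more than a false alarm)."""
    subjects = np.array(sorted(set(subject_ids)))
    voted = np.empty(len(subjects))
    mean_scores = np.empty(len(subjects))
    for i, s in enumerate(subjects):
        mask = subject_ids == s
        pos = int(np.sum(labels[mask] == 1))
        neg = int(np.sum(labels[mask] == -1))
        voted[i] = 1.0 if pos >= neg else -1.0
        mean_scores[i] = float(np.mean(scores[mask]))
    return subjects, voted, mean_scores


def evaluate_network(model, test: FeatureMatrix, threshold: float = 0.0
                     ) -> EvalReport:
    """Evaluate a trained model on a (standardized) test matrix.

    Emits both reporting levels: per laugh (the network's exemplars) and
    per subject (majority vote over a subject's laughs).  The subject-level
    ROC uses the mean score per subject.
    """
    if len(test) == 0:
        raise ValueError("test matrix is empty")
    pred, scores = predict_class(model, test.X, threshold=threshold)
    cm = confusion(test.y, pred)
    laugh_roc = roc(scores, test.y) if len(np.unique(test.y)) == 2 else None
    laugh_level = LevelReport(confusion=cm, validity=validity_metrics(cm),
                              roc=laugh_roc)

    subjects, voted, mean_scores = _majority_vote(test.subject_ids, pred, scores)
    true_by_subject = np.array([test.y[test.subject_ids == s][0] for s in subjects])
    cm_s = confusion(true_by_subject, voted)
    subj_roc = (roc(mean_scores, true_by_subject)
                if len(np.unique(true_by_subject)) == 2 else None)
    subject_level = LevelReport(confusion=cm_s, validity=validity_metrics(cm_s),
                                roc=subj_roc)

    perf = performance_metrics(scores, test.y, model, threshold=threshold)
    return EvalReport(laugh=laugh_level, subject=subject_level, performance=perf)
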