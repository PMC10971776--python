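"""Classification metrics with confidence intervals.

AUC-ROC is the Mann-Whitney probability that a random binder outscores a
random non-binder (ties counted half); its 95% confidence interval uses the
DeLong structural-components variance estimator.  Sensitivity and
specificity carry Wilson score intervals; the F1 interval is a seeded
nonparametric bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "EvalReport",
    "auc_roc",
    "delong_ci",
    "classification_metrics",
    "evaluate_scores",
]


class UndefinedMetricError(ValueError):
    pass


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise UndefinedMetricError("both classes must be present")
    return scores, labels


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve, P(score+ > score-) + 0.5 P(tie)."""
    scores, labels = _validate(scores, labels)
    return float(roc_auc_score(labels, scores))


def _delong_variance(scores, labels) -> tuple[float, float]:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    tz = stats.rankdata(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # structural components: v01 over positives, v10 over negatives
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    s01 = np.var(v01, ddof=1) if m > 1 else 0.0
    s10 = np.var(v10, ddof=1) if n > 1 else 0.0
    return float(auc), float(s01 / m + s10 / n)


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong normal-approximation confidence interval for the AUC, clipped to [0,1]."""
    scores, labels = _validate(scores, labels)
    if np.sum(labels == 1) < 2 or np.sum(labels == 0) < 2:
        raise UndefinedMetricError("DeLong CI needs at least 2 members per class")
    auc, var = _delong_variance(scores, labels)
    if var <= 0.0:
        warnings.warn("degenerate DeLong variance; interval collapses to the point")
        return auc, auc
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(np.clip(auc - half, 0.0, 1.0)), float(np.clip(auc + half, 0.0, 1.0))


@dataclass
class EvalReport:
    """Evaluation metrics of a binary binding classifier."""

    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    f1: float
    f1_ci: tuple[float, float]
    confusion: dict[str, int] = field(default_factory=dict)  # tp, fp, tn, fn
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "f1": self.f1,
            "f1_ci": list(self.f1_ci),
            "confusion": self.confusion,
        }


def classification_metrics(
    scores,
    labels,
    threshold: float = 0.5,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> dict:
    """Sensitivity, specificity and F1 at a threshold, with 95% CIs.

    Proportion intervals are Wilson score intervals; the F1 interval is a
    seeded ``n_bootstrap``-replicate nonparametric bootstrap (percentiles
    2.5/97.5).
    """
    scores, labels = _validate(scores, labels)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))

    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0

    sens_ci = proportion_confint(tp, tp + fn, alpha=0.05, method="wilson")
    spec_ci = proportion_confint(tn, tn + fp, alpha=0.05, method="wilson")

    rng = np.random.default_rng(seed)
    n = len(labels)
    f1_samples = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        p, t = pred[idx], labels[idx]
        btp = np.sum((p == 1) & (t == 1))
        denom = 2 * btp + np.sum((p == 1) & (t == 0)) + np.sum((p == 0) & (t == 1))
        f1_samples.append(2 * btp / denom if denom else 0.0)
    f1_ci = tuple(np.percentile(f1_samples, [2.5, 97.5]))

    return {
        "sensitivity": float(sens),
        "sensitivity_ci": (float(sens_ci[0]), float(sens_ci[1])),
        "specificity": float(spec),
        "specificity_ci": (float(spec_ci[0]), float(spec_ci[1])),
        "f1": float(f1),
        "f1_ci": (float(f1_ci[0]), float(f1_ci[1])),
        "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    }


def evaluate_scores(scores, labels, threshold: float = 0.5, seed: int = 0) -> EvalReport:
    """Full evaluation report: AUC with DeLong CI plus thresholded metrics."""
    scores, labels = _validate(scores, labels)
    auc = auc_roc(scores, labels)
    ci = delong_ci(scores, labels)
    cm = classification_metrics(scores, labels, threshold=threshold, seed=seed)
    fpr, tpr, _ = roc_curve(labels, scores)
    return EvalReport(
        auc=auc,
        auc_ci=ci,
        sensitivity=cm["sensitivity"],
        sensitivity_ci=cm["sensitivity_ci"],
        specificity=cm["specificity"],
        specificity_ci=cm["specificity_ci"],
        f1=cm["f1"],
        f1_ci=cm["f1_ci"],
        confusion=cm["confusion"],
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
    )
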