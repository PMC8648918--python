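"""Confusion-matrix indices, ROC/AUC and optimal-cutoff estimation.

Positive class is 1 (drug target).  Degenerate denominators are flagged, not
raised: MCC falls back to 0 when its denominator vanishes, rate metrics fall
back to 0 with an ``undefined`` flag, and DOR/DP are flagged undefined when
FP*FN = 0 unless the Haldane +0.5 correction is requested.

DP (discriminant power) is (sqrt(3)/pi) * (logit(sensitivity) + logit(specificity)),
which equals (sqrt(3)/pi) * ln(DOR) wherever both are defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

EPS = 1e-6


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for v in (self.tp, self.fp, self.tn, self.fn):
            if v < 0:
                raise ValueError("counts must be nonnegative")
        if self.total < 1:
            raise ValueError("at least one observation is required")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class MetricSet:
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    mcc: float
    dor: float  # nan when undefined
    dp: float   # nan when undefined
    auc: float | None = None
    counts: ConfusionCounts | None = None
    undefined: set = field(default_factory=set)

    def as_dict(self) -> dict:
        out = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "dor": None if math.isnan(self.dor) else self.dor,
            "dp": None if math.isnan(self.dp) else self.dp,
            "auc": self.auc,
        }
        if self.counts is not None:
            out["counts"] = {"tp": self.counts.tp, "fp": self.counts.fp,
                             "tn": self.counts.tn, "fn": self.counts.fn}
        if self.undefined:
            out["undefined"] = sorted(self.undefined)
        return out

    def __getitem__(self, name: str) -> float:
        return getattr(self, name)


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    y = np.asarray(true_labels).astype(int)
    p = np.asarray(predicted_labels).astype(int)
    if y.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    return ConfusionCounts(tp, fp, tn, fn)


def _rate(num, den, name, undefined):
    if den == 0:
        undefined.add(name)
        return 0.0
    return num / den


def mcc_from_counts(tp, fp, tn, fn) -> float:
    num = tp * tn - fp * fn
    den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return 0.0 if den == 0 else num / den


def compute_metrics(counts: ConfusionCounts, scores=None, labels=None,
                    haldane: bool = False) -> MetricSet:
    """All indices from the counts; AUC is filled in when scores are given."""
    und: set = set()
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sens = _rate(tp, tp + fn, "sensitivity", und)
    spec = _rate(tn, tn + fp, "specificity", und)
    prec = _rate(tp, tp + fp, "precision", und)
    acc = (tp + tn) / counts.total
    mcc = mcc_from_counts(tp, fp, tn, fn)
    if haldane:
        htp, hfp, htn, hfn = tp + 0.5, fp + 0.5, tn + 0.5, fn + 0.5
        dor = (htp * htn) / (hfp * hfn)
        hsens, hspec = htp / (htp + hfn), htn / (htn + hfp)
        dp = (math.sqrt(3) / math.pi) * (math.log(hsens / (1 - hsens)) + math.log(hspec / (1 - hspec)))
    elif fp * fn == 0 or tp * tn == 0:
        und.update({"dor", "dp"})
        dor = dp = math.nan
    else:
        dor = (tp * tn) / (fp * fn)
        dp = (math.sqrt(3) / math.pi) * (math.log(sens / (1 - sens)) + math.log(spec / (1 - spec)))
    auc = None
    if scores is not None and labels is not None:
        _, auc = roc_auc(scores, labels)
    return MetricSet(sens, spec, prec, acc, mcc, dor, dp, auc, counts, und)


def metric_set(true_labels, predicted_labels, scores=None, haldane: bool = False) -> MetricSet:
    counts = confusion(true_labels, predicted_labels)
    return compute_metrics(counts, scores=scores,
                           labels=true_labels if scores is not None else None,
                           haldane=haldane)


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending unique score values (tied scores grouped)
    fpr: np.ndarray         # anchored at (0,0) ... (1,1); one extra leading anchor point
    tpr: np.ndarray

    def youden(self) -> np.ndarray:
        """Youden's J = TPR - FPR at each real threshold (anchor excluded)."""
        return self.tpr[1:] - self.fpr[1:]


def roc_curve_points(scores, labels) -> RocCurve:
    """ROC by sweeping every unique score threshold (rule: score >= threshold)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC curve")
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    ss = scores[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    # group tied scores: keep the last index of each tie block
    last_of_tie = np.r_[np.diff(ss) != 0, True]
    thresholds = ss[last_of_tie]
    tpr = tps[last_of_tie] / n_pos
    fpr = fps[last_of_tie] / n_neg
    return RocCurve(thresholds, np.r_[0.0, fpr], np.r_[0.0, tpr])


def roc_auc(scores, labels):
    """(RocCurve, AUC) with AUC by the trapezoid rule (tie-grouped sweep)."""
    curve = roc_curve_points(scores, labels)
    auc = float(np.trapezoid(curve.tpr, curve.fpr))
    return curve, auc


def optimal_cutoff(scores, labels, method: str = "youden",
                   curve: RocCurve | None = None) -> float:
    """Decision cutoff from the training ROC.

    ``youden`` maximizes J = TPR - FPR (ties -> smaller threshold);
    ``closest`` minimizes the distance to the (0,1) corner.  The returned
    cutoff is clipped strictly inside (0,1).
    """
    if curve is None:
        curve = roc_curve_points(scores, labels)
    if method == "youden":
        crit = curve.tpr[1:] - curve.fpr[1:]
    elif method == "closest":
        crit = -np.hypot(curve.fpr[1:], 1.0 - curve.tpr[1:])
    else:
        raise ValueError(f"unknown cutoff method {method!r}")
    best = np.max(crit)
    candidates = curve.thresholds[crit >= best - 1e-12]
    cutoff = float(np.min(candidates))  # ties -> smaller threshold
    return float(np.clip(cutoff, EPS, 1.0 - EPS))
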