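"""Metric suite and validation protocols for binary HBP classification.

Scalar metrics follow the standard confusion-matrix formulas:

    ACC = (TP+TN)/(TP+TN+FP+FN)        Pre = TP/(TP+FP)
    Rec = SN = TP/(TP+FN)              SP  = TN/(TN+FP)
    F1  = 2·Pre·Rec/(Pre+Rec)
    MCC = (TP·TN − FP·FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Zero-denominator cases yield NaN (an explicit "undefined" marker — never an
exception and never a silent 0).  ROC and PR curves place one threshold at
every distinct score (ties grouped); areas use the trapezoidal rule.

Three protocols are provided: stratified K-fold cross-validation (default
K=5) with both pooled-counts and per-fold aggregation, the self-consistency
test (train and evaluate on the identical dataset — an upper-bound
diagnostic), and the independent test on a held-out set with an id-overlap
leakage guard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .model import BoostedForestConfig, TrainedModel, predict_label, predict_proba, train

#: Explicit marker for metrics whose denominator is zero.
UNDEFINED = float("nan")


def is_undefined(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass
class EvalReport:
    """Confusion counts, scalar metrics and ROC/PR curves for one experiment."""

    protocol: str
    counts: ConfusionCounts
    acc: float
    pre: float
    rec: float
    f1: float
    mcc: float
    sn: float
    sp: float
    roc: list[tuple[float, float]] | None = None
    pr: list[tuple[float, float]] | None = None
    auc: float | None = None
    auprc: float | None = None
    per_fold: list["EvalReport"] = field(default_factory=list)
    fold_mean: dict[str, float] = field(default_factory=dict)
    fold_sd: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "protocol": self.protocol,
            "tp": self.counts.tp, "tn": self.counts.tn,
            "fp": self.counts.fp, "fn": self.counts.fn,
            "acc": self.acc, "pre": self.pre, "rec": self.rec,
            "f1": self.f1, "mcc": self.mcc, "sn": self.sn, "sp": self.sp,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        if self.auprc is not None:
            d["auprc"] = self.auprc
        if self.fold_mean:
            d["fold_mean"] = self.fold_mean
            d["fold_sd"] = self.fold_sd
        return d


def confusion(truth, pred) -> ConfusionCounts:
    """2x2 confusion counts; positive class = HBP (label 1)."""
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if truth.shape != pred.shape:
        raise ValueError(f"length mismatch: {truth.shape} vs {pred.shape}")
    if truth.size == 0:
        raise ValueError("empty label vectors")
    tp = int(np.sum((truth == 1) & (pred == 1)))
    tn = int(np.sum((truth == 0) & (pred == 0)))
    fp = int(np.sum((truth == 0) & (pred == 1)))
    fn = int(np.sum((truth == 1) & (pred == 0)))
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else UNDEFINED


def scalar_metrics(c: ConfusionCounts) -> dict[str, float]:
    """All scalar metrics of one confusion table; NaN marks undefined values."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    acc = _ratio(c.tp + c.tn, c.total)
    pre = _ratio(c.tp, c.tp + c.fp)
    rec = _ratio(c.tp, c.tp + c.fn)
    sp = _ratio(c.tn, c.tn + c.fp)
    if is_undefined(pre) or is_undefined(rec) or (pre + rec) == 0:
        f1 = UNDEFINED
    else:
        f1 = 2 * pre * rec / (pre + rec)
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = _ratio(c.tp * c.tn - c.fp * c.fn, math.sqrt(denom)) if denom else UNDEFINED
    return {"acc": acc, "pre": pre, "rec": rec, "f1": f1, "mcc": mcc,
            "sn": rec, "sp": sp}


def roc_curve_and_auc(truth, score) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) with one threshold per distinct score, and
    the trapezoidal AUC.  Requires both classes present."""
    truth = np.asarray(truth, dtype=int)
    score = np.asarray(score, dtype=float)
    if truth.shape != score.shape:
        raise ValueError("length mismatch")
    n_pos = int(np.sum(truth == 1))
    n_neg = int(np.sum(truth == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-score, kind="stable")
    sorted_scores = score[order]
    sorted_truth = truth[order]
    tps = np.cumsum(sorted_truth == 1)
    fps = np.cumsum(sorted_truth == 0)
    # group ties: keep the last index of each distinct score
    distinct = np.nonzero(np.diff(sorted_scores, append=-np.inf))[0]
    tpr = np.concatenate([[0.0], tps[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fps[distinct] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def pr_curve_and_auprc(truth, score) -> tuple[list[tuple[float, float]], float]:
    """PR points (recall, precision) at every distinct score threshold, and
    the trapezoidal area over recall.  Requires at least one positive."""
    truth = np.asarray(truth, dtype=int)
    score = np.asarray(score, dtype=float)
    if truth.shape != score.shape:
        raise ValueError("length mismatch")
    n_pos = int(np.sum(truth == 1))
    if n_pos == 0:
        raise ValueError("PR curve requires at least one positive")
    order = np.argsort(-score, kind="stable")
    sorted_scores = score[order]
    sorted_truth = truth[order]
    tps = np.cumsum(sorted_truth == 1)
    preds = np.arange(1, len(truth) + 1)
    distinct = np.nonzero(np.diff(sorted_scores, append=-np.inf))[0]
    recall = tps[distinct] / n_pos
    precision = tps[distinct] / preds[distinct]
    # anchor the curve at recall 0 with the first threshold's precision
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    auprc = float(np.trapezoid(precision, recall))
    return list(zip(recall.tolist(), precision.tolist())), auprc


def _report(protocol: str, truth, pred, score=None) -> EvalReport:
    c = confusion(truth, pred)
    m = scalar_metrics(c)
    roc = pr = None
    auc = auprc = None
    truth_arr = np.asarray(truth, dtype=int)
    if score is not None and 0 < truth_arr.sum() < truth_arr.size:
        roc, auc = roc_curve_and_auc(truth, score)
        pr, auprc = pr_curve_and_auprc(truth, score)
    return EvalReport(protocol=protocol, counts=c, roc=roc, pr=pr,
                      auc=auc, auprc=auprc, **m)


def kfold_cv(
    table: pd.DataFrame,
    cfg: BoostedForestConfig = BoostedForestConfig(),
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> EvalReport:
    """Stratified K-fold cross-validation.

    Every sample is tested exactly once.  The headline report pools the
    confusion counts (and out-of-fold scores, for the curves) across folds;
    per-fold reports plus their mean ± sd are attached for the alternative
    fold-averaged aggregation.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if "label" not in table.columns:
        raise ValueError("feature table has no 'label' column")
    y = table["label"].to_numpy(dtype=int)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports: list[EvalReport] = []
    pooled_truth = np.empty(len(y), dtype=int)
    pooled_score = np.empty(len(y), dtype=float)
    for fold, (tr, te) in enumerate(splitter.split(np.zeros(len(y)), y)):
        m = train(table.iloc[tr], cfg)
        test = table.iloc[te]
        score = predict_proba(m, test)
        pred = (score >= threshold).astype(int)
        pooled_truth[te] = y[te]
        pooled_score[te] = score
        fold_reports.append(_report(f"cv-fold-{fold}", y[te], pred, score))
    pooled_pred = (pooled_score >= threshold).astype(int)
    report = _report("5-fold-cv" if k == 5 else f"{k}-fold-cv",
                     pooled_truth, pooled_pred, pooled_score)
    report.per_fold = fold_reports
    metrics = ("acc", "pre", "rec", "f1", "mcc", "sn", "sp")
    vals = {m: [getattr(r, m) for r in fold_reports] for m in metrics}
    report.fold_mean = {m: float(np.nanmean(v)) for m, v in vals.items()}
    report.fold_sd = {m: float(np.nanstd(v, ddof=1)) for m, v in vals.items()}
    return report


def self_consistency(
    table: pd.DataFrame,
    cfg: BoostedForestConfig = BoostedForestConfig(),
    threshold: float = 0.5,
) -> EvalReport:
    """Train and evaluate on the identical full dataset (upper bound)."""
    m = train(table, cfg)
    y = table["label"].to_numpy(dtype=int)
    score = predict_proba(m, table)
    pred = (score >= threshold).astype(int)
    return _report("self-consistency", y, pred, score)


def independent_test(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    cfg: BoostedForestConfig = BoostedForestConfig(),
    threshold: float = 0.5,
) -> tuple[TrainedModel, EvalReport]:
    """Fit on the training table only; report on the held-out test table.

    Raises on any id shared between the two tables (leakage guard).
    """
    overlap = set(train_table.index) & set(test_table.index)
    if overlap:
        raise ValueError(
            f"train/test id overlap (leakage): {sorted(overlap)[:5]}"
        )
    m = train(train_table, cfg)
    y = test_table["label"].to_numpy(dtype=int)
    score = predict_proba(m, test_table)
    pred = predict_label(m, test_table, threshold)
    return m, _report("independent-test", y, pred, score)


def write_report(report: EvalReport, path) -> None:
    """Structured key-value dump of an EvalReport as JSON."""
    import json

    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, allow_nan=True)
        fh.write("\n")


def write_curve(points: list[tuple[float, float]], path) -> None:
    """Two-column tab-separated curve dump."""
    with open(path, "w") as fh:
        for a, b in points:
            fh.write(f"{a:.10g}\t{b:.10g}\n")
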