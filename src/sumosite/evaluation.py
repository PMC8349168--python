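"""Binary-classification metrics and the three evaluation protocols.

Metrics are accuracy, sensitivity (recall on sumoylation sites), specificity
(recall on non-sites) and the Matthews correlation coefficient, plus ROC/AUC.
Protocols: self-consistency (train and evaluate on the same rows — a
memorisation check), an independent train/test split (70:30 in the published
study), and seeded stratified k-fold cross-validation whose headline numbers
are unweighted means of the per-fold metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve, auc as _trapezoid_auc
from sklearn.model_selection import StratifiedKFold, train_test_split

from sumosite.model import ModelConfig, train, predict_labels, predict_scores


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    """Metrics of one evaluation run (fractions in [0, 1], MCC in [-1, 1])."""

    acc: float
    sn: float | None
    sp: float | None
    mcc: float
    n: int
    protocol: str
    auc: float | None = None
    per_fold: list["MetricReport"] | None = None

    def to_dict(self) -> dict:
        out = {
            "protocol": self.protocol,
            "n": self.n,
            "acc": self.acc,
            "sn": self.sn,
            "sp": self.sp,
            "mcc": self.mcc,
            "auc": self.auc,
        }
        if self.per_fold is not None:
            out["per_fold"] = [f.to_dict() for f in self.per_fold]
        return out

    def __str__(self) -> str:
        def pct(v):
            return "-" if v is None else f"{100 * v:.2f}%"

        auc_s = "-" if self.auc is None else f"{self.auc:.4f}"
        return (
            f"[{self.protocol}] n={self.n} Acc={pct(self.acc)} Sn={pct(self.sn)} "
            f"Sp={pct(self.sp)} MCC={self.mcc:.4f} AUC={auc_s}"
        )


@dataclass
class ROCCurve:
    points: np.ndarray  # (k, 2) ordered (fpr, tpr)
    auc: float


def _as_binary(v, name: str) -> np.ndarray:
    arr = np.asarray(v).astype(int)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr


def confusion(predicted, truth) -> ConfusionCounts:
    """Standard 2x2 tally of predicted vs true binary labels."""
    pred = _as_binary(predicted, "predicted")
    y = _as_binary(truth, "truth")
    if pred.size != y.size:
        raise ValueError("predicted and truth differ in length")
    return ConfusionCounts(
        tp=int(((pred == 1) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )


def metrics(counts: ConfusionCounts, protocol: str = "unspecified",
            auc: float | None = None) -> MetricReport:
    """Acc, Sn, Sp and MCC from a confusion tally.

    Sn/Sp are ``None`` when the corresponding class is empty; MCC is defined
    as 0 whenever a denominator factor vanishes.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    n = counts.n
    if n == 0:
        raise ValueError("empty confusion table")
    acc = (tp + tn) / n
    sn = tp / (tp + fn) if (tp + fn) > 0 else None
    sp = tn / (tn + fp) if (tn + fp) > 0 else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricReport(acc=acc, sn=sn, sp=sp, mcc=mcc, n=n, protocol=protocol, auc=auc)


def roc(scores, truth) -> ROCCurve:
    """ROC curve by threshold sweep and AUC by the trapezoidal rule."""
    y = _as_binary(truth, "truth")
    s = np.asarray(scores, dtype=float)
    if s.size != y.size:
        raise ValueError("scores and truth differ in length")
    if y.min() == y.max():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:  # pragma: no cover - roc_curve guarantee
        fpr = np.append(fpr, 1.0)
        tpr = np.append(tpr, 1.0)
    return ROCCurve(points=np.column_stack([fpr, tpr]), auc=float(_trapezoid_auc(fpr, tpr)))


def _evaluate(model, X, y, protocol: str) -> MetricReport:
    pred = predict_labels(model, X)
    scores = predict_scores(model, X)
    report = metrics(confusion(pred, y), protocol=protocol)
    if np.unique(y).size == 2:
        report.auc = roc(scores, y).auc
    return report


def self_consistency(X, y, config: ModelConfig | None = None) -> MetricReport:
    """Train and evaluate on the same rows (resubstitution)."""
    model = train(X, y, config)
    return _evaluate(model, X, y, protocol="self_consistency")


def independent_test(train_X, train_y, test_X, test_y,
                     config: ModelConfig | None = None) -> MetricReport:
    """Train on the training split only, report metrics on the test split."""
    model = train(train_X, train_y, config)
    return _evaluate(model, test_X, test_y, protocol="independent")


def split_70_30(X, y, seed: int = 0, test_fraction: float = 0.3):
    """Seeded stratified train/test split (default 70:30)."""
    return train_test_split(
        np.asarray(X, dtype=float),
        np.asarray(y, dtype=int),
        test_size=test_fraction,
        stratify=np.asarray(y, dtype=int),
        random_state=seed,
    )


def kfold_cv(X, y, k: int = 10, config: ModelConfig | None = None,
             seed: int = 0) -> MetricReport:
    """Stratified k-fold cross-validation; headline = mean of per-fold metrics."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"every class needs >= {k} members for {k}-fold CV")
    folds = []
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in splitter.split(X, y):
        model = train(X[train_idx], y[train_idx], config)
        folds.append(_evaluate(model, X[test_idx], y[test_idx], protocol="kfold_fold"))
    aucs = [f.auc for f in folds if f.auc is not None]
    report = MetricReport(
        acc=float(np.mean([f.acc for f in folds])),
        sn=float(np.mean([f.sn for f in folds])),
        sp=float(np.mean([f.sp for f in folds])),
        mcc=float(np.mean([f.mcc for f in folds])),
        auc=float(np.mean(aucs)) if aucs else None,
        n=int(y.size),
        protocol="kfold",
        per_fold=folds,
    )
    return report
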