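"""Confusion-matrix metrics, ROC/AUC, cross-validation, and the ablation
ladder runner.

The ladder has four rungs of increasing model structure, all sharing the
same neighbourhood size K:

    knn          majority vote among the K nearest training points
    hknn         nearest local hyperplane, squared error
    hknn_krp     local hyperplane with the robust KRP loss (no graph)
    mvhknn_krp   KRP loss plus the fused multi-view Laplacian penalty

Cross-validation is stratified with a seeded shuffle; the primary metrics
pool the out-of-fold confusion counts (per-fold reports are retained).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .data import FeatureDataset
from .exceptions import ConfigurationError, ContractViolationError, MetricWarning
from .hknn import hknn_classify, knn_classify
from .solver import Hyperparameters, classify, without_graph

__all__ = [
    "RUNGS",
    "RUNG_LABELS",
    "EvaluationReport",
    "compute_metrics",
    "roc_auc",
    "predict_dataset",
    "cross_validate",
    "run_ablation",
    "report_table_tsv",
    "report_summary_json",
]

RUNGS = ("knn", "hknn", "hknn_krp", "mvhknn_krp")
RUNG_LABELS = {
    "knn": "KNN",
    "hknn": "HKNN",
    "hknn_krp": "HKNN(KRP)",
    "mvhknn_krp": "MvHKNN(KRP)",
}


@dataclass
class EvaluationReport:
    """Confusion counts, the four scalar metrics, and (when scores are
    available) the ROC curve and AUC. ``folds`` holds per-fold
    sub-reports for cross-validated runs."""

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sn: float
    sp: float
    mcc: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None
    folds: list["EvaluationReport"] | None = None

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> tuple[float, float, float, float]:
    """ACC, SN (recall on positives), SP (recall on negatives), MCC.

    MCC is reported as 0 with a :class:`MetricWarning` when any marginal
    in its denominator vanishes.
    """
    for name, v in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise ContractViolationError(f"{name} must be >= 0")
    total = tp + tn + fp + fn
    if total == 0:
        raise ConfigurationError("all confusion counts are zero")
    acc = (tp + tn) / total
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    if denom == 0:
        warnings.warn("MCC denominator has a zero marginal; reporting 0",
                      MetricWarning)
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    return float(acc), float(sn), float(sp), float(mcc)


def _report_from_confusion(y_true, y_pred, scores=None) -> EvaluationReport:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    acc, sn, sp, mcc = compute_metrics(tp, tn, fp, fn)
    rep = EvaluationReport(tp=tp, tn=tn, fp=fp, fn=fn,
                           acc=acc, sn=sn, sp=sp, mcc=mcc)
    if scores is not None and np.unique(y_true).size == 2:
        rep.roc_points, rep.auc = roc_auc(scores, y_true)
    return rep


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC points (fpr, tpr) over the unique score thresholds, and the
    AUC, which equals pairwise concordance with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ConfigurationError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def predict_dataset(train: FeatureDataset, X_test: np.ndarray,
                    hp: Hyperparameters, method: str = "mvhknn_krp"
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and ROC scores for every row of ``X_test``.

    Scores are oriented so larger means more class-1-like: the class-1
    vote fraction for ``knn`` and the class-0-minus-class-1 score or
    objective for the hyperplane rungs.
    """
    if method not in RUNGS:
        raise ConfigurationError(f"unknown method {method!r}; expected one of {RUNGS}")
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    n = X_test.shape[0]
    labels = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)

    if method == "knn":
        for i, x in enumerate(X_test):
            labels[i] = knn_classify(x, train, hp.K)
            dist = np.linalg.norm(train.X - x[None, :], axis=1)
            order = np.argsort(dist, kind="stable")[:hp.K]
            scores[i] = float(np.mean(train.y[order] == 1))
        return labels, scores

    if method == "hknn":
        for i, x in enumerate(X_test):
            labels[i], s = hknn_classify(x, train, hp.K, hp.lambda_r)
            scores[i] = float(s[0] - s[1]) if s.size == 2 else -float(s[labels[i]])
        return labels, scores

    hp_eff = without_graph(hp) if method == "hknn_krp" else hp
    for i, x in enumerate(X_test):
        labels[i], objs, score = classify(x, train, hp_eff)
        scores[i] = score if score is not None else -float(objs[labels[i]])
    return labels, scores


def _cv_splits(data: FeatureDataset, folds: int, seed: int):
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    if folds == data.n:
        return list(LeaveOneOut().split(data.X))
    for c in data.classes:
        if int(np.sum(data.y == c)) < folds:
            raise ConfigurationError(
                f"class {int(c)} too small for {folds}-fold stratification"
            )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(data.X, data.y))


def cross_validate(data: FeatureDataset, hp: Hyperparameters, folds: int = 5,
                   seed: int = 0, method: str = "mvhknn_krp",
                   splits=None) -> EvaluationReport:
    """Stratified k-fold cross-validation with pooled-confusion metrics.

    ``folds == n`` requests leave-one-out. Pre-computed ``splits`` may be
    passed to share fold assignments across methods.
    """
    if splits is None:
        splits = _cv_splits(data, folds, seed)
    y_pred = np.empty(data.n, dtype=int)
    scores = np.empty(data.n, dtype=float)
    fold_reports: list[EvaluationReport] = []
    for train_idx, test_idx in splits:
        sub = data.subset(train_idx)
        if method != "knn":
            sub.require_min_class_size(hp.K)
        lab, sc = predict_dataset(sub, data.X[test_idx], hp, method)
        y_pred[test_idx] = lab
        scores[test_idx] = sc
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", MetricWarning)
            fold_reports.append(_report_from_confusion(data.y[test_idx], lab))
    report = _report_from_confusion(data.y, y_pred, scores=scores)
    report.folds = fold_reports
    return report


def run_ablation(data: FeatureDataset, hp: Hyperparameters, folds: int = 5,
                 seed: int = 0, methods=RUNGS) -> dict[str, EvaluationReport]:
    """Cross-validate every requested rung on identical fold assignments
    (a paired comparison)."""
    splits = _cv_splits(data, folds, seed)
    return {
        m: cross_validate(data, hp, folds, seed, method=m, splits=splits)
        for m in methods
    }


def report_table_tsv(reports: dict[str, EvaluationReport]) -> str:
    """One TSV row per rung: framework, ACC, SN, SP, MCC, AUC, counts."""
    lines = ["framework\tacc\tsn\tsp\tmcc\tauc\ttp\ttn\tfp\tfn"]
    for name, r in reports.items():
        auc = f"{r.auc:.6f}" if r.auc is not None else "NA"
        lines.append(
            f"{RUNG_LABELS.get(name, name)}\t{r.acc:.6f}\t{r.sn:.6f}\t"
            f"{r.sp:.6f}\t{r.mcc:.6f}\t{auc}\t{r.tp}\t{r.tn}\t{r.fp}\t{r.fn}"
        )
    return "\n".join(lines) + "\n"


def report_summary_json(reports: dict[str, EvaluationReport]) -> str:
    """Deterministic JSON summary (no ROC points, which go to TSV)."""
    out = {}
    for name, r in reports.items():
        entry = {
            "acc": r.acc, "sn": r.sn, "sp": r.sp, "mcc": r.mcc,
            "auc": r.auc, "tp": r.tp, "tn": r.tn, "fp": r.fp, "fn": r.fn,
        }
        if r.folds:
            entry["folds"] = [
                {"acc": f.acc, "sn": f.sn, "sp": f.sp, "mcc": f.mcc,
                 "tp": f.tp, "tn": f.tn, "fp": f.fp, "fn": f.fn}
                for f in r.folds
            ]
        out[name] = entry
    return json.dumps(out, indent=2, sort_keys=True) + "\n"
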