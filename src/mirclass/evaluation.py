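"""Cross-validation, accuracy/confusion metrics, ROC curves, and holdout validation.

Metrics are pooled: out-of-fold predictions from every fold are gathered and
a single correct/total count, confusion matrix and ROC curve are computed on
the pool, matching the reporting style of the WEKA workbench (e.g. "83/88
correctly classified").  Percent accuracy is rounded half-up to two
decimals.  AUC is the trapezoidal area under the threshold-swept ROC curve,
which (with ties contributing half) equals the normalized Mann–Whitney U
statistic.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifiers import ClassifierSpec, TrainedModel, fit_model
from .core import FeatureTable

logger = logging.getLogger(__name__)


def accuracy_pct(correct: int, total: int) -> float:
    """100·correct/total, rounded half-up to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= correct <= total:
        raise ValueError(f"correct={correct} outside [0, {total}]")
    pct = Decimal(100 * correct) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Disjoint index folds preserving class proportions (counts differ ≤ 1).

    Falls back to the size of the smallest class when it has fewer than ``k``
    members, with a logged warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    min_class = int(counts.min())
    if min_class < k:
        logger.warning("smallest class has %d members; reducing k from %d", min_class, k)
        k = min_class
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def roc_auc(scores, labels) -> tuple[list[tuple[float, float, float]], float]:
    """ROC points and trapezoidal AUC from scores and binary labels.

    Thresholds sweep every distinct score from high to low; each returned
    point is ``(fpr, tpr, threshold)``.  The curve starts at (0, 0) (with a
    sentinel threshold above all scores) and ends at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    points = [(0.0, 0.0, float(s_sorted[0]) + 1.0)]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        thr = s_sorted[i]
        while i < n and s_sorted[i] == thr:  # group ties at one threshold
            if y_sorted[i] == 1:
                tp += 1
            else:
                fp += 1
            i += 1
        points.append((fp / n_neg, tp / n_pos, float(thr)))
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


@dataclass
class FoldMetrics:
    fold: int
    correct: int
    total: int
    accuracy_pct: float


@dataclass
class EvalReport:
    """Per-classifier evaluation: counts, confusion, ROC/AUC, per-fold detail."""

    classifier: str
    correct: int
    total: int
    accuracy_pct: float
    confusion: list[list[int]]  # rows: true random/selected; cols: predicted
    roc_points: list[tuple[float, float, float]]
    auc: float
    per_fold: list[FoldMetrics] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _report_from_predictions(
    name: str,
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray,
    per_fold: list[FoldMetrics],
) -> EvalReport:
    correct = int((y_pred == y_true).sum())
    total = len(y_true)
    confusion = [
        [int(((y_true == t) & (y_pred == p)).sum()) for p in (0, 1)] for t in (0, 1)
    ]
    points, auc = roc_auc(scores, y_true)
    return EvalReport(
        classifier=name,
        correct=correct,
        total=total,
        accuracy_pct=accuracy_pct(correct, total),
        confusion=confusion,
        roc_points=points,
        auc=auc,
        per_fold=per_fold,
    )


def cross_validate(
    spec: ClassifierSpec, table: FeatureTable, k: int = 10, seed: int = 0
) -> EvalReport:
    """Stratified k-fold CV with pooled out-of-fold metrics.

    The learner is re-initialized per fold with a fold-derived seed; all
    fitting (including z-scoring statistics) sees only the training fold.
    """
    y = table.y()
    folds = stratified_kfold(table.labels, k=k, seed=seed)
    scores = np.empty(len(y))
    y_pred = np.empty(len(y), dtype=int)
    per_fold = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        fold_spec = ClassifierSpec(spec.name, dict(spec.hyperparams), seed=spec.seed + f)
        model = fit_model(fold_spec, table.select_rows(train_idx))
        p = model.predict_proba(table.matrix[test_idx])
        scores[test_idx] = p
        y_pred[test_idx] = (p >= 0.5).astype(int)
        c = int((y_pred[test_idx] == y[test_idx]).sum())
        per_fold.append(FoldMetrics(f, c, len(test_idx), accuracy_pct(c, len(test_idx))))
    return _report_from_predictions(spec.name, y, y_pred, scores, per_fold)


def validate_holdout(model: TrainedModel, validation: FeatureTable) -> EvalReport:
    """Single-pass evaluation of a trained model on an independent table.

    Column names must match the model's training columns exactly.
    """
    scores = model.predict_proba(validation)  # raises on column mismatch
    y = validation.y()
    y_pred = (scores >= 0.5).astype(int)
    return _report_from_predictions(model.spec.name, y, y_pred, scores, [])


def plot_roc(report: EvalReport, path) -> None:
    """Optional ROC figure with per-point threshold coloring."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr = [p[0] for p in report.roc_points]
    tpr = [p[1] for p in report.roc_points]
    thr = [p[2] for p in report.roc_points]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(fpr, tpr, color="0.6", lw=1)
    sc = ax.scatter(fpr, tpr, c=thr, cmap="viridis", s=18)
    fig.colorbar(sc, ax=ax, label="threshold")
    ax.plot([0, 1], [0, 1], ls="--", color="0.8")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"{report.classifier} (AUC = {report.auc:.3f})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
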