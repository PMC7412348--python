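"""Leave-one-out cross-validation, diagnostic metrics and Youden-index
channel selection.

Metrics follow the diagnostic-test convention: the disease class is
positive, HC is negative. AUC is reported twice — ``auc_balanced`` =
(sensitivity + specificity) / 2, and ``auc_rank`` (trapezoidal on
decision scores) when scores are available — because the two definitions
are not interchangeable and both appear in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from gaitrp.features import FeatureMatrix, ClassifierSpec, train_classifier, predict
from gaitrp.records import CHANNELS


@dataclass(frozen=True)
class CVScheme:
    """Leave-one-out unit: ``window`` (each sample is a fold; windows of
    one subject may straddle train/test — leakage is disclosed in
    reports) or ``subject`` (all of a subject's windows form one fold)."""

    unit: str = "window"

    def __post_init__(self) -> None:
        if self.unit not in ("window", "subject"):
            raise ValueError("unit must be 'window' or 'subject'")


@dataclass
class EvalMetrics:
    task: str
    channel: str
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    auc_balanced: float | None
    J: float | None
    confusion: np.ndarray
    class_order: tuple
    auc_rank: float | None = None
    flags: list = field(default_factory=list)
    cv_unit: str | None = None

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "channel": self.channel,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc_balanced": self.auc_balanced,
            "auc_rank": self.auc_rank,
            "J": self.J,
            "confusion": self.confusion.tolist(),
            "class_order": list(self.class_order),
            "flags": list(self.flags),
            "cv_unit": self.cv_unit,
        }


def round_display(value: float, decimals: int) -> float:
    """Half-up rounding of the binary double, as used for table display."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(value).quantize(q, rounding=ROUND_HALF_UP))


def youden(sensitivity: float, specificity: float) -> float:
    """Youden's index J = sensitivity + specificity - 1."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError(
            "sensitivity and specificity must lie in [0, 1], got "
            f"{sensitivity}, {specificity}"
        )
    return sensitivity + specificity - 1.0


def loocv(
    fm: FeatureMatrix,
    scheme: CVScheme,
    classifier: ClassifierSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-unit-out predictions for every sample.

    Returns ``(predictions, fold_ids)`` aligned to the rows of ``fm``.
    Each unit is predicted by a model trained on all remaining units.
    """
    n = len(fm)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if len(np.unique(fm.labels)) < 2:
        raise ValueError("need at least 2 classes")
    units = fm.groups if scheme.unit == "subject" else np.arange(n)
    unique_units = np.unique(units)
    if scheme.unit == "subject":
        # every class needs >= 2 subjects so no train fold is single-class
        for lab in np.unique(fm.labels):
            if len(np.unique(fm.groups[fm.labels == lab])) < 2:
                raise ValueError(
                    f"class {lab!r} has fewer than 2 subjects; "
                    "subject-wise LOOCV would produce degenerate folds"
                )
    preds = np.empty(n, dtype=object)
    fold_ids = np.empty(n, dtype=object)
    for unit in unique_units:
        test_mask = units == unit
        train = fm.subset(~test_mask)
        if len(np.unique(train.labels)) < 2:
            raise ValueError(
                f"training fold for unit {unit!r} is single-class; "
                "LOOCV is degenerate for this dataset"
            )
        model = train_classifier(train, classifier)
        preds[test_mask] = predict(model, fm.F[test_mask])
        fold_ids[test_mask] = unit
    return preds.astype(fm.labels.dtype), fold_ids


def confusion_matrix(
    truth: np.ndarray, preds: np.ndarray, class_order: list | tuple
) -> np.ndarray:
    """Counts[i, j] = samples of class_order[i] predicted class_order[j]."""
    from sklearn.metrics import confusion_matrix as _cm

    return _cm(truth, preds, labels=list(class_order))


def binary_metrics(
    confusion: np.ndarray,
    positive_class,
    class_order: tuple,
    task: str = "",
    channel: str = "",
    scores: np.ndarray | None = None,
    truth: np.ndarray | None = None,
) -> EvalMetrics:
    """Diagnostic metrics from a 2x2 confusion matrix.

    Sides with zero positives or zero negatives yield ``None`` for the
    undefined metric and a flag, never a silent 0.
    """
    confusion = np.asarray(confusion)
    if confusion.shape != (2, 2):
        raise ValueError("binary_metrics requires a 2x2 confusion matrix")
    if confusion.min() < 0:
        raise ValueError("confusion counts must be nonnegative")
    total = int(confusion.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    if positive_class not in class_order:
        raise ValueError(f"{positive_class!r} not in class order {class_order}")
    p = class_order.index(positive_class)
    q = 1 - p
    tp = int(confusion[p, p])
    fn = int(confusion[p, q])
    tn = int(confusion[q, q])
    fp = int(confusion[q, p])

    flags = []
    sens = spec = None
    if tp + fn > 0:
        sens = tp / (tp + fn)
    else:
        flags.append("sensitivity undefined: no positive samples")
    if tn + fp > 0:
        spec = tn / (tn + fp)
    else:
        flags.append("specificity undefined: no negative samples")
    acc = (tp + tn) / total
    auc_b = (sens + spec) / 2.0 if sens is not None and spec is not None else None
    j = youden(sens, spec) if sens is not None and spec is not None else None

    auc_rank = None
    if scores is not None and truth is not None and sens is not None and spec is not None:
        from sklearn.metrics import roc_auc_score

        y = (np.asarray(truth) == positive_class).astype(int)
        if 0 < y.sum() < len(y):
            auc_rank = float(roc_auc_score(y, scores))

    return EvalMetrics(
        task=task,
        channel=channel,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        auc_balanced=auc_b,
        auc_rank=auc_rank,
        J=j,
        confusion=confusion,
        class_order=tuple(class_order),
        flags=flags,
    )


def multiclass_metrics(
    confusion: np.ndarray,
    class_order: tuple,
    task: str = "multiclass",
    channel: str = "",
) -> dict:
    """Per-class one-vs-rest collapse of a K x K confusion matrix.

    Returns ``{"overall_accuracy": ..., "per_class": {label: EvalMetrics}}``.
    """
    confusion = np.asarray(confusion)
    k = confusion.shape[0]
    if k < 3 or confusion.shape != (k, k):
        raise ValueError("multiclass_metrics requires a square K x K matrix, K >= 3")
    if len(class_order) != k:
        raise ValueError("class_order length must match matrix size")
    total = confusion.sum()
    per_class = {}
    for idx, label in enumerate(class_order):
        tp = confusion[idx, idx]
        fn = confusion[idx].sum() - tp
        fp = confusion[:, idx].sum() - tp
        tn = total - tp - fn - fp
        collapsed = np.array([[tp, fn], [fp, tn]])
        per_class[label] = binary_metrics(
            collapsed,
            positive_class=label,
            class_order=(label, "rest"),
            task=task,
            channel=channel,
        )
    return {
        "overall_accuracy": float(np.trace(confusion) / total) if total else None,
        "per_class": per_class,
    }


def select_best_channel(metrics: list[EvalMetrics]) -> str:
    """Channel with the highest Youden index.

    Ties break by accuracy, then by the fixed order LF < RF < CF.
    """
    if not metrics:
        raise ValueError("no channel metrics given")

    def key(m: EvalMetrics):
        j = m.J if m.J is not None else -np.inf
        return (-j, -m.accuracy, CHANNELS.index(m.channel))

    return min(metrics, key=key).channel


def evaluate_task(
    fm: FeatureMatrix,
    task_classes: tuple,
    positive_class,
    scheme: CVScheme,
    classifier: ClassifierSpec,
    task: str = "",
    channel: str = "",
) -> EvalMetrics:
    """LOOCV a binary task on the subset of samples in ``task_classes``."""
    mask = np.isin(fm.labels, list(task_classes))
    sub = fm.subset(mask)
    preds, _ = loocv(sub, scheme, classifier)
    cm = confusion_matrix(sub.labels, preds, task_classes)
    m = binary_metrics(
        cm, positive_class, tuple(task_classes), task=task, channel=channel
    )
    m.cv_unit = scheme.unit
    if scheme.unit == "window":
        m.flags.append(
            "window-level LOOCV: overlapping windows of one subject may "
            "appear in both train and test folds (optimistic estimate)"
        )
    return m
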