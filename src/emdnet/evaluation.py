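"""Cross-validated training/testing and multiclass metrics.

Folds: stratified k-fold (default k=5) either at segment level — every
epoch assigned independently, the 80/20-per-fold split used for the
headline numbers — or at subject level, where all epochs of a subject
stay on one side of each split (recommended against subject leakage,
since consecutive overlapping epochs of one subject are highly
correlated).

Metrics: per-class one-vs-rest TP/TN/FP/FN feed the standard accuracy /
precision / recall / F1 formulas, reported under micro averaging (pool
the per-class counts first) and macro averaging (unweighted mean of
per-class values).  For single-label multiclass data, micro precision =
micro recall = micro F1 = accuracy — an algebraic identity, because
every false positive for one class is a false negative for another, so
pooled FP equals pooled FN.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .cnn import EMDNetClassifier, ModelSpec, TrainConfig
from .records import ClassLabel, EpochSet

__all__ = [
    "FoldPlan",
    "MetricsReport",
    "make_folds",
    "confusion_matrix",
    "compute_metrics",
    "aggregate_reports",
    "cross_validate",
]

N_CLASSES = 3


@dataclass
class FoldPlan:
    """Train/test index lists for each of k folds."""

    k: int
    mode: str  # "segment_level" | "subject_level"
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)
    seed: int

    def __iter__(self):
        return iter(self.folds)


def make_folds(
    labels: Sequence[int] | EpochSet,
    k: int = 5,
    mode: str = "segment_level",
    seed: int = 0,
    subject_ids: Sequence[str] | None = None,
) -> FoldPlan:
    """Build a stratified k-fold plan over an epoch set.

    In ``subject_level`` mode no subject appears on both sides of any
    fold; this requires at least k subjects per class.  Test sets
    partition the epoch index set exactly in both modes.
    """
    if isinstance(labels, EpochSet):
        subject_ids = labels.subject_ids
        labels = labels.labels
    y = np.asarray(labels, dtype=np.int64)
    if k < 2:
        raise ValueError("k must be >= 2")
    if mode == "segment_level":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [(tr, te) for tr, te in splitter.split(np.zeros_like(y), y)]
    elif mode == "subject_level":
        if subject_ids is None:
            raise ValueError("subject_level folds need subject_ids")
        groups = np.asarray(subject_ids)
        for c in np.unique(y):
            n_subj = len(np.unique(groups[y == c]))
            if n_subj < k:
                raise ValueError(
                    f"class {ClassLabel(int(c)).name} has {n_subj} subjects; "
                    f"subject_level {k}-fold needs at least {k}"
                )
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [(tr, te) for tr, te in splitter.split(np.zeros_like(y), y, groups)]
    else:
        raise ValueError(f"unknown fold mode {mode!r}")
    return FoldPlan(k=k, mode=mode, folds=folds, seed=seed)


def confusion_matrix(y_true: Sequence[int], y_pred: Sequence[int]) -> np.ndarray:
    """3x3 counts; entry (i, j) = epochs with true class i predicted j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    for name, v in (("true", y_true), ("predicted", y_pred)):
        if len(v) and not np.isin(v, (0, 1, 2)).all():
            raise ValueError(f"{name} labels outside {{0, 1, 2}}")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


@dataclass
class MetricsReport:
    """Confusion matrix plus accuracy/precision/recall/F1 (micro and macro)."""

    confusion: np.ndarray
    per_class: dict = field(default_factory=dict)  # class name -> counts + metrics
    accuracy: float = 0.0
    micro: dict = field(default_factory=dict)
    macro: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "accuracy": self.accuracy,
            "micro": self.micro,
            "macro": self.macro,
        }


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, defining the value as 0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(confusion: np.ndarray) -> MetricsReport:
    """Evaluate the standard metric formulas on a 3x3 confusion matrix.

    Per class c (one-vs-rest): TP = confusion[c, c], FP = predicted-c
    errors, FN = missed-c errors, TN = the rest.  Accuracy is the global
    trace / total; micro metrics pool TP/FP/FN over classes; macro
    metrics average per-class values.  Zero-denominator precision or
    recall is defined as 0 with a warning.
    """
    cm = np.asarray(confusion)
    if cm.shape != (N_CLASSES, N_CLASSES) or (cm < 0).any():
        raise ValueError("confusion must be a nonnegative 3x3 matrix")
    if not np.issubdtype(cm.dtype, np.integer):
        raise ValueError("confusion entries must be integers")
    total = int(cm.sum())
    if total == 0:
        raise ValueError("confusion matrix is empty")

    per_class: dict = {}
    tps = fps = fns = 0
    prec, rec, f1s, accs = [], [], [], []
    for c in range(N_CLASSES):
        tp = int(cm[c, c])
        fp = int(cm[:, c].sum() - tp)
        fn = int(cm[c, :].sum() - tp)
        tn = total - tp - fp - fn
        name = ClassLabel(c).name
        p = _safe_div(tp, tp + fp, f"precision[{name}]")
        r = _safe_div(tp, tp + fn, f"recall[{name}]")
        f = _safe_div(2 * p * r, p + r, f"f1[{name}]")
        a = (tp + tn) / total
        per_class[name] = {
            "TP": tp, "TN": tn, "FP": fp, "FN": fn,
            "precision": p, "recall": r, "f1": f, "accuracy": a,
        }
        tps, fps, fns = tps + tp, fps + fp, fns + fn
        prec.append(p); rec.append(r); f1s.append(f); accs.append(a)

    accuracy = int(np.trace(cm)) / total
    micro_p = _safe_div(tps, tps + fps, "micro precision")
    micro_r = _safe_div(tps, tps + fns, "micro recall")
    micro_f = _safe_div(2 * micro_p * micro_r, micro_p + micro_r, "micro f1")
    report = MetricsReport(
        confusion=cm,
        per_class=per_class,
        accuracy=accuracy,
        micro={
            "accuracy": accuracy, "precision": micro_p,
            "recall": micro_r, "f1": micro_f,
        },
        macro={
            "accuracy": float(np.mean(accs)), "precision": float(np.mean(prec)),
            "recall": float(np.mean(rec)), "f1": float(np.mean(f1s)),
        },
    )
    return report


def aggregate_reports(reports: list[MetricsReport]) -> dict:
    """Mean-over-folds summary plus the pooled confusion matrix."""
    pooled = np.sum([r.confusion for r in reports], axis=0)
    out = {
        "n_folds": len(reports),
        "mean_accuracy": float(np.mean([r.accuracy for r in reports])),
        "pooled_confusion": pooled.tolist(),
    }
    for scheme in ("micro", "macro"):
        for m in ("accuracy", "precision", "recall", "f1"):
            vals = [getattr(r, scheme)[m] for r in reports]
            out[f"mean_{scheme}_{m}"] = float(np.mean(vals))
    return out


def cross_validate(
    tensors: np.ndarray,
    labels: Sequence[int],
    plan: FoldPlan,
    model_spec: ModelSpec | None = None,
    train_config: TrainConfig | None = None,
    normalize: bool = True,
    seed: int = 0,
) -> tuple[list[MetricsReport], dict]:
    """Train a freshly initialized classifier per fold and evaluate it.

    Returns the per-fold reports and a mean-over-folds aggregate that
    also carries the run provenance (seed, spec hash, fold plan mode).
    """
    tensors = np.asarray(tensors, dtype=np.float32)
    y = np.asarray(labels, dtype=np.int64)
    cfg = train_config or TrainConfig()
    reports: list[MetricsReport] = []
    for f, (tr, te) in enumerate(plan):
        clf = EMDNetClassifier(
            model_spec=model_spec,
            learning_rate=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2,
            batch_size=cfg.batch_size, epochs=cfg.epochs,
            normalize=normalize, random_state=seed + f,
        )
        clf.fit(tensors[tr], y[tr])
        pred = clf.predict(tensors[te])
        reports.append(compute_metrics(confusion_matrix(y[te], pred)))
    aggregate = aggregate_reports(reports)
    aggregate["provenance"] = {
        "seed": seed,
        "fold_mode": plan.mode,
        "k": plan.k,
        "spec_hash": (model_spec or EMDNetClassifier()._spec()).hash(),
        "epochs": cfg.epochs,
        "batch_size": cfg.batch_size,
        "learning_rate": cfg.learning_rate,
        "normalize": normalize,
    }
    return reports, aggregate


def save_reports(reports: list[MetricsReport], aggregate: dict, path) -> None:
    """Serialize fold reports + aggregate to one JSON file."""
    payload = {
        "folds": [r.to_dict() for r in reports],
        "aggregate": aggregate,
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=2)
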