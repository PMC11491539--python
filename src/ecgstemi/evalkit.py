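"""Detection and classification metrics plus the cross-validation harness.

Detection evaluation follows the standard object-detection protocol:
predictions are matched to ground truths greedily by score, one-to-one,
at a fixed IoU threshold (0.5), yielding per-class sensitivity and
all-point-interpolated average precision.  Classification metrics are the
usual thresholded confusion-matrix set plus AUROC/AUPRC, reported per fold
with mean and standard deviation under stratified k-fold cross-validation.

Undefined metrics (e.g. precision with no positive predictions, AUROC on a
single-class fold) are reported as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .detector import BoundingBox, Detection, iou
from .synthgen import LESSER_STE, STE, GroundTruthBox

__all__ = [
    "MatchResult",
    "DetectionEvalResult",
    "ClassificationEvalResult",
    "match_detections",
    "average_precision",
    "evaluate_detections",
    "classification_metrics",
    "kfold_cv",
]


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    #: (prediction index, ground-truth index, IoU) per true positive
    matches: list[tuple[int, int, float]] = field(default_factory=list)
    #: per prediction, sorted by score descending: (score, matched?)
    scored: list[tuple[float, bool]] = field(default_factory=list)


def _gt_box(gt) -> BoundingBox:
    if isinstance(gt, GroundTruthBox):
        return BoundingBox.from_rect(gt.rect)
    if isinstance(gt, BoundingBox):
        return gt
    return BoundingBox.from_rect(gt)


def match_detections(
    gt: list,
    pred: list[Detection],
    iou_min: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching of predictions to ground truths.

    Predictions are visited in descending score order (stable for ties);
    each claims the unmatched ground truth of highest IoU, provided
    IoU >= ``iou_min``.  Caller is responsible for restricting both lists
    to one case and one class.
    """
    gt_boxes = [_gt_box(g) for g in gt]
    order = sorted(range(len(pred)), key=lambda i: (-pred[i].score, i))
    taken = [False] * len(gt_boxes)
    result = MatchResult(tp=0, fp=0, fn=0)
    for i in order:
        best_j, best_ov = -1, 0.0
        for j, gbox in enumerate(gt_boxes):
            if taken[j]:
                continue
            ov = iou(pred[i].box, gbox)
            if ov > best_ov:
                best_j, best_ov = j, ov
        if best_j >= 0 and best_ov >= iou_min:
            taken[best_j] = True
            result.tp += 1
            result.matches.append((i, best_j, best_ov))
            result.scored.append((pred[i].score, True))
        else:
            result.fp += 1
            result.scored.append((pred[i].score, False))
    result.fn = len(gt_boxes) - result.tp
    return result


def average_precision(
    scored: list[tuple[float, bool]],
    n_ground_truth: int,
) -> float:
    """All-point-interpolated area under the precision-recall curve.

    ``scored`` holds (score, is_true_positive) over the whole dataset;
    ``n_ground_truth`` normalizes recall.  Returns NaN when there are no
    ground truths (undefined).
    """
    if n_ground_truth == 0:
        return float("nan")
    if not scored:
        return 0.0
    order = sorted(range(len(scored)), key=lambda i: (-scored[i][0], i))
    tp = np.cumsum([1 if scored[i][1] else 0 for i in order])
    fp = np.cumsum([0 if scored[i][1] else 1 for i in order])
    recall = tp / n_ground_truth
    precision = tp / (tp + fp)
    # precision envelope, integrated at every recall change
    mrec = np.concatenate(([0.0], recall, [recall[-1]]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


@dataclass
class DetectionEvalResult:
    """Per-class detection performance over a dataset."""

    cls: str
    n_ground_truth: int
    n_detections: int
    tp: int
    sensitivity: float
    average_precision: float
    iou_min: float = 0.5


def evaluate_detections(
    gt_per_case: list[list],
    pred_per_case: list[list[Detection]],
    iou_min: float = 0.5,
    classes: tuple[str, ...] = (STE, LESSER_STE),
) -> dict[str, DetectionEvalResult]:
    """Per-class sensitivity and AP across a dataset of cases."""
    if len(gt_per_case) != len(pred_per_case):
        raise ValueError("ground-truth and prediction lists differ in length")
    out: dict[str, DetectionEvalResult] = {}
    for cls in classes:
        scored: list[tuple[float, bool]] = []
        n_gt = n_pred = tp = 0
        for gt, pred in zip(gt_per_case, pred_per_case):
            g = [b for b in gt if b.cls == cls]
            p = [d for d in pred if d.cls == cls]
            m = match_detections(g, p, iou_min=iou_min)
            scored.extend(m.scored)
            n_gt += len(g)
            n_pred += len(p)
            tp += m.tp
        sens = tp / n_gt if n_gt else float("nan")
        out[cls] = DetectionEvalResult(
            cls=cls,
            n_ground_truth=n_gt,
            n_detections=n_pred,
            tp=tp,
            sensitivity=sens,
            average_precision=average_precision(scored, n_gt),
            iou_min=iou_min,
        )
    return out


@dataclass
class ClassificationEvalResult:
    auroc: float
    auprc: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "auroc": self.auroc,
            "auprc": self.auprc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
        }


def classification_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
) -> ClassificationEvalResult:
    """Threshold-free (AUROC, AUPRC) and thresholded confusion metrics.

    ``labels`` are 0/1 with 1 = positive (STEMI); ``scores`` are
    probability-like.  AUROC uses the tie-corrected rank statistic, AUPRC
    all-point precision-recall integration.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have matching shapes")
    single_class = len(np.unique(labels)) < 2
    auroc = float("nan") if single_class else float(roc_auc_score(labels, scores))
    auprc = float("nan") if single_class else float(average_precision_score(labels, scores))

    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))

    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    f1 = (
        2 * prec * sens / (prec + sens)
        if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
        else float("nan")
    )
    return ClassificationEvalResult(
        auroc=auroc,
        auprc=auprc,
        accuracy=_ratio(tp + tn, tp + tn + fp + fn),
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f1=f1,
    )


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    estimator,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> dict:
    """Stratified k-fold cross-validation of a probability classifier.

    The estimator must expose sklearn-style ``fit``/``predict_proba``; it is
    cloned per fold.  Folds are stratified and deterministic given ``seed``.
    Returns per-fold metric dicts plus mean and standard deviation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) < k:
        raise ValueError("fewer cases than folds")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation requires both classes")
    if counts.min() < k:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has only {counts.min()} cases; "
            f"cannot stratify {k} folds"
        )
    y_bin = (y == classes[-1]).astype(int) if y.dtype.kind in "USO" else y.astype(int)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    assignments = []
    for train_idx, test_idx in skf.split(X, y_bin):
        est = clone(estimator)
        est.fit(X[train_idx], y[train_idx])
        proba = est.predict_proba(X[test_idx])[:, -1]
        folds.append(classification_metrics(proba, y_bin[test_idx], threshold=threshold))
        assignments.append((train_idx, test_idx))

    metric_names = folds[0].as_dict().keys()
    per_fold = [f.as_dict() for f in folds]
    summary = {
        name: {
            "mean": float(np.nanmean([f[name] for f in per_fold])),
            "std": float(np.nanstd([f[name] for f in per_fold])),
        }
        for name in metric_names
    }
    return {"folds": per_fold, "summary": summary, "seed": seed, "k": k, "assignments": assignments}
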