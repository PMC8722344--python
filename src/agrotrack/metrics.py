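"""Evaluation suite: detection PR/F1, segmentation IoU, confusion accuracy,
and yield-count agreement (mean normalized absolute error, R²)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instances import InstanceMask

__all__ = [
    "DetectionCounts",
    "RowCounts",
    "match_detections",
    "f1_score",
    "pr_curve_f1",
    "segmentation_iou",
    "instance_vs_semantic_eval",
    "confusion_matrix",
    "confusion_accuracy",
    "mu_nae",
    "r_squared",
    "load_row_counts",
    "save_row_counts",
]


@dataclass(frozen=True)
class DetectionCounts:
    """True-positive / false-positive / false-negative detection tallies."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("detection counts must be non-negative")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0


@dataclass
class RowCounts:
    """Per-row ground-truth and predicted object counts.

    ``gt`` and ``pred`` map a row identifier to either a total count or a
    per-sub-class dict of counts.
    """

    gt: dict
    pred: dict

    def totals(self) -> tuple[np.ndarray, np.ndarray]:
        rows = sorted(self.gt)
        g = np.array([_total(self.gt[r]) for r in rows], dtype=float)
        p = np.array([_total(self.pred.get(r, 0)) for r in rows], dtype=float)
        return g, p


def _total(entry) -> float:
    if isinstance(entry, dict):
        return float(sum(entry.values()))
    return float(entry)


# ---------------------------------------------------------------------------
# detection metrics
# ---------------------------------------------------------------------------

def segmentation_iou(output: InstanceMask, ground_truth: InstanceMask) -> float:
    """Pixel-wise intersection-over-union of a prediction/ground-truth pair."""
    if output.is_empty and ground_truth.is_empty:
        return 1.0
    if output.is_empty or ground_truth.is_empty:
        return 0.0
    width = int(max(output.pixels[:, 0].max(),
                    ground_truth.pixels[:, 0].max())) + 1
    a = output.linear_indices(width)
    b = ground_truth.linear_indices(width)
    inter = np.intersect1d(a, b, assume_unique=True).size
    return inter / (a.size + b.size - inter)


def match_detections(predictions: list[InstanceMask],
                     ground_truth: list[InstanceMask],
                     iou_threshold: float = 0.4
                     ) -> tuple[DetectionCounts, list[tuple[int, int, float]]]:
    """Greedy one-to-one matching of predictions to ground truth by IoU.

    Predictions are visited in descending confidence order; each claims the
    unclaimed ground-truth mask of maximal IoU, provided that IoU reaches
    the threshold.  Returns the detection counts plus the matched
    ``(pred_index, gt_index, iou)`` triples.
    """
    order = sorted(range(len(predictions)),
                   key=lambda i: (-predictions[i].confidence, i))
    claimed: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for pi in order:
        best_j, best_iou = None, 0.0
        for gj, gt in enumerate(ground_truth):
            if gj in claimed:
                continue
            iou = segmentation_iou(predictions[pi], gt)
            if iou > best_iou:
                best_j, best_iou = gj, iou
        if best_j is not None and best_iou >= iou_threshold:
            claimed.add(best_j)
            matches.append((pi, best_j, best_iou))
    tp = len(matches)
    counts = DetectionCounts(tp=tp, fp=len(predictions) - tp,
                             fn=len(ground_truth) - tp)
    return counts, matches


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def pr_curve_f1(confidences: np.ndarray, is_tp: np.ndarray, n_ground_truth: int
                ) -> tuple[pd.DataFrame, float]:
    """Precision-recall curve and the F1 score at the P = R operating point.

    ``confidences``/``is_tp`` describe scored detections (matched against
    ground truth once, at full recall); the curve sweeps the confidence
    threshold.  The operating point where precision equals recall is found
    by linear interpolation between adjacent curve samples; at that point
    F1 equals the common value of P and R.
    """
    confidences = np.asarray(confidences, dtype=float)
    is_tp = np.asarray(is_tp, dtype=bool)
    if confidences.size == 0:
        return pd.DataFrame({"threshold": [], "precision": [], "recall": []}), 0.0
    order = np.argsort(-confidences, kind="stable")
    c = confidences[order]
    tp_cum = np.cumsum(is_tp[order])
    k = np.arange(1, c.size + 1)
    precision = tp_cum / k
    recall = tp_cum / n_ground_truth if n_ground_truth else np.zeros_like(precision)
    curve = pd.DataFrame({"threshold": c, "precision": precision,
                          "recall": recall})
    diff = precision - recall
    if diff.size == 1 or np.all(diff >= 0) or np.all(diff <= 0):
        # no crossing inside the curve: take the sample closest to P = R
        idx = int(np.argmin(np.abs(diff)))
        return curve, f1_score(precision[idx], recall[idx])
    sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    i = int(sign_change[0])
    d0, d1 = diff[i], diff[i + 1]
    w = 0.0 if d1 == d0 else d0 / (d0 - d1)
    p_star = precision[i] + w * (precision[i + 1] - precision[i])
    r_star = recall[i] + w * (recall[i + 1] - recall[i])
    return curve, f1_score(p_star, r_star)


# ---------------------------------------------------------------------------
# segmentation protocols
# ---------------------------------------------------------------------------

def _binary_union(masks: list[InstanceMask], image_size: tuple[int, int]
                  ) -> np.ndarray:
    w, h = image_size
    out = np.zeros((h, w), dtype=bool)
    for m in masks:
        if len(m):
            out[m.pixels[:, 1], m.pixels[:, 0]] = True
    return out


def _binary_iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum()) / float(union)


def instance_vs_semantic_eval(predictions: list[InstanceMask],
                              ground_truth: list[InstanceMask],
                              image_size: tuple[int, int],
                              iou_threshold: float = 0.4) -> dict:
    """Foreground/background IoU under the instance and semantic protocols.

    Instance protocol: predictions and ground truth are matched one-to-one
    (IoU >= threshold); the foreground IoU is averaged over the union of
    instances, with unmatched predictions (false positives) and unmatched
    ground truths (missed detections) each contributing 0.  A
    matched-instances-only average is also reported.

    Semantic protocol: all instances on each side collapse into one binary
    map and the foreground/background IoUs are computed pixel-wise.

    Both protocols report ``mu_iou = (bg_iou + fg_iou) / 2``.
    """
    counts, matches = match_detections(predictions, ground_truth, iou_threshold)
    matched_ious = [iou for (_, _, iou) in matches]
    n_instances = counts.tp + counts.fp + counts.fn
    fg_instance = (sum(matched_ious) / n_instances) if n_instances else 1.0
    fg_matched_only = (float(np.mean(matched_ious)) if matched_ious else 0.0)

    pred_map = _binary_union(predictions, image_size)
    gt_map = _binary_union(ground_truth, image_size)
    fg_semantic = _binary_iou(pred_map, gt_map)
    bg_semantic = _binary_iou(~pred_map, ~gt_map)

    # instance-protocol background: complement IoU averaged per instance pair
    bg_pairs = [
        _binary_iou(~predictions[pi].to_binary(image_size),
                    ~ground_truth[gj].to_binary(image_size))
        for (pi, gj, _) in matches
    ]
    full = np.ones((image_size[1], image_size[0]), dtype=bool)
    matched_preds = {pi for (pi, _, _) in matches}
    matched_gts = {gj for (_, gj, _) in matches}
    for pi, m in enumerate(predictions):
        if pi not in matched_preds:
            bg_pairs.append(_binary_iou(~m.to_binary(image_size), full))
    for gj, m in enumerate(ground_truth):
        if gj not in matched_gts:
            bg_pairs.append(_binary_iou(full, ~m.to_binary(image_size)))
    bg_instance = float(np.mean(bg_pairs)) if bg_pairs else 1.0

    return {
        "counts": counts,
        "instance": {"bg_iou": bg_instance, "fg_iou": fg_instance,
                     "mu_iou": (bg_instance + fg_instance) / 2,
                     "fg_iou_matched_only": fg_matched_only},
        "semantic": {"bg_iou": bg_semantic, "fg_iou": fg_semantic,
                     "mu_iou": (bg_semantic + fg_semantic) / 2},
    }


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

def confusion_matrix(true_labels: list[str], pred_labels: list[str],
                     vocabulary: tuple[str, ...]) -> np.ndarray:
    """Row-normalized confusion matrix over a fixed label vocabulary.

    Rows are ground truth, columns are predictions; rows of absent classes
    stay all-zero.  Typically fed with matched (IoU-gated) pairs only.
    """
    index = {label: i for i, label in enumerate(vocabulary)}
    n = len(vocabulary)
    C = np.zeros((n, n), dtype=float)
    for t, p in zip(true_labels, pred_labels, strict=True):
        C[index[t], index[p]] += 1
    sums = C.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        C = np.where(sums > 0, C / sums, 0.0)
    return C


def confusion_accuracy(C: np.ndarray) -> float:
    """Mean of the diagonal of a row-normalized confusion matrix."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    sums = C.sum(axis=1)
    if np.any((sums > 0) & (np.abs(sums - 1) > 1e-9)):
        raise ValueError("confusion matrix rows must be normalized")
    return float(np.trace(C)) / C.shape[0]


# ---------------------------------------------------------------------------
# yield-count agreement
# ---------------------------------------------------------------------------

def mu_nae(rows: RowCounts, per_sub_class: bool = False):
    """Mean normalized absolute error of predicted vs ground-truth counts.

    ``mean_i |GT_i − P_i| / GT_i`` over rows; 0 is perfect and the value is
    unbounded above.  In per-sub-class mode the mean additionally runs over
    sub-classes, and zero-ground-truth cells are excluded with a warning.
    """
    if not per_sub_class:
        g, p = rows.totals()
        if np.any(g <= 0):
            raise ValueError("ground-truth totals must be positive")
        return float(np.mean(np.abs(g - p) / g))
    errs = []
    for r in sorted(rows.gt):
        gt_row = rows.gt[r]
        pred_row = rows.pred.get(r, {})
        if not isinstance(gt_row, dict):
            raise ValueError("per-sub-class mode requires dict counts")
        for label, g in gt_row.items():
            if g <= 0:
                warnings.warn(f"row {r!r}, sub-class {label!r}: zero ground "
                              "truth excluded from per-sub-class muNAE")
                continue
            p = pred_row.get(label, 0) if isinstance(pred_row, dict) else 0
            errs.append(abs(g - p) / g)
    return float(np.mean(errs)) if errs else 0.0


def r_squared(rows: RowCounts, fit: str = "ols") -> float:
    """Coefficient of determination of predicted vs ground-truth counts.

    ``fit="ols"`` (default) scores the ordinary least-squares fit of the
    predictions on the ground truth; ``fit="identity"`` scores residuals
    about the 1:1 line instead.
    """
    g, p = rows.totals()
    if g.size < 2 or np.all(g == g[0]):
        raise ValueError("R² needs at least two rows with non-constant "
                         "ground truth")
    if fit == "ols":
        result = stats.linregress(g, p)
        return float(result.rvalue ** 2)
    if fit == "identity":
        ss_res = float(np.sum((p - g) ** 2))
        ss_tot = float(np.sum((p - np.mean(p)) ** 2))
        if ss_tot == 0:
            return 1.0 if ss_res == 0 else 0.0
        return 1.0 - ss_res / ss_tot
    raise ValueError("fit must be 'ols' or 'identity'")


# ---------------------------------------------------------------------------
# visual ground-truth count files (row id + per-sub-class counts + total)
# ---------------------------------------------------------------------------

def save_row_counts(path, counts: dict[str, dict[str, int]],
                    sub_classes: tuple[str, ...]) -> None:
    """Write per-row sub-class counts as CSV with a validated Total column."""
    records = []
    for row_id in counts:
        rec = {"Row": row_id}
        rec.update({s: int(counts[row_id].get(s, 0)) for s in sub_classes})
        rec["Total"] = sum(rec[s] for s in sub_classes)
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def load_row_counts(path) -> dict[str, dict[str, int]]:
    """Load a per-row count CSV; the Total column must equal the row sum."""
    df = pd.read_csv(path)
    if "Row" not in df.columns:
        raise ValueError("count file must have a 'Row' column")
    sub_cols = [c for c in df.columns if c not in ("Row", "Total")]
    out: dict[str, dict[str, int]] = {}
    for _, rec in df.iterrows():
        row_counts = {c: int(rec[c]) for c in sub_cols}
        if "Total" in df.columns and int(rec["Total"]) != sum(row_counts.values()):
            raise ValueError(f"row {rec['Row']!r}: Total does not equal the "
                             "sum of sub-class counts")
        out[str(rec["Row"])] = row_counts
    return out
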