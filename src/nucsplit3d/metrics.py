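"""Object-level evaluation of instance segmentations.

Predicted and ground-truth instances are matched one-to-one by IoU at each
threshold ``t`` of a threshold set; from the matched/unmatched counts we
report precision, recall and F1 per threshold and their means (mP, mR, mF1,
on the 0-100 scale), the per-threshold average precision ``AP_t = TP / (TP +
FP + FN)`` and its mean mAP, and the Aggregated Jaccard Index, which folds
voxel-level agreement into a single dataset-level ratio in [0, 1].
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linear_sum_assignment

from .volumes import LabelVolume

__all__ = [
    "DEFAULT_THRESHOLDS",
    "SPARSE_THRESHOLDS",
    "MatchResult",
    "MetricsReport",
    "instance_iou_matrix",
    "match_at_threshold",
    "detection_metrics",
    "aji",
    "ap_from_scores",
    "voxel_metrics",
    "evaluate",
]

#: IoU thresholds for dense, hard-to-segment volumes.
DEFAULT_THRESHOLDS = (0.25, 0.30, 0.35, 0.40, 0.45)
#: IoU thresholds for sparser, easier volumes.
SPARSE_THRESHOLDS = (0.50, 0.55, 0.60, 0.65, 0.70, 0.75)


@dataclasses.dataclass
class MatchResult:
    threshold: float
    pairs: List[Tuple[int, int, float]]  # (gt label, pred label, IoU)
    n_tp: int
    n_fp: int
    n_fn: int


@dataclasses.dataclass
class MetricsReport:
    thresholds: Tuple[float, ...]
    per_threshold: Dict[float, Dict[str, float]]
    mean_precision: float
    mean_recall: float
    mean_f1: float
    mean_ap: float
    aji: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "thresholds": list(self.thresholds),
            "per_threshold": {str(t): v for t, v in self.per_threshold.items()},
            "mP": self.mean_precision,
            "mR": self.mean_recall,
            "mF1": self.mean_f1,
            "mAP": self.mean_ap,
            "AJI": self.aji,
        }


def _overlap_table(gt: np.ndarray, pred: np.ndarray):
    """Sparse contingency of voxel counts between nonzero gt/pred labels,
    plus per-label voxel counts."""
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    g = gt.ravel()
    p = pred.ravel()
    both = (g > 0) | (p > 0)
    g, p = g[both], p[both]
    n_g = int(gt.max(initial=0)) + 1
    n_p = int(pred.max(initial=0)) + 1
    table = sparse.coo_matrix(
        (np.ones(g.size, dtype=np.int64), (g, p)), shape=(n_g, n_p)
    ).tocsr()
    gt_sizes = np.asarray(table.sum(axis=1)).ravel()
    pred_sizes = np.asarray(table.sum(axis=0)).ravel()
    return table, gt_sizes, pred_sizes


def instance_iou_matrix(gt: LabelVolume, pred: LabelVolume) -> sparse.csr_matrix:
    """Pairwise IoU between every overlapping (gt, pred) nonzero label pair.

    Returned as a sparse matrix indexed by raw label values; non-overlapping
    pairs are implicitly zero.
    """
    table, gt_sizes, pred_sizes = _overlap_table(gt.data, pred.data)
    inter = table.tocoo()
    rows, cols, vals = inter.row, inter.col, inter.data
    keep = (rows > 0) & (cols > 0)
    rows, cols, vals = rows[keep], cols[keep], vals[keep]
    union = gt_sizes[rows] + pred_sizes[cols] - vals
    iou = vals / union
    return sparse.csr_matrix((iou, (rows, cols)), shape=table.shape)


def _pairs_sorted(iou_matrix: sparse.csr_matrix) -> List[Tuple[float, int, int]]:
    coo = iou_matrix.tocoo()
    order = np.lexsort((coo.col, coo.row, -coo.data))
    return [(float(coo.data[i]), int(coo.row[i]), int(coo.col[i])) for i in order]


def match_at_threshold(
    iou_matrix: sparse.csr_matrix,
    t: float,
    n_gt: Optional[int] = None,
    n_pred: Optional[int] = None,
    optimal: bool = False,
) -> MatchResult:
    """One-to-one matching among pairs with IoU >= t.

    Default is greedy in descending IoU (ties broken by label order);
    ``optimal=True`` solves the maximum-cardinality assignment instead.
    ``n_gt``/``n_pred`` default to the number of labels present in the
    matrix's rows/columns.
    """
    if not (0.0 < t < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    coo = iou_matrix.tocoo()
    if n_gt is None:
        n_gt = np.unique(coo.row[coo.data > 0]).size
    if n_pred is None:
        n_pred = np.unique(coo.col[coo.data > 0]).size
    pairs: List[Tuple[int, int, float]] = []
    if optimal:
        keep = coo.data >= t
        rows, cols, vals = coo.row[keep], coo.col[keep], coo.data[keep]
        if rows.size:
            r_ids = np.unique(rows)
            c_ids = np.unique(cols)
            cost = np.zeros((r_ids.size, c_ids.size))
            r_pos = {v: i for i, v in enumerate(r_ids)}
            c_pos = {v: i for i, v in enumerate(c_ids)}
            for r, c, v in zip(rows, cols, vals):
                cost[r_pos[r], c_pos[c]] = v
            ri, ci = linear_sum_assignment(cost, maximize=True)
            for i, j in zip(ri, ci):
                if cost[i, j] >= t:
                    pairs.append((int(r_ids[i]), int(c_ids[j]), float(cost[i, j])))
    else:
        used_gt, used_pred = set(), set()
        for v, r, c in _pairs_sorted(iou_matrix):
            if v < t:
                break
            if r in used_gt or c in used_pred:
                continue
            used_gt.add(r)
            used_pred.add(c)
            pairs.append((r, c, v))
    n_tp = len(pairs)
    return MatchResult(t, pairs, n_tp, n_pred - n_tp, n_gt - n_tp)


def detection_metrics(
    gt: LabelVolume,
    pred: LabelVolume,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    optimal: bool = False,
) -> MetricsReport:
    """Precision/recall/F1/AP per threshold and their means, 0-100 scale.

    The empty-vs-empty case scores 100 everywhere (perfect vacuous
    agreement); an empty prediction against a nonempty ground truth scores 0.
    """
    if len(thresholds) == 0:
        raise ValueError("threshold set must be nonempty")
    n_gt = gt.labels().size
    n_pred = pred.labels().size
    iou = instance_iou_matrix(gt, pred)
    per: Dict[float, Dict[str, float]] = {}
    for t in thresholds:
        if n_gt == 0 and n_pred == 0:
            per[t] = {"precision": 100.0, "recall": 100.0, "f1": 100.0, "ap": 100.0,
                      "n_tp": 0, "n_fp": 0, "n_fn": 0}
            continue
        m = match_at_threshold(iou, t, n_gt=n_gt, n_pred=n_pred, optimal=optimal)
        tp, fp, fn = m.n_tp, m.n_fp, m.n_fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        ap = tp / (tp + fp + fn) if tp + fp + fn else 0.0
        per[t] = {"precision": 100 * prec, "recall": 100 * rec, "f1": 100 * f1,
                  "ap": 100 * ap, "n_tp": tp, "n_fp": fp, "n_fn": fn}
    return MetricsReport(
        thresholds=tuple(thresholds),
        per_threshold=per,
        mean_precision=float(np.mean([per[t]["precision"] for t in thresholds])),
        mean_recall=float(np.mean([per[t]["recall"] for t in thresholds])),
        mean_f1=float(np.mean([per[t]["f1"] for t in thresholds])),
        mean_ap=float(np.mean([per[t]["ap"] for t in thresholds])),
    )


def aji(gt: LabelVolume, pred: LabelVolume) -> float:
    """Aggregated Jaccard Index in [0, 1].

    For each ground-truth instance, the not-yet-used predicted instance with
    the highest Jaccard similarity is taken; matched intersections accumulate
    in the numerator, matched unions in the denominator, and the voxel counts
    of unmatched predictions are added to the denominator.
    """
    table, gt_sizes, pred_sizes = _overlap_table(gt.data, pred.data)
    gt_ids = np.nonzero(gt_sizes)[0]
    gt_ids = gt_ids[gt_ids > 0]
    pred_ids = set(int(i) for i in np.nonzero(pred_sizes)[0] if i > 0)
    if gt_ids.size == 0:
        return 1.0 if not pred_ids else 0.0
    num = 0.0
    den = 0.0
    used = set()
    for g in gt_ids:
        row = table.getrow(g).tocoo()
        best_j, best_i, best_u = -1.0, 0.0, float(gt_sizes[g])
        for c, inter in zip(row.col, row.data):
            if c == 0 or c in used:
                continue
            union = gt_sizes[g] + pred_sizes[c] - inter
            j = inter / union
            if j > best_j:
                best_j, best_i, best_u = j, float(inter), float(union)
                best_c = int(c)
        if best_j >= 0:
            used.add(best_c)
            num += best_i
            den += best_u
        else:
            den += float(gt_sizes[g])  # unmatched ground truth: union with empty set
    for c in pred_ids - used:
        den += float(pred_sizes[c])
    return num / den if den else 0.0


def ap_from_scores(
    gt: LabelVolume,
    pred: LabelVolume,
    scores: Dict[int, float],
    t: float,
) -> float:
    """Curve-based average precision at IoU threshold ``t`` (0-100 scale).

    Requires a per-instance confidence for every predicted label (instance
    maps alone carry no ranking, which is why the default ``AP_t`` is the
    count ratio instead).  Predictions are swept in descending confidence;
    each is a TP if it matches a not-yet-matched ground-truth instance at
    IoU >= t.  AP is the area under the resulting precision-recall curve
    (step interpolation).
    """
    pred_ids = pred.labels()
    missing = [int(p) for p in pred_ids if int(p) not in scores]
    if missing:
        raise ValueError(f"missing confidence scores for predictions {missing}")
    n_gt = gt.labels().size
    if n_gt == 0:
        return 100.0 if pred_ids.size == 0 else 0.0
    iou = instance_iou_matrix(gt, pred).tocsc()
    order = sorted((int(p) for p in pred_ids), key=lambda p: -scores[p])
    matched_gt: set = set()
    tp = 0
    area = 0.0
    prev_recall = 0.0
    for rank, p in enumerate(order, start=1):
        col = iou.getcol(p).tocoo()
        best = None
        for g, v in sorted(zip(col.row, col.data), key=lambda x: -x[1]):
            if v >= t and g not in matched_gt:
                best = int(g)
                break
        if best is not None:
            matched_gt.add(best)
            tp += 1
        recall = tp / n_gt
        precision = tp / rank
        area += precision * (recall - prev_recall)
        prev_recall = recall
    return 100.0 * area


def voxel_metrics(gt: LabelVolume, pred: LabelVolume) -> Dict[str, float]:
    """Semantic (foreground vs background) precision/recall/F1, 0-100."""
    g = gt.data > 0
    p = pred.data > 0
    tp = int(np.sum(g & p))
    fp = int(np.sum(~g & p))
    fn = int(np.sum(g & ~p))
    prec = tp / (tp + fp) if tp + fp else (1.0 if fn == 0 else 0.0)
    rec = tp / (tp + fn) if tp + fn else 1.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 100.0 / 100
    return {"precision": 100 * prec, "recall": 100 * rec, "f1": 100 * f1}


def evaluate(
    gt: LabelVolume,
    pred: LabelVolume,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    optimal: bool = False,
) -> MetricsReport:
    """Full report: detection metrics over the threshold set plus AJI."""
    report = detection_metrics(gt, pred, thresholds, optimal=optimal)
    report.aji = aji(gt, pred)
    return report
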