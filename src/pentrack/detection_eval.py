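"""Detection-evaluation mathematics: IOU, matching, PR curves, AP/mAP.

Evaluates per-frame object detections against manual bounding-box annotation
with the COCO-style machinery: intersection over union, greedy one-to-one
matching in descending confidence order, precision/recall per confidence
threshold, 101-point interpolated average precision, and its mean over
classes and over a ladder of IOU thresholds.  Also provides the
median-IOU/IQR summary used for annotator reliability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

N_RECALL_POINTS = 101
COCO_IOU_THRESHOLDS = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))

__all__ = [
    "BoundingBox",
    "PRPoint",
    "EvalReport",
    "iou",
    "match_frame",
    "pr_curve",
    "average_precision",
    "map_over",
    "annotator_reliability",
    "boxes_by_frame",
    "COCO_IOU_THRESHOLDS",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in image pixels, stored center/width/height."""

    cx: float
    cy: float
    w: float
    h: float
    cls: Optional[str] = None
    conf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"degenerate box: w={self.w}, h={self.h}")
        if self.conf is not None and not 0.0 <= self.conf <= 1.0:
            raise ValueError(f"confidence {self.conf} outside [0, 1]")

    @property
    def left(self) -> float:
        return self.cx - self.w / 2.0

    @property
    def top(self) -> float:
        return self.cy - self.h / 2.0

    @property
    def right(self) -> float:
        return self.cx + self.w / 2.0

    @property
    def bottom(self) -> float:
        return self.cy + self.h / 2.0


@dataclass(frozen=True)
class PRPoint:
    """Counts and derived rates at one confidence threshold."""

    conf_threshold: float
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class EvalReport:
    """Per-class AP, mAP at each IOU threshold, and the F1-optimal operating point."""

    ap_per_class: dict
    map_at: dict
    map_mean: float
    best_conf: float
    precision_at_best: float
    recall_at_best: float
    f1_at_best: float
    n_recall_points: int = N_RECALL_POINTS

    def to_dict(self) -> dict:
        return {
            "ap_per_class": {c: dict(v) for c, v in self.ap_per_class.items()},
            "map_at": dict(self.map_at),
            "map_mean": self.map_mean,
            "best_conf": self.best_conf,
            "precision_at_best": self.precision_at_best,
            "recall_at_best": self.recall_at_best,
            "f1_at_best": self.f1_at_best,
            "n_recall_points": self.n_recall_points,
        }


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint, 1 when identical."""
    iw = min(a.right, b.right) - max(a.left, b.left)
    ih = min(a.bottom, b.bottom) - max(a.top, b.top)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.w * a.h + b.w * b.h - inter
    return inter / union


def match_frame(
    preds: Sequence[BoundingBox],
    gts: Sequence[BoundingBox],
    conf_t: float,
    iou_t: float,
) -> tuple[int, int, int]:
    """TP/FP/FN counts for one frame at the given thresholds.

    Predictions below ``conf_t`` are discarded.  Survivors are processed in
    descending confidence order and greedily matched one-to-one to the
    unmatched same-class ground truth of highest IOU; a match with
    IOU >= ``iou_t`` is a true positive, anything else (wrong class, low
    overlap, or ground truth already taken) a false positive.  Unmatched
    ground truths are false negatives.
    """
    flags = _greedy_match_flags(preds, gts, iou_t, conf_t=conf_t)
    tp = int(sum(flags))
    fp = len(flags) - tp
    fn = len(gts) - tp
    return tp, fp, fn


def _greedy_match_flags(
    preds: Sequence[BoundingBox],
    gts: Sequence[BoundingBox],
    iou_t: float,
    conf_t: float = 0.0,
) -> list[bool]:
    """Per-surviving-prediction TP flags, in descending-confidence order."""
    survivors = [p for p in preds if (p.conf or 0.0) >= conf_t]
    order = sorted(
        range(len(survivors)), key=lambda i: (-(survivors[i].conf or 0.0), i)
    )
    taken = [False] * len(gts)
    flags = []
    for i in order:
        p = survivors[i]
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if taken[j] or g.cls != p.cls:
                continue
            v = iou(p, g)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_t:
            taken[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    return flags


def pr_curve(
    preds: Mapping[int, Sequence[BoundingBox]],
    gts: Mapping[int, Sequence[BoundingBox]],
    iou_t: float,
) -> list[PRPoint]:
    """Precision-recall curve over all frames, one point per distinct confidence.

    Greedy matching processes predictions in descending confidence order, so
    the matching at a higher threshold is a prefix of the matching at
    threshold zero; the curve is computed with a single sweep and cumulative
    TP/FP counts.
    """
    n_gt = sum(len(v) for v in gts.values())
    if n_gt == 0:
        raise ValueError("recall undefined: no ground truths")
    confs: list[float] = []
    flags: list[bool] = []
    for frame, frame_preds in preds.items():
        frame_gts = gts.get(frame, ())
        frame_flags = _greedy_match_flags(frame_preds, frame_gts, iou_t)
        ordered = sorted(frame_preds, key=lambda b: -(b.conf or 0.0))
        confs.extend((b.conf or 0.0) for b in ordered)
        flags.extend(frame_flags)
    if not confs:
        return []
    conf_arr = np.asarray(confs)
    flag_arr = np.asarray(flags, dtype=bool)
    order = np.argsort(-conf_arr, kind="stable")
    conf_arr = conf_arr[order]
    flag_arr = flag_arr[order]
    tp_cum = np.cumsum(flag_arr)
    fp_cum = np.cumsum(~flag_arr)
    # one point per distinct confidence, taken at the last (lowest) index
    points: list[PRPoint] = []
    for k in range(len(conf_arr)):
        if k + 1 < len(conf_arr) and conf_arr[k + 1] == conf_arr[k]:
            continue
        tp = int(tp_cum[k])
        fp = int(fp_cum[k])
        points.append(PRPoint(float(conf_arr[k]), tp, fp, n_gt - tp))
    return points


def average_precision(curve: Sequence[PRPoint]) -> float:
    """COCO-style AP: interpolated precision averaged over 101 recall points.

    For each reference recall r in {0, 0.01, ..., 1}, the interpolated
    precision is the maximum precision among curve points with recall >= r
    (zero when the recall level is never reached).
    """
    if not curve:
        raise ValueError("empty precision-recall curve")
    recalls = np.array([p.recall for p in curve])
    precisions = np.array([p.precision for p in curve])
    total = 0.0
    for r in np.linspace(0.0, 1.0, N_RECALL_POINTS):
        mask = recalls >= r - 1e-12
        total += precisions[mask].max() if mask.any() else 0.0
    return total / N_RECALL_POINTS


def map_over(
    preds: Mapping[int, Sequence[BoundingBox]],
    gts: Mapping[int, Sequence[BoundingBox]],
    iou_thresholds: Sequence[float] = COCO_IOU_THRESHOLDS,
) -> EvalReport:
    """Per-class AP at each IOU threshold, mAP, and the F1-best threshold.

    ``map_at[t]`` is the class mean of AP at IOU threshold ``t``;
    ``map_mean`` averages those over the threshold ladder.  The operating
    point reported is the confidence threshold maximizing F1 at IOU 0.5.
    """
    classes = sorted({g.cls for v in gts.values() for g in v})
    if not classes:
        raise ValueError("no ground-truth classes")
    ap_per_class: dict = {c: {} for c in classes}
    for c in classes:
        p_c = {f: [b for b in v if b.cls == c] for f, v in preds.items()}
        g_c = {f: [b for b in v if b.cls == c] for f, v in gts.items()}
        for t in iou_thresholds:
            curve = pr_curve(p_c, g_c, t)
            ap_per_class[c][t] = average_precision(curve) if curve else 0.0
    map_at = {
        t: float(np.mean([ap_per_class[c][t] for c in classes]))
        for t in iou_thresholds
    }
    map_mean = float(np.mean(list(map_at.values())))

    curve_50 = pr_curve(preds, gts, 0.5)
    best = max(curve_50, key=lambda p: (p.f1, p.conf_threshold))
    return EvalReport(
        ap_per_class=ap_per_class,
        map_at=map_at,
        map_mean=map_mean,
        best_conf=best.conf_threshold,
        precision_at_best=best.precision,
        recall_at_best=best.recall,
        f1_at_best=best.f1,
    )


def annotator_reliability(
    pairs: Sequence[tuple[BoundingBox, BoundingBox]]
) -> tuple[float, float]:
    """Median and interquartile range of pairwise IOUs of matched annotations."""
    if not pairs:
        raise ValueError("no annotation pairs")
    ious = np.array([iou(a, b) for a, b in pairs])
    q25, q50, q75 = np.percentile(ious, [25, 50, 75])
    return float(q50), float(q75 - q25)


def boxes_by_frame(df: pd.DataFrame, with_conf: bool = True) -> dict[int, list[BoundingBox]]:
    """Group a detection/annotation table into per-frame box lists."""
    needed = ["frame", "cls", "cx", "cy", "w", "h"] + (["conf"] if with_conf else [])
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing}")
    out: dict[int, list[BoundingBox]] = {}
    for row in df.itertuples(index=False):
        box = BoundingBox(
            cx=float(row.cx),
            cy=float(row.cy),
            w=float(row.w),
            h=float(row.h),
            cls=row.cls,
            conf=float(row.conf) if with_conf else None,
        )
        out.setdefault(int(row.frame), []).append(box)
    return out
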