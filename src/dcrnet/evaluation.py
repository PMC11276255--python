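"""COCO-style detection evaluation and stained/unstained counting reports.

AP is the mean, over IoU thresholds 0.50:0.05:0.95 and over the two cell
classes, of the 101-point-interpolated area under the precision–recall curve
obtained by greedy confidence-ordered matching (each ground truth matched at
most once per threshold).  Size-stratified variants (APS/APM/APL) restrict
ground truths to an area stratum; detections outside the stratum that match
nothing are ignored rather than counted as false positives.  All AP figures
are reported on the 0–100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

IOU_THRESHOLDS = np.round(np.arange(0.50, 0.96, 0.05), 2)
RECALL_GRID = np.linspace(0.0, 1.0, 101)

SMALL_MAX_AREA = 32 * 32      # exclusive upper bound of the small stratum
MEDIUM_MAX_AREA = 96 * 96     # inclusive upper bound of the medium stratum

AREA_RANGES: dict[str, tuple[float, float]] = {
    "all": (0.0, float("inf")),
    # strata on box area: small < 32², 32² <= medium <= 96², large > 96²
    "small": (0.0, SMALL_MAX_AREA),
    "medium": (SMALL_MAX_AREA, MEDIUM_MAX_AREA + 1),
    "large": (MEDIUM_MAX_AREA + 1, float("inf")),
}


@dataclass(frozen=True)
class Detection:
    """A predicted box (0-based half-open pixels) with class and confidence."""

    box: tuple[float, float, float, float]
    label: str
    confidence: float

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.box
        return max(0.0, x1 - x0) * max(0.0, y1 - y0)


@dataclass
class APReport:
    """Average-precision summary on the 0-100 scale; ``None`` marks strata
    with no ground truth (undefined, never silently zero)."""

    ap: float | None
    ap50: float | None
    ap75: float | None
    ap_small: float | None
    ap_medium: float | None
    ap_large: float | None

    def to_dict(self) -> dict:
        return {"AP": self.ap, "AP50": self.ap50, "AP75": self.ap75,
                "APS": self.ap_small, "APM": self.ap_medium, "APL": self.ap_large}


@dataclass
class CountSummary:
    stained: int
    unstained: int

    @property
    def total(self) -> int:
        return self.stained + self.unstained

    @property
    def unstained_rate(self) -> float | None:
        return None if self.total == 0 else self.unstained / self.total

    def to_dict(self) -> dict:
        return {"stained": self.stained, "unstained": self.unstained,
                "total": self.total, "unstained_rate": self.unstained_rate}


@dataclass
class CountComparison:
    summary_auto: CountSummary
    summary_ref: CountSummary

    @property
    def rate_difference(self) -> float:
        ra, rr = self.summary_auto.unstained_rate, self.summary_ref.unstained_rate
        if ra is None or rr is None:
            raise ValueError("rate comparison undefined for empty counts")
        return abs(ra - rr)

    @property
    def rate_difference_percent(self) -> float:
        return 100.0 * self.rate_difference


def iou(box_a: Sequence[float], box_b: Sequence[float]) -> float:
    """Intersection over union of two half-open boxes; 0 for degenerate
    boxes by convention."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    area_a = max(0.0, ax1 - ax0) * max(0.0, ay1 - ay0)
    area_b = max(0.0, bx1 - bx0) * max(0.0, by1 - by0)
    if area_a <= 0.0 or area_b <= 0.0:
        return 0.0
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def size_class(box: Sequence[float]) -> str:
    """COCO-style stratum of a box by area: small < 32², medium in
    [32², 96²] (closed band), large > 96²."""
    x0, y0, x1, y1 = box
    area = (x1 - x0) * (y1 - y0)
    if area < SMALL_MAX_AREA:
        return "small"
    if area <= MEDIUM_MAX_AREA:
        return "medium"
    return "large"


class UndefinedAPError(ValueError):
    """Raised when AP is requested but no ground truth exists at all."""


def _interpolated_ap(scores: np.ndarray, matched: np.ndarray, ignored: np.ndarray,
                     n_gt: int) -> float:
    """101-point interpolated AP from per-detection outcomes (already pooled
    over images, any order)."""
    if len(scores) == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    matched = matched[order]
    keep = ~ignored[order]
    tp = np.cumsum(matched & keep)
    fp = np.cumsum(~matched & keep)
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    # precision envelope, then sample at the 101 recall points
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    idx = np.searchsorted(recall, RECALL_GRID, side="left")
    sampled = np.where(idx < len(prec_env), prec_env[np.minimum(idx, max(len(prec_env) - 1, 0))], 0.0)
    if len(prec_env) == 0:
        return 0.0
    return float(sampled.mean())


def _match_class(dets_by_img: Mapping, gts_by_img: Mapping, label: str,
                 threshold: float, area_range: tuple[float, float]) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Greedy confidence-ordered matching for one class / IoU threshold /
    area stratum.  Returns per-detection (scores, matched, ignored) pooled
    over images plus the number of counted ground truths."""
    lo, hi = area_range
    all_scores: list[float] = []
    all_matched: list[bool] = []
    all_ignored: list[bool] = []
    n_gt = 0
    img_ids = set(dets_by_img) | set(gts_by_img)
    for img_id in sorted(img_ids, key=str):
        gts = [g for g in gts_by_img.get(img_id, []) if g.label == label]
        gt_boxes = [g.box for g in gts]
        gt_area = np.array([(b[2] - b[0]) * (b[3] - b[1]) for b in gt_boxes], dtype=float)
        gt_ignore = ~((gt_area >= lo) & (gt_area < hi)) if len(gts) else np.zeros(0, bool)
        n_gt += int((~gt_ignore).sum())
        dets = sorted((d for d in dets_by_img.get(img_id, []) if d.label == label),
                      key=lambda d: -d.confidence)
        taken = np.zeros(len(gts), dtype=bool)
        for d in dets:
            # highest-IoU free GT at or above the threshold; a detection may
            # fall back to an ignored GT only when no counted GT qualifies
            best = -1
            for prefer_counted in (True, False):
                best_iou = threshold
                for j, gb in enumerate(gt_boxes):
                    if taken[j] or gt_ignore[j] == prefer_counted:
                        continue
                    ov = iou(d.box, gb)
                    if ov >= best_iou:
                        best, best_iou = j, ov
                if best >= 0:
                    break
            if best >= 0:
                taken[best] = True
                all_scores.append(d.confidence)
                all_matched.append(True)
                all_ignored.append(bool(gt_ignore[best]))
            else:
                in_range = lo <= d.area < hi
                all_scores.append(d.confidence)
                all_matched.append(False)
                all_ignored.append(not in_range)
    return (np.array(all_scores), np.array(all_matched, bool),
            np.array(all_ignored, bool), n_gt)


def _ap_for_range(dets_by_img, gts_by_img, labels, thresholds, area_range) -> float | None:
    aps = []
    for label in labels:
        per_thr = []
        for thr in thresholds:
            scores, matched, ignored, n_gt = _match_class(
                dets_by_img, gts_by_img, label, thr, area_range)
            if n_gt == 0:
                per_thr = None
                break
            per_thr.append(_interpolated_ap(scores, matched, ignored, n_gt))
        if per_thr is not None:
            aps.append(float(np.mean(per_thr)))
    if not aps:
        return None
    return 100.0 * float(np.mean(aps))


def evaluate(dets_by_img: Mapping[object, Sequence[Detection]],
             gts_by_img: Mapping[object, Sequence],
             labels: Iterable[str] = ("stained", "unstained")) -> APReport:
    """Compute the AP report over a set of images.

    ``gts_by_img`` maps image ids to objects with ``.box`` / ``.label``
    (e.g. :class:`dcrnet.data.Annotation`).  Raises
    :class:`UndefinedAPError` when there is no ground truth at all.
    """
    labels = list(labels)
    if not any(gts_by_img.get(k) for k in gts_by_img):
        raise UndefinedAPError("no ground truth boxes: AP is undefined")
    return APReport(
        ap=_ap_for_range(dets_by_img, gts_by_img, labels, IOU_THRESHOLDS, AREA_RANGES["all"]),
        ap50=_ap_for_range(dets_by_img, gts_by_img, labels, [0.50], AREA_RANGES["all"]),
        ap75=_ap_for_range(dets_by_img, gts_by_img, labels, [0.75], AREA_RANGES["all"]),
        ap_small=_ap_for_range(dets_by_img, gts_by_img, labels, IOU_THRESHOLDS, AREA_RANGES["small"]),
        ap_medium=_ap_for_range(dets_by_img, gts_by_img, labels, IOU_THRESHOLDS, AREA_RANGES["medium"]),
        ap_large=_ap_for_range(dets_by_img, gts_by_img, labels, IOU_THRESHOLDS, AREA_RANGES["large"]),
    )


def count_cells(detections: Iterable[Detection],
                confidence_threshold: float = 0.5) -> CountSummary:
    """Count stained/unstained detections above a confidence threshold."""
    stained = unstained = 0
    for d in detections:
        if d.confidence < confidence_threshold:
            continue
        if d.label == "stained":
            stained += 1
        elif d.label == "unstained":
            unstained += 1
        else:
            raise ValueError(f"unknown label {d.label!r}")
    return CountSummary(stained=stained, unstained=unstained)


def compare_counts(auto: CountSummary, ref: CountSummary) -> CountComparison:
    """Automatic-vs-reference comparison of unstained rates."""
    if auto.total == 0 or ref.total == 0:
        raise ValueError("cannot compare counts with an empty total")
    return CountComparison(summary_auto=auto, summary_ref=ref)
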