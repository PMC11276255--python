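"""Two-stage cell detector on DCRNet pyramid features.

Stage one, a region-proposal network (RPN), scores a dense grid of anchors
on every pyramid level for objectness and regresses candidate boxes; after
non-maximum suppression the surviving proposals are pooled to a fixed
spatial size (RoI align) and a small fully connected head classifies each
region as stained, unstained or background and refines its box.

The training curriculum mirrors the published recipe: a warm-up phase on
low-resolution tiles (640×480 or smaller) followed by the complete training
set, batch size 4, loss recorded every five iterations — all scalable by a
single desk-scale factor so the same code trains a miniature network on a
laptop CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
import numpy as np

from . import autograd as ag
from .autograd import SGD, Tensor
from .backbone import DCRNet, BackboneConfig
from .data import AnnotatedImage, DatasetSplit, resize_canonical
from .evaluation import Detection, iou
from .nn import Conv2d, Linear, Module

CLASS_NAMES = ("stained", "unstained")          # head classes 1, 2; 0 = background


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class AnchorConfig:
    """Anchor layout: one tuple of scales per pyramid level, shared aspect
    ratios, per-level strides.  Anchor count per level is
    H × W × (#scales × #ratios)."""

    scales: tuple[tuple[float, ...], ...] = ((32.0,), (64.0,), (128.0,), (256.0,))
    ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    strides: tuple[int, ...] = (4, 8, 16, 32)

    def __post_init__(self):
        if len(self.scales) != len(self.strides):
            raise ValueError("one scale tuple per pyramid level required")
        if any(s <= 0 for lv in self.scales for s in lv) or any(r <= 0 for r in self.ratios):
            raise ValueError("anchor scales and ratios must be positive")

    @property
    def per_location(self) -> tuple[int, ...]:
        return tuple(len(lv) * len(self.ratios) for lv in self.scales)


@dataclass(frozen=True)
class RegionProposal:
    box: tuple[float, float, float, float]
    objectness: float


@dataclass(frozen=True)
class DetectorConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    anchors: AnchorConfig = field(default_factory=AnchorConfig)
    input_size: tuple[int, int] | None = (1800, 1200)   # (w, h); None = native
    roi_size: int = 7
    rpn_pos_iou: float = 0.7
    rpn_neg_iou: float = 0.3
    rpn_batch: int = 256
    rpn_pos_fraction: float = 0.5
    pre_nms_top_n: int = 1000
    nms_thresh: float = 0.7
    proposals_train: int = 1000
    proposals_test: int = 300
    roi_pos_iou: float = 0.5
    roi_batch: int = 64
    roi_pos_fraction: float = 0.25
    detection_nms: float = 0.5
    score_threshold: float = 0.05
    confidence_threshold: float = 0.5        # counting threshold, exposed not hard-coded
    head_width: int = 256

    @classmethod
    def desk_scale(cls, plain: bool = False) -> "DetectorConfig":
        """Miniature detector for CPU-scale training on 320×240 fields."""
        return cls(
            backbone=BackboneConfig.desk_scale(plain=plain),
            anchors=AnchorConfig(scales=((14.0, 22.0), (30.0, 44.0), (60.0, 88.0),
                                         (120.0, 176.0)),
                                 ratios=(0.7, 1.0, 1.4), strides=(4, 8, 16, 32)),
            input_size=None,
            pre_nms_top_n=400, proposals_train=300, proposals_test=150,
            roi_batch=48, head_width=96,
        )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["backbone"] = self.backbone.to_dict()
        d["anchors"] = {"scales": [list(s) for s in self.anchors.scales],
                        "ratios": list(self.anchors.ratios),
                        "strides": list(self.anchors.strides)}
        d["input_size"] = list(self.input_size) if self.input_size else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        d = dict(d)
        d["backbone"] = BackboneConfig.from_dict(d["backbone"])
        a = d["anchors"]
        d["anchors"] = AnchorConfig(scales=tuple(tuple(s) for s in a["scales"]),
                                    ratios=tuple(a["ratios"]), strides=tuple(a["strides"]))
        if d.get("input_size"):
            d["input_size"] = tuple(d["input_size"])
        return cls(**d)


# ---------------------------------------------------------------------------
# box utilities (numpy, outside the autograd graph)
# ---------------------------------------------------------------------------

def generate_anchors(h: int, w: int, stride: int, scales, ratios) -> np.ndarray:
    """Dense anchors for one level, (H*W*A, 4) half-open boxes, ordered
    row-major by position then (scale, ratio)."""
    ws, hs = [], []
    for s in scales:
        for r in ratios:
            ws.append(s / np.sqrt(r))
            hs.append(s * np.sqrt(r))
    ws = np.asarray(ws)
    hs = np.asarray(hs)
    cx = (np.arange(w) + 0.5) * stride
    cy = (np.arange(h) + 0.5) * stride
    cyy, cxx = np.meshgrid(cy, cx, indexing="ij")
    centers = np.stack([cxx.ravel(), cyy.ravel()], axis=1)      # (HW, 2)
    boxes = np.empty((h * w, len(ws), 4))
    boxes[:, :, 0] = centers[:, None, 0] - ws[None, :] / 2
    boxes[:, :, 1] = centers[:, None, 1] - hs[None, :] / 2
    boxes[:, :, 2] = centers[:, None, 0] + ws[None, :] / 2
    boxes[:, :, 3] = centers[:, None, 1] + hs[None, :] / 2
    return boxes.reshape(-1, 4)


def encode_boxes(anchors: np.ndarray, gt: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + aw / 2
    ay = anchors[:, 1] + ah / 2
    gw = gt[:, 2] - gt[:, 0]
    gh = gt[:, 3] - gt[:, 1]
    gx = gt[:, 0] + gw / 2
    gy = gt[:, 1] + gh / 2
    return np.stack([(gx - ax) / aw, (gy - ay) / ah,
                     np.log(gw / aw), np.log(gh / ah)], axis=1)


def decode_boxes(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + aw / 2
    ay = anchors[:, 1] + ah / 2
    dx, dy, dw, dh = deltas[:, 0], deltas[:, 1], deltas[:, 2], deltas[:, 3]
    dw = np.clip(dw, -4.0, 4.0)
    dh = np.clip(dh, -4.0, 4.0)
    cx = ax + dx * aw
    cy = ay + dy * ah
    w = aw * np.exp(dw)
    h = ah * np.exp(dh)
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    iw = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    ih = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    return inter / (area_a[:, None] + area_b[None, :] - inter + 1e-9)


def nms(boxes: np.ndarray, scores: np.ndarray, threshold: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices in score order."""
    order = np.argsort(-scores, kind="stable")
    kept = []
    if len(boxes) <= 2048:
        iou_mat = box_iou_matrix(boxes, boxes)
        suppressed = np.zeros(len(boxes), dtype=bool)
        for i in order:
            if suppressed[i]:
                continue
            kept.append(i)
            suppressed |= iou_mat[i] > threshold
    else:
        suppressed = np.zeros(len(boxes), dtype=bool)
        for i in order:
            if suppressed[i]:
                continue
            kept.append(i)
            suppressed |= box_iou_matrix(boxes[i:i + 1], boxes)[0] > threshold
    return np.asarray(kept, dtype=np.int64)


# ---------------------------------------------------------------------------
# network heads
# ---------------------------------------------------------------------------

class RPNHead(Module):
    def __init__(self, in_ch: int, anchors_per_loc: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_ch, in_ch, 3, rng, padding=1, bias=True)
        self.cls = Conv2d(in_ch, anchors_per_loc, 1, rng, bias=True)
        self.reg = Conv2d(in_ch, 4 * anchors_per_loc, 1, rng, bias=True)

    def forward(self, feat: Tensor) -> tuple[Tensor, Tensor]:
        x = ag.relu(self.conv(feat))
        return self.cls(x), self.reg(x)


class RoIHead(Module):
    def __init__(self, in_ch: int, roi_size: int, width: int, n_classes: int,
                 rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(in_ch * roi_size * roi_size, width, rng)
        self.fc2 = Linear(width, width, rng)
        self.cls = Linear(width, n_classes, rng, std=0.01)
        self.reg = Linear(width, 4, rng, std=0.001)  # class-agnostic refinement

    def forward(self, pooled: Tensor) -> tuple[Tensor, Tensor]:
        x = ag.reshape(pooled, (pooled.shape[0], -1))
        x = ag.relu(self.fc1(x))
        x = ag.relu(self.fc2(x))
        return self.cls(x), self.reg(x)


class CellDetector(Module):
    """DCRNet backbone + RPN + RoI classification head."""

    def __init__(self, cfg: DetectorConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.backbone = DCRNet(cfg.backbone, rng)
        per_loc = cfg.anchors.per_location
        if len(set(per_loc)) != 1:
            raise ValueError("all pyramid levels must share the anchors-per-location count")
        self.rpn = RPNHead(cfg.backbone.fpn_channels, per_loc[0], rng)
        self.roi_head = RoIHead(cfg.backbone.fpn_channels, cfg.roi_size,
                                cfg.head_width, 1 + len(CLASS_NAMES), rng)
        self.trained = False

    # -- pieces ---------------------------------------------------------------
    def features(self, images: Tensor) -> list[Tensor]:
        return self.backbone(images)

    def anchors_for(self, feats: list[Tensor]) -> list[np.ndarray]:
        a = self.cfg.anchors
        return [generate_anchors(f.shape[2], f.shape[3], a.strides[i], a.scales[i], a.ratios)
                for i, f in enumerate(feats)]

    def rpn_forward(self, feats: list[Tensor]) -> tuple[list[Tensor], list[Tensor]]:
        logits, deltas = [], []
        for f in feats:
            lg, dl = self.rpn(f)
            logits.append(lg)
            deltas.append(dl)
        return logits, deltas

    def propose(self, feats: list[Tensor], image_hw: tuple[int, int],
                training: bool = False) -> list[list[RegionProposal]]:
        """Top-N region proposals per image after objectness scoring, box
        decoding and NMS."""
        if not feats:
            raise ValueError("empty feature pyramid")
        logits, deltas = self.rpn_forward(feats)
        return self._proposals_from_outputs(feats, logits, deltas, image_hw, training)

    def _proposals_from_outputs(self, feats, logits, deltas, image_hw, training
                                ) -> list[list[RegionProposal]]:
        cfg = self.cfg
        H, W = image_hw
        N = feats[0].shape[0]
        anchors = self.anchors_for(feats)
        out: list[list[RegionProposal]] = []
        for n in range(N):
            boxes_all, scores_all = [], []
            for lvl, (lg, dl) in enumerate(zip(logits, deltas)):
                A = lg.shape[1]
                sc = lg.data[n].transpose(1, 2, 0).reshape(-1)               # (HWA,)
                dd = dl.data[n].reshape(A, 4, lg.shape[2], lg.shape[3])
                dd = dd.transpose(2, 3, 0, 1).reshape(-1, 4)
                k = min(cfg.pre_nms_top_n, len(sc))
                top = np.argpartition(-sc, k - 1)[:k] if k < len(sc) else np.arange(len(sc))
                bx = decode_boxes(anchors[lvl][top], dd[top])
                bx[:, 0::2] = np.clip(bx[:, 0::2], 0, W)
                bx[:, 1::2] = np.clip(bx[:, 1::2], 0, H)
                ok = (bx[:, 2] - bx[:, 0] >= 2) & (bx[:, 3] - bx[:, 1] >= 2)
                boxes_all.append(bx[ok])
                scores_all.append(sc[top][ok])
            boxes = np.concatenate(boxes_all)
            scores = np.concatenate(scores_all)
            keep = nms(boxes, scores, cfg.nms_thresh)
            n_keep = cfg.proposals_train if training else cfg.proposals_test
            keep = keep[:n_keep]
            sig = 1.0 / (1.0 + np.exp(-scores[keep]))
            out.append([RegionProposal(tuple(b), float(s))
                        for b, s in zip(boxes[keep], sig)])
        return out

    def _roi_level(self, boxes: np.ndarray) -> np.ndarray:
        """FPN level assignment by box scale (canonical heuristic)."""
        area = np.clip((boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1]), 1, None)
        lvl = np.floor(np.log2(np.sqrt(area) / 224.0) + 3.0 + 1e-6)
        return np.clip(lvl, 0, len(self.cfg.anchors.strides) - 1).astype(np.int64)

    def pool_rois(self, feats: list[Tensor], rois: np.ndarray) -> tuple[Tensor, np.ndarray]:
        """RoI-align rois (R, 5: batch,x0,y0,x1,y1) on their assigned pyramid
        level; returns pooled features and the permutation applied to rows."""
        cfg = self.cfg
        levels = self._roi_level(rois[:, 1:])
        pooled_parts, order_parts = [], []
        for lvl in range(len(feats)):
            sel = np.flatnonzero(levels == lvl)
            if not len(sel):
                continue
            pooled_parts.append(ag.roi_align(
                feats[lvl], rois[sel], out_size=cfg.roi_size,
                spatial_scale=1.0 / cfg.anchors.strides[lvl]))
            order_parts.append(sel)
        order = np.concatenate(order_parts) if order_parts else np.zeros(0, np.int64)
        pooled = ag.concat(pooled_parts, axis=0) if pooled_parts else None
        return pooled, order

    def classify_regions(self, feats: list[Tensor],
                         proposals: list[list[RegionProposal]]) -> list[list[Detection]]:
        """Pool, classify and refine each proposal; drop background, apply
        per-class NMS and the score threshold."""
        cfg = self.cfg
        results: list[list[Detection]] = []
        for n, props in enumerate(proposals):
            if not props:
                results.append([])
                continue
            boxes = np.array([p.box for p in props])
            rois = np.concatenate([np.full((len(boxes), 1), n, dtype=float), boxes], axis=1)
            pooled, order = self.pool_rois(feats, rois)
            cls_logits, reg = self.roi_head(pooled)
            probs = ag.softmax(cls_logits.data, axis=1)
            refined = decode_boxes(boxes[order], reg.data)
            dets: list[Detection] = []
            for ci, cname in enumerate(CLASS_NAMES, start=1):
                scores = probs[:, ci]
                labels_best = probs.argmax(axis=1)
                sel = np.flatnonzero((labels_best == ci) & (scores >= cfg.score_threshold))
                if not len(sel):
                    continue
                keep = nms(refined[sel], scores[sel], cfg.detection_nms)
                for i in sel[keep]:
                    x0, y0, x1, y1 = refined[i]
                    if x1 - x0 < 1 or y1 - y0 < 1:
                        continue
                    dets.append(Detection((float(x0), float(y0), float(x1), float(y1)),
                                          cname, float(min(max(scores[i], 0.0), 1.0))))
            results.append(dets)
        return results


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainingSchedule:
    """Curriculum: a list of (subset_name, epochs) phases.

    ``low_res`` selects images whose resolution is 640×480 or smaller; ``all``
    the complete set.  Defaults reproduce the published recipe (30 warm-up
    epochs on low-resolution tiles, then 270 on everything, batch 4, loss
    logged every 5 iterations); ``scale`` shrinks the epoch counts for
    desk-scale runs.
    """

    phases: list[tuple[str, int]] = field(default_factory=lambda: [("low_res", 30), ("all", 270)])
    batch_size: int = 4
    loss_log_interval: int = 5
    learning_rate: float = 0.02 * 4 / 16
    momentum: float = 0.9
    weight_decay: float = 1e-4
    warmup_iterations: int = 100
    grad_clip: float = 10.0
    rng_seed: int = 0
    max_iterations: int | None = None    # cap across all phases (desk runs)

    def __post_init__(self):
        if self.batch_size <= 0 or any(e <= 0 for _, e in self.phases):
            raise ValueError("batch size and phase epochs must be positive")


def build_schedule(split: DatasetSplit, scale: float = 1.0, seed: int = 0) -> TrainingSchedule:
    """Schedule for a dataset split; epochs scaled by ``scale``."""
    for img in split.train:
        if not getattr(img, "resolution_tag", None):
            raise ValueError("training images must carry a resolution tag")
    return TrainingSchedule(
        phases=[("low_res", max(1, round(30 * scale))), ("all", max(1, round(270 * scale)))],
        rng_seed=seed)


def _is_low_res(img: AnnotatedImage) -> bool:
    return img.width * img.height <= 640 * 480


def _prepare_batch(images: list[AnnotatedImage], input_size) -> tuple[Tensor, list[AnnotatedImage]]:
    if input_size is not None:
        images = [resize_canonical(im, input_size) for im in images]
    arr = np.stack([im.image for im in images]).astype(np.float32)
    arr = (arr / 255.0 - 0.5) / 0.25
    return Tensor(arr.transpose(0, 3, 1, 2)), images


def _rpn_targets(anchors: np.ndarray, gt_boxes: np.ndarray, image_hw, cfg: DetectorConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-anchor labels (1/0/-1 = pos/neg/ignore) and encoded regression
    targets for one image."""
    A = len(anchors)
    labels = np.full(A, -1, dtype=np.int64)
    targets = np.zeros((A, 4))
    H, W = image_hw
    inside = ((anchors[:, 0] >= -8) & (anchors[:, 1] >= -8) &
              (anchors[:, 2] <= W + 8) & (anchors[:, 3] <= H + 8))
    if len(gt_boxes):
        ious = box_iou_matrix(anchors, gt_boxes)
        best_gt = ious.argmax(axis=1)
        best_iou = ious[np.arange(A), best_gt]
        labels[inside & (best_iou < cfg.rpn_neg_iou)] = 0
        labels[inside & (best_iou >= cfg.rpn_pos_iou)] = 1
        # every GT claims its best anchor even below the threshold
        per_gt_best = ious.max(axis=0)
        is_best = np.abs(ious - per_gt_best[None, :]) < 1e-9
        claim_rows, claim_cols = np.nonzero(is_best)
        labels[claim_rows] = 1
        best_gt[claim_rows] = claim_cols
        pos = labels == 1
        targets[pos] = encode_boxes(anchors[pos], gt_boxes[best_gt[pos]])
    else:
        labels[inside] = 0
    # subsample to the RPN mini-batch
    pos_idx = np.flatnonzero(labels == 1)
    n_pos_max = int(cfg.rpn_batch * cfg.rpn_pos_fraction)
    if len(pos_idx) > n_pos_max:
        drop = rng.choice(pos_idx, len(pos_idx) - n_pos_max, replace=False)
        labels[drop] = -1
        pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    n_neg = cfg.rpn_batch - len(pos_idx)
    if len(neg_idx) > n_neg:
        drop = rng.choice(neg_idx, len(neg_idx) - n_neg, replace=False)
        labels[drop] = -1
    return labels, targets


def _sample_rois(proposals: np.ndarray, gt_boxes: np.ndarray, gt_labels: np.ndarray,
                 cfg: DetectorConfig, rng: np.random.Generator):
    """Sample training RoIs (GT boxes are appended as proposals); returns
    (rois, class labels with 0 = background, regression targets)."""
    if len(gt_boxes):
        cand = np.concatenate([proposals, gt_boxes]) if len(proposals) else gt_boxes
    else:
        cand = proposals
    if not len(cand):
        return cand, np.zeros(0, np.int64), np.zeros((0, 4))
    labels = np.zeros(len(cand), dtype=np.int64)
    targets = np.zeros((len(cand), 4))
    if len(gt_boxes):
        ious = box_iou_matrix(cand, gt_boxes)
        best = ious.argmax(axis=1)
        best_iou = ious[np.arange(len(cand)), best]
        pos = best_iou >= cfg.roi_pos_iou
        labels[pos] = gt_labels[best[pos]]
        targets[pos] = encode_boxes(cand[pos], gt_boxes[best[pos]])
    pos_idx = np.flatnonzero(labels > 0)
    neg_idx = np.flatnonzero(labels == 0)
    n_pos = min(len(pos_idx), int(cfg.roi_batch * cfg.roi_pos_fraction))
    n_neg = min(len(neg_idx), cfg.roi_batch - n_pos)
    sel = np.concatenate([
        rng.choice(pos_idx, n_pos, replace=False) if n_pos else np.zeros(0, np.int64),
        rng.choice(neg_idx, n_neg, replace=False) if n_neg else np.zeros(0, np.int64)])
    return cand[sel], labels[sel], targets[sel]


def compute_losses(model: CellDetector, batch: list[AnnotatedImage],
                   rng: np.random.Generator) -> tuple[Tensor, dict[str, float]]:
    """Joint RPN + RoI-head loss for one mini-batch of equally sized images."""
    cfg = model.cfg
    images, batch = _prepare_batch(batch, cfg.input_size)
    H, W = images.shape[2], images.shape[3]
    feats = model.features(images)
    logits, deltas = model.rpn_forward(feats)
    anchors = model.anchors_for(feats)
    anchors_cat = np.concatenate(anchors)
    N = images.shape[0]

    # flatten RPN outputs to (N, total_anchors) in anchor order
    flat_logits, flat_deltas = [], []
    for lg, dl in zip(logits, deltas):
        A = lg.shape[1]
        h, w = lg.shape[2], lg.shape[3]
        flat_logits.append(ag.reshape(ag.permute(lg, (0, 2, 3, 1)), (N, h * w * A)))
        d5 = ag.reshape(dl, (N, A, 4, h, w))
        flat_deltas.append(ag.reshape(ag.permute(d5, (0, 3, 4, 1, 2)), (N, h * w * A, 4)))
    rpn_logits = ag.concat(flat_logits, axis=1)          # (N, At)
    rpn_deltas = ag.concat(flat_deltas, axis=1)          # (N, At, 4)

    lbl_rows, tgt_rows = [], []
    gt_per_image = []
    for n in range(N):
        gt_boxes = np.array([a.box for a in batch[n].annotations], dtype=float).reshape(-1, 4)
        gt_labels = np.array([1 + CLASS_NAMES.index(a.label) for a in batch[n].annotations],
                             dtype=np.int64)
        gt_per_image.append((gt_boxes, gt_labels))
        lbl, tgt = _rpn_targets(anchors_cat, gt_boxes, (H, W), cfg, rng)
        lbl_rows.append(lbl)
        tgt_rows.append(tgt)
    labels = np.stack(lbl_rows)            # (N, At)
    targets = np.stack(tgt_rows)

    sample_w = (labels >= 0).astype(np.float64)
    rpn_cls = ag.sigmoid_bce(ag.reshape(rpn_logits, (-1,)),
                             (labels == 1).astype(float).ravel(), sample_w.ravel())
    pos_w = (labels == 1).astype(np.float64).ravel()
    rpn_reg = ag.smooth_l1(ag.reshape(rpn_deltas, (-1, 4)), targets.reshape(-1, 4),
                           pos_w, beta=1.0 / 9.0,
                           normalizer=max(float(sample_w.sum()), 1.0))

    # stage 2: sample RoIs from the proposals of the current RPN
    with ag.no_grad():
        proposals = model._proposals_from_outputs(
            feats, [Tensor(l.data) for l in logits], [Tensor(d.data) for d in deltas],
            (H, W), training=True)
    roi_rows, roi_labels, roi_targets = [], [], []
    for n in range(N):
        pboxes = np.array([p.box for p in proposals[n]]).reshape(-1, 4)
        gt_boxes, gt_labels = gt_per_image[n]
        rois, lbls, tgts = _sample_rois(pboxes, gt_boxes, gt_labels, cfg, rng)
        if len(rois):
            roi_rows.append(np.concatenate(
                [np.full((len(rois), 1), n, dtype=float), rois], axis=1))
            roi_labels.append(lbls)
            roi_targets.append(tgts)
    parts: dict[str, float] = {}
    if roi_rows:
        rois = np.concatenate(roi_rows)
        rlabels = np.concatenate(roi_labels)
        rtargets = np.concatenate(roi_targets)
        pooled, order = model.pool_rois(feats, rois)
        cls_logits, reg = model.roi_head(pooled)
        rlabels = rlabels[order]
        rtargets = rtargets[order]
        roi_cls = ag.softmax_cross_entropy(cls_logits, rlabels)
        roi_reg = ag.smooth_l1(reg, rtargets, (rlabels > 0).astype(np.float64),
                               beta=1.0, normalizer=max(float(len(rlabels)), 1.0))
        total = ag.add(ag.add(rpn_cls, rpn_reg), ag.add(roi_cls, roi_reg))
        parts["roi_cls"] = float(roi_cls.data)
        parts["roi_reg"] = float(roi_reg.data)
    else:
        total = ag.add(rpn_cls, rpn_reg)
    parts["rpn_cls"] = float(rpn_cls.data)
    parts["rpn_reg"] = float(rpn_reg.data)
    parts["total"] = float(total.data)
    return total, parts


def train(model: CellDetector, images: list[AnnotatedImage],
          schedule: TrainingSchedule, checkpoint_path=None,
          progress: bool = False) -> list[dict]:
    """Train the detector; returns the loss trace (one record per
    ``loss_log_interval`` iterations).

    Aborts with :class:`TrainingDivergedError` on a non-finite loss, saving
    the last finite state when a checkpoint path is given.
    """
    rng = np.random.default_rng(schedule.rng_seed)
    model.train()
    opt = SGD(model.parameters(), lr=schedule.learning_rate,
              momentum=schedule.momentum, weight_decay=schedule.weight_decay)
    trace: list[dict] = []
    it = 0
    budget_exhausted = False
    for phase_name, epochs in schedule.phases:
        if budget_exhausted:
            break
        subset = [im for im in images if phase_name == "all" or _is_low_res(im)]
        if not subset:
            continue
        for epoch in range(epochs):
            if budget_exhausted:
                break
            order = rng.permutation(len(subset))
            for start in range(0, len(subset), schedule.batch_size):
                if schedule.max_iterations is not None and it >= schedule.max_iterations:
                    budget_exhausted = True
                    break
                batch = [subset[i] for i in order[start:start + schedule.batch_size]]
                # group by identical shapes (batches stack images)
                shape0 = batch[0].image.shape
                batch = [b for b in batch if b.image.shape == shape0]
                lr_scale = min(1.0, (it + 1) / max(schedule.warmup_iterations, 1))
                opt.lr = schedule.learning_rate * lr_scale
                loss, parts = compute_losses(model, batch, rng)
                if not np.isfinite(parts["total"]):
                    if checkpoint_path is not None:
                        save_checkpoint(model, checkpoint_path)
                    raise TrainingDivergedError(
                        f"non-finite loss at iteration {it}: {parts}")
                opt.zero_grad()
                loss.backward()
                opt.clip_grad_norm(schedule.grad_clip)
                opt.step()
                if it % schedule.loss_log_interval == 0:
                    trace.append({"iteration": it, "phase": phase_name,
                                  "epoch": epoch, **parts})
                    if progress:
                        print(f"iter {it} phase {phase_name} loss {parts['total']:.4f}")
                it += 1
    model.trained = True
    model.eval()
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    return trace


# ---------------------------------------------------------------------------
# inference and checkpoints
# ---------------------------------------------------------------------------

def detect(model: CellDetector, image: np.ndarray,
           score_threshold: float | None = None) -> list[Detection]:
    """Full pipeline on one RGB image: canonical resize, backbone, proposals,
    region classification; detections are mapped back to the original frame.
    """
    import warnings

    if not model.trained:
        warnings.warn("detector has not been trained; detections will be noise",
                      stacklevel=2)
    cfg = model.cfg
    if score_threshold is not None:
        object.__setattr__(model, "cfg", replace(cfg, score_threshold=score_threshold))
    try:
        model.eval()
        oh, ow = image.shape[:2]
        ai = AnnotatedImage(image, [], source_id="query")
        images, _ = _prepare_batch([ai], cfg.input_size)
        H, W = images.shape[2], images.shape[3]
        with ag.no_grad():
            feats = model.features(images)
            proposals = model.propose(feats, (H, W), training=False)
            dets = model.classify_regions(feats, proposals)[0]
        sx, sy = ow / W, oh / H
        out = []
        for d in dets:
            x0, y0, x1, y1 = d.box
            out.append(Detection((max(0.0, x0 * sx), max(0.0, y0 * sy),
                                  min(float(ow), x1 * sx), min(float(oh), y1 * sy)),
                                 d.label, d.confidence))
        return out
    finally:
        object.__setattr__(model, "cfg", cfg)


def detections_to_coco(dets_by_img: dict[object, list[Detection]]) -> list[dict]:
    """COCO-style result records: image_id, category_id, bbox [x, y, w, h],
    score (category 1 = stained, 2 = unstained)."""
    records = []
    for img_id, dets in dets_by_img.items():
        for d in dets:
            x0, y0, x1, y1 = d.box
            records.append({"image_id": img_id,
                            "category_id": 1 + CLASS_NAMES.index(d.label),
                            "bbox": [x0, y0, x1 - x0, y1 - y0],
                            "score": d.confidence})
    return records


CHECKPOINT_VERSION = 1


def save_checkpoint(model: CellDetector, path) -> None:
    state = model.state_dict()
    meta = json.dumps({"version": CHECKPOINT_VERSION, "trained": model.trained,
                       "config": model.cfg.to_dict()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> CellDetector:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        cfg = DetectorConfig.from_dict(meta["config"])
        model = CellDetector(cfg, seed=0)
        state = {k: z[k] for k in z.files if k != "__meta__"}
    model.load_state_dict(state)
    model.trained = bool(meta["trained"])
    model.eval()
    return model


def load_pretrained_backbone(model: CellDetector, path) -> None:
    """Hook to ingest externally pre-trained backbone weights (a checkpoint
    containing `backbone.*` entries)."""
    with np.load(path) as z:
        state = {k[len("backbone."):]: z[k] for k in z.files if k.startswith("backbone.")}
    if not state:
        raise ValueError(f"{path} contains no backbone weights")
    model.backbone.load_state_dict(state)
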