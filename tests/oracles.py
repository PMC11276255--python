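"""Independent reference implementations used as test oracles.

Everything here is written as plain scalar loops or direct transcriptions of
definitions, deliberately independent of the vectorised production code it
checks.
"""

from __future__ import annotations

import numpy as np


def deformable_conv_reference(x: np.ndarray, w: np.ndarray, offsets: np.ndarray,
                              stride: int = 1, padding: int = 1) -> np.ndarray:
    """Direct per-location evaluation of deformable convolution.

    Y(p0) = sum_{pn in R} w(pn) · X(p0 + pn + Δpn), with bilinear
    interpolation at fractional positions and zero outside the map.
    x: (C, H, W); w: (Co, C, kh, kw); offsets: (2*kh*kw, Ho, Wo).
    """
    C, H, W = x.shape
    Co, _, kh, kw = w.shape
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1

    def sample(c, py, px):
        y0, x0 = int(np.floor(py)), int(np.floor(px))
        ty, tx = py - y0, px - x0
        val = 0.0
        for dy, wy in ((0, 1 - ty), (1, ty)):
            for dx, wx in ((0, 1 - tx), (1, tx)):
                yy, xx = y0 + dy, x0 + dx
                if 0 <= yy < H and 0 <= xx < W:
                    val += wy * wx * x[c, yy, xx]
        return val

    y = np.zeros((Co, Ho, Wo))
    for oy in range(Ho):
        for ox in range(Wo):
            for co in range(Co):
                acc = 0.0
                k = 0
                for ki in range(kh):
                    for kj in range(kw):
                        dy = offsets[2 * k, oy, ox]
                        dx = offsets[2 * k + 1, oy, ox]
                        py = oy * stride - padding + ki + dy
                        px = ox * stride - padding + kj + dx
                        for c in range(C):
                            acc += w[co, c, ki, kj] * sample(c, py, px)
                        k += 1
                y[co, oy, ox] = acc
    return y


def conv2d_reference(x: np.ndarray, w: np.ndarray, stride: int = 1,
                     padding: int = 0) -> np.ndarray:
    """Scalar-loop standard convolution, (C,H,W) input."""
    K = w.shape[2] * w.shape[3]
    offsets = np.zeros((2 * K,) + _out_hw(x, w, stride, padding))
    return deformable_conv_reference(x, w, offsets, stride, padding)


def _out_hw(x, w, stride, padding):
    H, W = x.shape[1:]
    kh, kw = w.shape[2:]
    return ((H + 2 * padding - kh) // stride + 1, (W + 2 * padding - kw) // stride + 1)


def average_precision_reference(gt_boxes: list, det_boxes: list, det_scores: list,
                                iou_threshold: float) -> float:
    """Single-image, single-class AP at one IoU threshold, transcribed from
    the definition: greedy matching in confidence order, each ground truth
    used at most once, then 101-point interpolation of the PR curve."""

    def iou(a, b):
        ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
        ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
        iw, ih = max(0.0, ix1 - ix0), max(0.0, iy1 - iy0)
        inter = iw * ih
        aa = max(0.0, a[2] - a[0]) * max(0.0, a[3] - a[1])
        ab = max(0.0, b[2] - b[0]) * max(0.0, b[3] - b[1])
        if aa <= 0 or ab <= 0:
            return 0.0
        return inter / (aa + ab - inter)

    order = sorted(range(len(det_boxes)), key=lambda i: -det_scores[i])
    used = [False] * len(gt_boxes)
    outcomes = []  # (score, is_tp)
    for i in order:
        best, best_iou = -1, iou_threshold
        for j, g in enumerate(gt_boxes):
            if used[j]:
                continue
            ov = iou(det_boxes[i], g)
            if ov >= best_iou:
                best, best_iou = j, ov
        if best >= 0:
            used[best] = True
            outcomes.append((det_scores[i], True))
        else:
            outcomes.append((det_scores[i], False))
    if not gt_boxes:
        raise ValueError("AP undefined without ground truth")
    tp = fp = 0
    points = []  # (recall, precision) after each detection
    for _, is_tp in outcomes:
        if is_tp:
            tp += 1
        else:
            fp += 1
        points.append((tp / len(gt_boxes), tp / (tp + fp)))
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        best_p = 0.0
        for rec, prec in points:
            if rec >= r - 1e-12 and prec > best_p:
                best_p = prec
        ap += best_p / 101.0
    return ap
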