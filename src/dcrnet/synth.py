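"""Deterministic synthetic stained-cell fields with ground-truth annotations.

Emulates the statistical structure of Ki-67-style immunohistochemistry
fields: round/oval nuclei in two colour classes (stained vs unstained),
a configurable fraction of cells deformed into spindle/bar shapes (elongated
ellipses), a fraction placed in adherent (touching) clusters, and dark
non-cell stain blobs that act as false-positive bait and are deliberately
*not* annotated.  Cells are anti-aliased filled ellipses with per-cell colour
jitter over a light textured background plus Gaussian sensor noise, which is
enough to reproduce the detection difficulties of interest (adhesion,
deformation, unspecific stains) without attempting photorealism.

Identical :class:`FieldSpec` values (including the seed) reproduce
bit-identical fields.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .data import Annotation, AnnotatedImage, save_image, write_voc

# Default colour convention: blue = stained, brown = unstained.  The inverse
# mapping occurs in parts of the source imagery's documentation, so the
# mapping is configurable rather than hard-coded.
DEFAULT_COLORS: dict[str, tuple[int, int, int]] = {
    "stained": (70, 80, 165),     # blue-ish nucleus
    "unstained": (165, 115, 60),  # brown-ish nucleus
}
DISTRACTOR_COLOR = (26, 24, 22)   # near-black unspecific stain


class FieldSpecError(ValueError):
    pass


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic field.

    Defaults describe a desk-scale 320×240 field: ~15 nuclei of 8–16 px
    radius, a stained fraction matching the ~0.19 rate seen in practice
    (note the generator labels the *stained* class with ``stained_fraction``
    of the cells), a tenth of cells deformed to spindle/bar shapes and a
    fifth placed in adherent clusters, plus a few dark distractor blobs.
    """

    width: int = 320
    height: int = 240
    n_cells: int = 15
    stained_fraction: float = 0.19
    deformed_fraction: float = 0.10
    adhesion_fraction: float = 0.20
    n_distractors: int = 2
    cell_radius_range: tuple[float, float] = (8.0, 16.0)
    rng_seed: int = 0

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise FieldSpecError(f"image dimensions must be positive, got "
                                 f"{self.width}x{self.height}")
        if self.n_cells < 0 or self.n_distractors < 0:
            raise FieldSpecError("cell and distractor counts must be non-negative")
        for name in ("stained_fraction", "deformed_fraction", "adhesion_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FieldSpecError(f"{name}={v} outside [0, 1]")
        rmin, rmax = self.cell_radius_range
        if not 0 < rmin <= rmax:
            raise FieldSpecError(f"invalid cell_radius_range {self.cell_radius_range}")
        if self.n_cells * np.pi * rmin * rmin > self.width * self.height:
            raise FieldSpecError(
                f"{self.n_cells} cells of minimum radius {rmin} cannot fit a "
                f"{self.width}x{self.height} field")


@dataclass
class RenderedField:
    """A generated field: image, cell annotations, and the (unannotated)
    distractor boxes."""

    image: np.ndarray
    annotations: list[Annotation]
    distractor_boxes: list[tuple[int, int, int, int]]
    spec: FieldSpec

    def to_annotated_image(self, source_id: str = "") -> AnnotatedImage:
        return AnnotatedImage(self.image, list(self.annotations),
                              source_id=source_id or f"field_seed{self.spec.rng_seed}")


def _circle_overlap_distance(r1: float, r2: float, frac: float) -> float:
    """Distance between two circle centres at which the lens overlap equals
    ``frac`` of the smaller circle's area."""
    if r1 > r2:
        r1, r2 = r2, r1
    target = frac * np.pi * r1 * r1

    def lens(d):
        if d >= r1 + r2:
            return 0.0
        if d <= r2 - r1:
            return np.pi * r1 * r1
        a1 = r1 * r1 * np.arccos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
        a2 = r2 * r2 * np.arccos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
        a3 = 0.5 * np.sqrt(max(0.0, (-d + r1 + r2) * (d + r1 - r2) *
                               (d - r1 + r2) * (d + r1 + r2)))
        return a1 + a2 - a3

    return brentq(lambda d: lens(d) - target, max(r2 - r1, 1e-6) + 1e-9, r1 + r2 - 1e-9)


def _paint_ellipse(img: np.ndarray, cx: float, cy: float, a: float, b: float,
                   theta: float, color: np.ndarray) -> tuple[int, int, int, int] | None:
    """Alpha-composite an anti-aliased filled ellipse; returns its tight
    bounding box (half-open, clipped to the image) or None if off-image."""
    h, w = img.shape[:2]
    ct, st = np.cos(theta), np.sin(theta)
    ex = np.sqrt((a * ct) ** 2 + (b * st) ** 2)
    ey = np.sqrt((a * st) ** 2 + (b * ct) ** 2)
    x0 = max(int(np.floor(cx - ex - 1)), 0)
    y0 = max(int(np.floor(cy - ey - 1)), 0)
    x1 = min(int(np.ceil(cx + ex + 2)), w)
    y1 = min(int(np.ceil(cy + ey + 2)), h)
    if x1 <= x0 or y1 <= y0:
        return None
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx = xs + 0.5 - cx
    dy = ys + 0.5 - cy
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    r = np.sqrt(u * u + v * v)
    alpha = np.clip((1.0 - r) * min(a, b) + 0.5, 0.0, 1.0)
    patch = img[y0:y1, x0:x1]
    patch *= (1.0 - alpha)[..., None]
    patch += alpha[..., None] * color[None, None, :]
    mask = alpha >= 0.5
    if not mask.any():
        return None
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return (x0 + cols[0], y0 + rows[0], x0 + cols[-1] + 1, y0 + rows[-1] + 1)


def generate_field(spec: FieldSpec,
                   colors: dict[str, tuple[int, int, int]] | None = None) -> RenderedField:
    """Render one field from its specification (bit-deterministic)."""
    colors = colors or DEFAULT_COLORS
    rng = np.random.default_rng(spec.rng_seed)
    w, h = spec.width, spec.height
    rmin, rmax = spec.cell_radius_range

    # light textured background
    coarse = rng.normal(0.0, 6.0, (h // 16 + 2, w // 16 + 2))
    texture = ndimage.zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]), order=1)
    img = np.empty((h, w, 3), dtype=np.float64)
    for ch, base in enumerate((236.0, 232.0, 228.0)):
        img[:, :, ch] = base + texture

    n_stained = int(round(spec.n_cells * spec.stained_fraction))
    labels = ["stained"] * n_stained + ["unstained"] * (spec.n_cells - n_stained)
    rng.shuffle(labels)
    n_def = int(round(spec.n_cells * spec.deformed_fraction))
    deformed = np.zeros(spec.n_cells, dtype=bool)
    if n_def:
        deformed[rng.choice(spec.n_cells, size=n_def, replace=False)] = True
    n_adh = int(round(spec.n_cells * spec.adhesion_fraction))

    placed: list[tuple[float, float, float]] = []  # (cx, cy, effective radius)
    annotations: list[Annotation] = []
    for i in range(spec.n_cells):
        if deformed[i]:
            a = rng.uniform(rmin * 1.3, rmax * 1.5)
            ratio = rng.uniform(3.0, 4.5)  # spindle/bar: major/minor >= 3
            b = a / ratio
        else:
            a = rng.uniform(rmin, rmax)
            b = a / rng.uniform(1.0, 1.5)
        theta = rng.uniform(0.0, np.pi)
        reff = float(np.sqrt(a * b))
        adherent = i >= 1 and i < 1 + n_adh and placed
        cx = cy = None
        if adherent:
            # overlap a previously placed neighbour by 10-40% of area
            ncx, ncy, nr = placed[rng.integers(len(placed))]
            frac = rng.uniform(0.10, 0.40)
            d = _circle_overlap_distance(reff, nr, frac)
            for _ in range(20):
                phi = rng.uniform(0.0, 2 * np.pi)
                tx, ty = ncx + d * np.cos(phi), ncy + d * np.sin(phi)
                if 2 <= tx < w - 2 and 2 <= ty < h - 2:
                    cx, cy = tx, ty
                    break
        if cx is None:
            margin = min(a, (min(w, h) - 4) / 2.0)
            for _ in range(60):
                tx = rng.uniform(margin, w - margin)
                ty = rng.uniform(margin, h - margin)
                if all((tx - px) ** 2 + (ty - py) ** 2 > (reff + pr + 2) ** 2
                       for px, py, pr in placed):
                    cx, cy = tx, ty
                    break
            else:
                cx, cy = tx, ty  # dense field: accept the last candidate
        color = np.clip(np.asarray(colors[labels[i]], dtype=np.float64)
                        + rng.normal(0.0, 8.0, 3), 0, 255)
        box = _paint_ellipse(img, cx, cy, a, b, theta, color)
        placed.append((cx, cy, reff))
        if box is not None:
            annotations.append(Annotation(box, labels[i]))

    distractor_boxes: list[tuple[int, int, int, int]] = []
    dcolor = np.asarray(DISTRACTOR_COLOR, dtype=np.float64)
    for _ in range(spec.n_distractors):
        n_lobes = int(rng.integers(2, 5))
        bx0, by0 = w, h
        bx1 = by1 = 0
        cx = rng.uniform(8, w - 8)
        cy = rng.uniform(8, h - 8)
        for _ in range(n_lobes):
            la = rng.uniform(2.5, 6.0)
            lb = la / rng.uniform(1.0, 2.0)
            lt = rng.uniform(0.0, np.pi)
            jx = cx + rng.normal(0.0, 3.0)
            jy = cy + rng.normal(0.0, 3.0)
            box = _paint_ellipse(img, jx, jy, la, lb, lt,
                                 np.clip(dcolor + rng.normal(0, 4, 3), 0, 255))
            if box is not None:
                bx0, by0 = min(bx0, box[0]), min(by0, box[1])
                bx1, by1 = max(bx1, box[2]), max(by1, box[3])
        if bx1 > bx0 and by1 > by0:
            distractor_boxes.append((bx0, by0, bx1, by1))

    img += rng.normal(0.0, 3.0, img.shape)  # sensor noise, sigma = 3/255
    image = np.clip(img, 0, 255).astype(np.uint8)
    return RenderedField(image, annotations, distractor_boxes, spec)


def write_fixture_set(specs: list[FieldSpec], out_dir) -> list[dict]:
    """Render a list of specs to ``out_dir`` as PNG + VOC XML pairs plus a
    ``manifest.csv`` listing file paths, seeds and class counts.

    Returns the manifest rows as dictionaries.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out_dir}: {exc}") from exc
    rows: list[dict] = []
    for i, spec in enumerate(specs):
        fld = generate_field(spec)
        stem = f"field_{i:04d}"
        img_path = out_dir / f"{stem}.png"
        xml_path = out_dir / f"{stem}.xml"
        try:
            save_image(fld.image, img_path)
        except OSError as exc:
            raise OSError(f"cannot write image {img_path}: {exc}") from exc
        write_voc(fld.to_annotated_image(stem), xml_path, image_filename=img_path.name)
        rows.append({
            "image": img_path.name,
            "xml": xml_path.name,
            "seed": spec.rng_seed,
            "width": spec.width,
            "height": spec.height,
            "n_stained": sum(a.label == "stained" for a in fld.annotations),
            "n_unstained": sum(a.label == "unstained" for a in fld.annotations),
            "n_distractors": len(fld.distractor_boxes),
        })
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()) if rows else
                                ["image", "xml", "seed", "width", "height",
                                 "n_stained", "n_unstained", "n_distractors"])
        writer.writeheader()
        writer.writerows(rows)
    return rows
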