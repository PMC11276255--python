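"""Dataset engineering for stained-cell detection.

Covers Pascal VOC XML annotation I/O (the LabelImg dialect), horizontal and
vertical flip augmentation, exact multi-scale tiling with bounding-box
remapping, the 6:3:1 train/validation/test split and the canonical resize
applied before the detector.

Coordinate conventions: VOC XML stores 1-based inclusive pixel coordinates;
in memory every box is 0-based half-open ``(x0, y0, x1, y1)`` with
``width = x1 - x0``.  The two VOC converters in this module are the only
place the mapping occurs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, TypeVar

import numpy as np
from lxml import etree
from PIL import Image

VOCABULARY = ("stained", "unstained")

Box = tuple[int, int, int, int]


class VocError(ValueError):
    """Malformed or inconsistent VOC annotation data."""


class TilingError(ValueError):
    pass


@dataclass(frozen=True)
class Annotation:
    """One labelled bounding box, 0-based half-open pixel coordinates."""

    box: Box
    label: str

    def __post_init__(self):
        x0, y0, x1, y1 = self.box
        if x1 < x0 or y1 < y0:
            raise VocError(f"degenerate box {self.box}")
        if self.label not in VOCABULARY:
            raise VocError(f"label {self.label!r} not in vocabulary {VOCABULARY}")

    @property
    def area(self) -> int:
        x0, y0, x1, y1 = self.box
        return (x1 - x0) * (y1 - y0)


@dataclass
class AnnotatedImage:
    """An RGB image (H, W, 3 uint8) plus its labelled boxes."""

    image: np.ndarray
    annotations: list[Annotation]
    source_id: str = ""

    def __post_init__(self):
        h, w = self.image.shape[:2]
        for i, a in enumerate(self.annotations):
            x0, y0, x1, y1 = a.box
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise VocError(
                    f"{self.source_id or 'image'}: object {i} box {a.box} outside {w}x{h}")

    @property
    def width(self) -> int:
        return self.image.shape[1]

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def resolution_tag(self) -> str:
        return f"{self.width}x{self.height}"


@dataclass
class DatasetSplit:
    train: list
    val: list
    test: list


# ---------------------------------------------------------------------------
# VOC XML I/O
# ---------------------------------------------------------------------------

def read_voc(xml_path, vocabulary: Sequence[str] = VOCABULARY
             ) -> tuple[list[Annotation], tuple[int, int]]:
    """Parse a LabelImg-style VOC XML file.

    Returns the annotations (internal half-open coordinates) and the declared
    image size ``(width, height)``.
    """
    xml_path = Path(xml_path)
    try:
        tree = etree.parse(str(xml_path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise VocError(f"{xml_path}: cannot parse annotation XML: {exc}") from exc
    root = tree.getroot()
    size = root.find("size")
    if size is None:
        raise VocError(f"{xml_path}: missing <size> element")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    annotations: list[Annotation] = []
    for i, obj in enumerate(root.findall("object")):
        name = obj.findtext("name")
        if name not in vocabulary:
            raise VocError(f"{xml_path}: object {i} has unknown label {name!r}; "
                           f"expected one of {list(vocabulary)}")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise VocError(f"{xml_path}: object {i} has no <bndbox>")
        try:
            xmin = int(round(float(bnd.findtext("xmin"))))
            ymin = int(round(float(bnd.findtext("ymin"))))
            xmax = int(round(float(bnd.findtext("xmax"))))
            ymax = int(round(float(bnd.findtext("ymax"))))
        except (TypeError, ValueError) as exc:
            raise VocError(f"{xml_path}: object {i} has malformed <bndbox>") from exc
        if xmin > xmax or ymin > ymax:
            raise VocError(f"{xml_path}: object {i} box inverted "
                           f"({xmin},{ymin},{xmax},{ymax})")
        if xmin < 1 or ymin < 1 or xmax > width or ymax > height:
            raise VocError(f"{xml_path}: object {i} box ({xmin},{ymin},{xmax},{ymax}) "
                           f"outside image {width}x{height}")
        # VOC 1-based inclusive -> 0-based half-open
        annotations.append(Annotation((xmin - 1, ymin - 1, xmax, ymax), name))
    return annotations, (width, height)


def write_voc(annotated: AnnotatedImage, xml_path, image_filename: str | None = None) -> None:
    """Write annotations as LabelImg-style VOC XML (lossless round-trip with
    :func:`read_voc`)."""
    xml_path = Path(xml_path)
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = xml_path.parent.name
    etree.SubElement(root, "filename").text = image_filename or f"{annotated.source_id}.png"
    src = etree.SubElement(root, "source")
    etree.SubElement(src, "database").text = "Unknown"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(annotated.width)
    etree.SubElement(size, "height").text = str(annotated.height)
    etree.SubElement(size, "depth").text = "3"
    etree.SubElement(root, "segmented").text = "0"
    for a in annotated.annotations:
        x0, y0, x1, y1 = a.box
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = a.label
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(x0 + 1)
        etree.SubElement(bnd, "ymin").text = str(y0 + 1)
        etree.SubElement(bnd, "xmax").text = str(x1)
        etree.SubElement(bnd, "ymax").text = str(y1)
    try:
        xml_path.write_bytes(etree.tostring(root, pretty_print=True))
    except OSError as exc:
        raise OSError(f"cannot write annotation file {xml_path}: {exc}") from exc


# ---------------------------------------------------------------------------
# geometric transforms
# ---------------------------------------------------------------------------

def flip(annotated: AnnotatedImage, axis: str) -> AnnotatedImage:
    """Mirror an image and its boxes horizontally or vertically."""
    if axis not in ("horizontal", "vertical"):
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    w, h = annotated.width, annotated.height
    if axis == "horizontal":
        img = annotated.image[:, ::-1].copy()
        anns = [Annotation((w - x1, y0, w - x0, y1), a.label)
                for a in annotated.annotations for x0, y0, x1, y1 in (a.box,)]
    else:
        img = annotated.image[::-1].copy()
        anns = [Annotation((x0, h - y1, x1, h - y0), a.label)
                for a in annotated.annotations for x0, y0, x1, y1 in (a.box,)]
    return AnnotatedImage(img, anns, source_id=f"{annotated.source_id}_{axis[0]}flip")


def count_tiles(image_w: int, image_h: int, tile_w: int, tile_h: int) -> int:
    """Number of non-overlapping tiles covering an image (exact grid)."""
    if image_w % tile_w or image_h % tile_h:
        raise TilingError(
            f"image {image_w}x{image_h} is not an integral multiple of tile {tile_w}x{tile_h}")
    return (image_w // tile_w) * (image_h // tile_h)


def tile(annotated: AnnotatedImage, tile_w: int, tile_h: int,
         min_visibility: float = 0.25) -> list[AnnotatedImage]:
    """Cut an image into a non-overlapping grid of tiles.

    Each annotation is assigned to every tile it intersects, clipped to the
    tile and remapped to tile-local coordinates.  A clipped box is dropped
    when its area falls below ``min_visibility`` of the original box area
    (with ``min_visibility=0`` any positive-area intersection is kept).
    """
    w, h = annotated.width, annotated.height
    n = count_tiles(w, h, tile_w, tile_h)  # raises on non-divisible dims
    tiles: list[AnnotatedImage] = []
    for r in range(h // tile_h):
        for c in range(w // tile_w):
            ox, oy = c * tile_w, r * tile_h
            sub = annotated.image[oy:oy + tile_h, ox:ox + tile_w].copy()
            anns = []
            for a in annotated.annotations:
                x0, y0, x1, y1 = a.box
                cx0, cy0 = max(x0, ox), max(y0, oy)
                cx1, cy1 = min(x1, ox + tile_w), min(y1, oy + tile_h)
                area = max(0, cx1 - cx0) * max(0, cy1 - cy0)
                if area <= 0 or area < min_visibility * a.area:
                    continue
                anns.append(Annotation((cx0 - ox, cy0 - oy, cx1 - ox, cy1 - oy), a.label))
            tiles.append(AnnotatedImage(
                sub, anns, source_id=f"{annotated.source_id}_t{r:02d}{c:02d}"))
    assert len(tiles) == n
    return tiles


T = TypeVar("T")


def split_6_3_1(groups: Mapping[str, Sequence[T]], seed: int) -> DatasetSplit:
    """Per-resolution 6:3:1 split.

    For a group of ``n`` items, ``round(0.6 n)`` go to training,
    ``floor(0.3 n)`` to validation and the remainder to test — the allocation
    that reproduces the published per-resolution counts (225 → 135/67/23,
    210 → 126/63/21).  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    train: list[T] = []
    val: list[T] = []
    test: list[T] = []
    for key in sorted(groups):
        items = list(groups[key])
        n = len(items)
        if n < 10:
            raise ValueError(f"group {key!r} has only {n} images; need at least 10 "
                             "for a 6:3:1 split")
        order = rng.permutation(n)
        n_train = math.floor(0.6 * n + 0.5)
        n_val = math.floor(0.3 * n)
        train.extend(items[i] for i in order[:n_train])
        val.extend(items[i] for i in order[n_train:n_train + n_val])
        test.extend(items[i] for i in order[n_train + n_val:])
    return DatasetSplit(train, val, test)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def resize_canonical(annotated: AnnotatedImage,
                     target: tuple[int, int] = (1800, 1200)) -> AnnotatedImage:
    """Resample to the fixed detector input size ``target = (width, height)``.

    Boxes are scaled per axis in the half-open frame, rounded half-up and
    clamped to bounds; aspect ratio is not preserved (a single fixed size is
    used for every input).
    """
    tw, th = target
    w, h = annotated.width, annotated.height
    if (w, h) == (tw, th):
        return annotated
    img = np.asarray(Image.fromarray(annotated.image).resize((tw, th), Image.BILINEAR))
    sx, sy = tw / w, th / h
    anns = []
    for a in annotated.annotations:
        x0, y0, x1, y1 = a.box
        nx0 = min(max(_round_half_up(x0 * sx), 0), tw - 1)
        ny0 = min(max(_round_half_up(y0 * sy), 0), th - 1)
        nx1 = min(max(_round_half_up(x1 * sx), nx0 + 1), tw)
        ny1 = min(max(_round_half_up(y1 * sy), ny0 + 1), th)
        anns.append(Annotation((nx0, ny0, nx1, ny1), a.label))
    return AnnotatedImage(img, anns, source_id=annotated.source_id)


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF image as an RGB uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(image: np.ndarray, path) -> None:
    Image.fromarray(image).save(path)
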