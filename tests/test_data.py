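"""VOC I/O, flips, tiling arithmetic, splitting and the canonical resize."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcrnet.data import (Annotation, AnnotatedImage, TilingError, VocError,
                         count_tiles, flip, read_voc, resize_canonical, split_6_3_1,
                         tile, write_voc)


def _blank(w, h, anns=(), source="img"):
    return AnnotatedImage(np.zeros((h, w, 3), dtype=np.uint8), list(anns), source_id=source)


# ---------------------------------------------------------------------------
# VOC XML
# ---------------------------------------------------------------------------

def test_parse_single_object(tmp_path):
    xml = tmp_path / "a.xml"
    xml.write_text("""<annotation><size><width>100</width><height>80</height><depth>3</depth></size>
      <object><name>stained</name><bndbox><xmin>10</xmin><ymin>20</ymin><xmax>30</xmax><ymax>40</ymax></bndbox></object>
      </annotation>""")
    anns, (w, h) = read_voc(xml)
    assert (w, h) == (100, 80)
    # 1-based inclusive on disk -> 0-based half-open in memory
    assert anns == [Annotation((9, 19, 30, 40), "stained")]


@settings(max_examples=30, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 98), st.integers(0, 78),
                          st.integers(1, 99), st.integers(1, 79),
                          st.booleans()), max_size=20))
def test_write_read_round_trip_is_identity(tmp_path_factory, raw):
    anns = []
    for x0, y0, dw, dh, stained in raw:
        x1 = min(x0 + dw, 100)
        y1 = min(y0 + dh, 80)
        if x1 > x0 and y1 > y0:
            anns.append(Annotation((x0, y0, x1, y1), "stained" if stained else "unstained"))
    tmp = tmp_path_factory.mktemp("voc")
    path = tmp / "r.xml"
    write_voc(_blank(100, 80, anns), path)
    back, (w, h) = read_voc(path)
    assert back == anns
    assert (w, h) == (100, 80)


def test_unknown_label_raises_with_file_and_index(tmp_path):
    xml = tmp_path / "bad.xml"
    xml.write_text("""<annotation><size><width>50</width><height>50</height></size>
      <object><name>cat</name><bndbox><xmin>1</xmin><ymin>1</ymin><xmax>5</xmax><ymax>5</ymax></bndbox></object>
      </annotation>""")
    with pytest.raises(VocError, match=r"object 0.*'cat'"):
        read_voc(xml)


def test_malformed_xml_and_out_of_bounds_box_rejected(tmp_path):
    bad = tmp_path / "broken.xml"
    bad.write_text("<annotation><size>")
    with pytest.raises(VocError, match="broken.xml"):
        read_voc(bad)
    oob = tmp_path / "oob.xml"
    oob.write_text("""<annotation><size><width>20</width><height>20</height></size>
      <object><name>stained</name><bndbox><xmin>1</xmin><ymin>1</ymin><xmax>25</xmax><ymax>5</ymax></bndbox></object>
      </annotation>""")
    with pytest.raises(VocError, match="outside image"):
        read_voc(oob)


# ---------------------------------------------------------------------------
# flips
# ---------------------------------------------------------------------------

def test_horizontal_flip_box_arithmetic():
    # VOC box (10,20,30,40) in a width-100 image maps to (71,20,91,40);
    # internally (9,19,30,40) -> (70,19,91,40)
    ai = _blank(100, 60, [Annotation((9, 19, 30, 40), "stained")])
    flipped = flip(ai, "horizontal")
    assert flipped.annotations[0].box == (70, 19, 91, 40)


@pytest.mark.parametrize("axis", ["horizontal", "vertical"])
def test_flip_is_an_involution(axis, rng):
    img = rng.integers(0, 255, size=(40, 60, 3), dtype=np.uint8)
    anns = [Annotation((5, 4, 20, 30), "stained"), Annotation((33, 10, 57, 39), "unstained")]
    ai = AnnotatedImage(img, anns, source_id="x")
    twice = flip(flip(ai, axis), axis)
    np.testing.assert_array_equal(twice.image, img)
    assert [a.box for a in twice.annotations] == [a.box for a in anns]


def test_centered_box_is_flip_invariant():
    ai = _blank(100, 100, [Annotation((40, 40, 60, 60), "stained")])
    for axis in ("horizontal", "vertical"):
        assert flip(ai, axis).annotations[0].box == (40, 40, 60, 60)


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def test_tile_grid_counts_follow_exact_arithmetic():
    assert count_tiles(3840, 2880, 320, 240) == 144          # 12 x 12
    assert count_tiles(2560, 1920, 320, 240) == 64
    assert count_tiles(3840, 2880, 640, 480) == 36
    assert count_tiles(3840, 2880, 1280, 960) == 9


def test_published_tile_totals_reproduced():
    """(135, 126) training and (67, 63) validation originals at the three
    tile sizes give the published dataset sizes."""
    groups = {(3840, 2880): (135, 67), (2560, 1920): (126, 63)}
    expected = {(320, 240): (27_504, 13_680),
                (640, 480): (6_876, 3_420),
                (1280, 960): (1_719, 855)}
    for (tw, th), (want_train, want_val) in expected.items():
        got_train = sum(n_tr * count_tiles(w, h, tw, th) for (w, h), (n_tr, _) in groups.items())
        got_val = sum(n_va * count_tiles(w, h, tw, th) for (w, h), (_, n_va) in groups.items())
        assert (got_train, got_val) == (want_train, want_val)


def test_full_size_tile_is_identity(rng):
    img = rng.integers(0, 255, (24, 32, 3), dtype=np.uint8)
    ai = AnnotatedImage(img, [Annotation((2, 3, 10, 12), "stained")], source_id="t")
    tiles = tile(ai, 32, 24)
    assert len(tiles) == 1
    np.testing.assert_array_equal(tiles[0].image, img)
    assert tiles[0].annotations == ai.annotations


def test_tiles_reassemble_image_and_conserve_boxes(rng):
    img = rng.integers(0, 255, (24, 32, 3), dtype=np.uint8)
    anns = [Annotation((2, 3, 10, 12), "stained"),
            Annotation((14, 10, 25, 20), "unstained"),    # straddles tiles
            Annotation((30, 22, 32, 24), "stained")]
    ai = AnnotatedImage(img, anns, source_id="t")
    tiles = tile(ai, 16, 12, min_visibility=0.0)
    assert len(tiles) == 4
    # pixel content reassembles exactly
    top = np.concatenate([tiles[0].image, tiles[1].image], axis=1)
    bottom = np.concatenate([tiles[2].image, tiles[3].image], axis=1)
    np.testing.assert_array_equal(np.concatenate([top, bottom], axis=0), img)
    # every box appears (possibly clipped) in at least one tile
    per_tile = [len(t.annotations) for t in tiles]
    assert sum(per_tile) >= len(anns)
    for t in tiles:
        for a in t.annotations:
            x0, y0, x1, y1 = a.box
            assert 0 <= x0 < x1 <= 16 and 0 <= y0 < y1 <= 12


def test_min_visibility_drops_slivers():
    ai = _blank(32, 24, [Annotation((14, 0, 32, 10), "stained")])
    # box spans x 14..32: 2 px visible in the left tile (area fraction 1/9)
    tiles_keep = tile(ai, 16, 24, min_visibility=0.0)
    tiles_drop = tile(ai, 16, 24, min_visibility=0.25)
    assert len(tiles_keep[0].annotations) == 1
    assert len(tiles_drop[0].annotations) == 0
    assert len(tiles_drop[1].annotations) == 1


def test_non_divisible_dimensions_error_names_both_resolutions():
    ai = _blank(30, 24)
    with pytest.raises(TilingError, match=r"30x24.*16x12"):
        tile(ai, 16, 12)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n,expected", [(225, (135, 67, 23)), (210, (126, 63, 21)),
                                        (10, (6, 3, 1))])
def test_split_allocation_matches_published_counts(n, expected):
    split = split_6_3_1({"g": list(range(n))}, seed=0)
    assert (len(split.train), len(split.val), len(split.test)) == expected


def test_split_is_deterministic_disjoint_and_exhaustive():
    items = {"a": [f"a{i}" for i in range(25)], "b": [f"b{i}" for i in range(12)]}
    s1 = split_6_3_1(items, seed=9)
    s2 = split_6_3_1(items, seed=9)
    assert (s1.train, s1.val, s1.test) == (s2.train, s2.val, s2.test)
    allocated = s1.train + s1.val + s1.test
    assert sorted(allocated) == sorted(items["a"] + items["b"])
    assert len(set(s1.train) & set(s1.val)) == 0
    assert len(set(s1.train) & set(s1.test)) == 0


def test_split_rejects_small_groups():
    with pytest.raises(ValueError, match="at least 10"):
        split_6_3_1({"g": list(range(9))}, seed=0)


# ---------------------------------------------------------------------------
# canonical resize
# ---------------------------------------------------------------------------

def test_resize_identity_when_already_canonical(rng):
    img = rng.integers(0, 255, (1200, 1800, 3), dtype=np.uint8)
    ai = AnnotatedImage(img, [Annotation((10, 10, 100, 100), "stained")], source_id="c")
    out = resize_canonical(ai)
    assert out is ai


def test_resize_preserves_full_frame_box():
    ai = _blank(3600, 2400, [Annotation((0, 0, 3600, 2400), "stained")])
    out = resize_canonical(ai)
    assert out.image.shape == (1200, 1800, 3)
    assert out.annotations[0].box == (0, 0, 1800, 1200)


def test_resize_scales_boxes_per_axis():
    ai = _blank(360, 240, [Annotation((10, 10, 100, 100), "stained")])
    out = resize_canonical(ai)      # x5 in both axes for the 1800x1200 target
    assert out.annotations[0].box == (50, 50, 500, 500)
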