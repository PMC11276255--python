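"""Two-stage detector: anchors, proposals, training mechanics, inference."""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pytest

from dcrnet import autograd as ag
from dcrnet.autograd import Tensor
from dcrnet.data import AnnotatedImage, DatasetSplit, flip
from dcrnet.detector import (CellDetector, DetectorConfig, TrainingDivergedError,
                             TrainingSchedule, build_schedule, detect,
                             detections_to_coco, generate_anchors, load_checkpoint,
                             nms, save_checkpoint, train)
from dcrnet.evaluation import iou
from dcrnet.experiments import make_fields
from dcrnet.synth import FieldSpec, generate_field


# ---------------------------------------------------------------------------
# anchors and NMS
# ---------------------------------------------------------------------------

def test_anchor_count_formula_at_a_stride_16_level():
    # 256x256 input, stride 16 -> 16x16 grid; 3 scales x 3 ratios -> 2304
    anchors = generate_anchors(16, 16, 16, (32, 64, 128), (0.5, 1.0, 2.0))
    assert anchors.shape == (2304, 4)


def test_anchor_count_formula_holds_on_every_pyramid_level():
    model = CellDetector(DetectorConfig.desk_scale(), seed=0)
    x = Tensor(np.zeros((1, 3, 320, 240), dtype=np.float32))
    with ag.no_grad():
        feats = model.features(x)
    a = model.cfg.anchors
    for lvl, (f, anchors) in enumerate(zip(feats, model.anchors_for(feats))):
        h, w = f.shape[2], f.shape[3]
        assert len(anchors) == h * w * len(a.scales[lvl]) * len(a.ratios)


def test_anchor_geometry_respects_scale_and_ratio():
    anchors = generate_anchors(1, 1, 8, (32,), (0.5, 1.0, 2.0))
    ws = anchors[:, 2] - anchors[:, 0]
    hs = anchors[:, 3] - anchors[:, 1]
    np.testing.assert_allclose(ws * hs, 32 * 32, rtol=1e-6)   # constant area
    np.testing.assert_allclose(hs / ws, [0.5, 1.0, 2.0], rtol=1e-6)


def test_nms_collapses_identical_boxes_to_one():
    boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10.0]])
    keep = nms(boxes, np.array([0.9, 0.8]), threshold=0.5)
    assert list(keep) == [0]


def test_nms_keeps_disjoint_boxes():
    boxes = np.array([[0, 0, 10, 10], [20, 20, 30, 30.0], [0, 0, 10, 10]])
    keep = nms(boxes, np.array([0.5, 0.9, 0.8]), threshold=0.5)
    assert set(keep) == {1, 2}


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def _tagged_split():
    imgs = []
    for i in range(12):
        imgs.append(AnnotatedImage(np.zeros((240, 320, 3), np.uint8), [], source_id=f"lo{i}"))
    return DatasetSplit(train=imgs, val=[], test=[])


def test_default_schedule_reproduces_published_curriculum():
    sched = build_schedule(_tagged_split())
    assert sched.phases == [("low_res", 30), ("all", 270)]
    assert sched.batch_size == 4
    assert sched.loss_log_interval == 5


def test_schedule_scales_linearly():
    sched = build_schedule(_tagged_split(), scale=0.1)
    assert sched.phases == [("low_res", 3), ("all", 27)]


def test_schedule_requires_resolution_tags():
    class Untagged:
        resolution_tag = None
    with pytest.raises(ValueError, match="resolution tag"):
        build_schedule(DatasetSplit(train=[Untagged()], val=[], test=[]))


def test_loss_trace_interval_arithmetic(tiny_fields):
    model = CellDetector(_tiny_config(), seed=0)
    sched = TrainingSchedule(phases=[("all", 100)], batch_size=2, max_iterations=11,
                             learning_rate=1e-3, loss_log_interval=5, rng_seed=0)
    trace = train(model, tiny_fields, sched)
    assert [r["iteration"] for r in trace] == [0, 5, 10]


# ---------------------------------------------------------------------------
# training mechanics (tiny configuration for speed)
# ---------------------------------------------------------------------------

def _tiny_config() -> DetectorConfig:
    cfg = DetectorConfig.desk_scale()
    return replace(cfg, pre_nms_top_n=100, proposals_train=60, proposals_test=40,
                   roi_batch=16)


@pytest.fixture(scope="module")
def tiny_fields():
    spec = FieldSpec(width=160, height=120, n_cells=5, n_distractors=1)
    return make_fields(4, 300, template=spec, prefix="tiny")


def test_equal_seeds_give_identical_loss_traces(tiny_fields):
    traces = []
    for _ in range(2):
        model = CellDetector(_tiny_config(), seed=5)
        sched = TrainingSchedule(phases=[("all", 10)], batch_size=2, max_iterations=6,
                                 learning_rate=1e-3, loss_log_interval=1, rng_seed=5)
        traces.append(train(model, tiny_fields, sched))
    t1, t2 = traces
    assert [r["total"] for r in t1] == [r["total"] for r in t2]


def test_loss_is_finite_and_decreases_on_a_short_run(tiny_fields):
    model = CellDetector(_tiny_config(), seed=1)
    sched = TrainingSchedule(phases=[("all", 100)], batch_size=2, max_iterations=50,
                             learning_rate=5e-3, loss_log_interval=1,
                             warmup_iterations=10, rng_seed=1)
    trace = train(model, tiny_fields, sched)
    losses = [r["total"] for r in trace]
    assert all(np.isfinite(losses))
    assert np.mean(losses[-10:]) < np.mean(losses[:10])


def test_divergence_aborts_with_checkpoint(tiny_fields, tmp_path):
    model = CellDetector(_tiny_config(), seed=2)
    sched = TrainingSchedule(phases=[("all", 100)], batch_size=2, max_iterations=40,
                             learning_rate=1e6, warmup_iterations=1, grad_clip=0.0,
                             rng_seed=2)
    ckpt = tmp_path / "last.npz"
    with pytest.raises(TrainingDivergedError):
        train(model, tiny_fields, sched, checkpoint_path=ckpt)
    assert ckpt.exists()


def test_checkpoint_round_trip_reproduces_detections(toy_model, tmp_path):
    field = generate_field(FieldSpec(rng_seed=901))
    ckpt = tmp_path / "model.npz"
    save_checkpoint(toy_model, ckpt)
    reloaded = load_checkpoint(ckpt)
    d1 = detect(toy_model, field.image)
    d2 = detect(reloaded, field.image)
    assert [(d.box, d.label, d.confidence) for d in d1] == \
           [(d.box, d.label, d.confidence) for d in d2]


# ---------------------------------------------------------------------------
# behaviour of a trained model
# ---------------------------------------------------------------------------

def test_untrained_model_warns_on_detect():
    model = CellDetector(_tiny_config(), seed=0)
    img = np.zeros((120, 160, 3), dtype=np.uint8)
    with pytest.warns(UserWarning, match="not been trained"):
        detect(model, img)


def test_top_proposal_covers_a_single_high_contrast_cell(toy_model):
    spec = FieldSpec(n_cells=1, n_distractors=0, adhesion_fraction=0.0,
                     deformed_fraction=0.0, cell_radius_range=(12.0, 14.0),
                     rng_seed=902)
    field = generate_field(spec)
    gt = field.annotations[0].box
    from dcrnet.detector import _prepare_batch
    images, _ = _prepare_batch([field.to_annotated_image("one")], None)
    with ag.no_grad():
        feats = toy_model.features(images)
        props = toy_model.propose(feats, images.shape[2:], training=False)[0]
    assert props, "no proposals at all"
    assert max(iou(p.box, gt) for p in props[:5]) > 0.5


def test_stained_fixture_cell_is_labelled_stained(toy_model):
    spec = FieldSpec(n_cells=1, stained_fraction=1.0, n_distractors=0,
                     deformed_fraction=0.0, cell_radius_range=(12.0, 14.0),
                     rng_seed=903)
    field = generate_field(spec)
    dets = [d for d in detect(toy_model, field.image) if d.confidence >= 0.5]
    assert dets, "trained model failed to detect the single cell"
    best = max(dets, key=lambda d: iou(d.box, field.annotations[0].box))
    assert best.label == "stained"


def test_blank_background_yields_no_confident_detections(toy_model):
    spec = FieldSpec(n_cells=0, n_distractors=0, rng_seed=904)
    field = generate_field(spec)
    dets = [d for d in detect(toy_model, field.image) if d.confidence >= 0.5]
    assert dets == []


def test_detection_coordinates_lie_within_image_bounds(toy_model):
    field = generate_field(FieldSpec(rng_seed=905))
    for d in detect(toy_model, field.image):
        x0, y0, x1, y1 = d.box
        assert 0 <= x0 < x1 <= 320
        assert 0 <= y0 < y1 <= 240
        assert 0 <= d.confidence <= 1


def test_detections_equivariant_under_horizontal_flip(toy_model):
    """For a flip-augmented-trained model, detections on the mirrored image
    should match the mirrored detections of the original."""
    field = generate_field(FieldSpec(rng_seed=906)).to_annotated_image("eq")
    flipped = flip(field, "horizontal")
    d_orig = [d for d in detect(toy_model, field.image) if d.confidence >= 0.5]
    d_flip = [d for d in detect(toy_model, flipped.image) if d.confidence >= 0.5]
    assert d_orig and d_flip
    w = field.width
    back = [(w - d.box[2], d.box[1], w - d.box[0], d.box[3]) for d in d_flip]
    matched = 0
    for d in d_orig:
        if any(iou(d.box, b) >= 0.5 for b in back):
            matched += 1
    assert matched / len(d_orig) >= 0.8


def test_zero_proposals_give_zero_detections(toy_model):
    x = Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32))
    with ag.no_grad():
        feats = toy_model.features(x)
        out = toy_model.classify_regions(feats, [[]])
    assert out == [[]]


def test_region_class_probabilities_sum_to_one(toy_model, rng):
    pooled = Tensor(rng.normal(size=(6, toy_model.cfg.backbone.fpn_channels,
                                     7, 7)).astype(np.float32))
    with ag.no_grad():
        logits, _ = toy_model.roi_head(pooled)
    probs = ag.softmax(logits.data, axis=1)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert probs.shape[1] == 3          # stained, unstained, background


def test_coco_export_record_shape(toy_model):
    field = generate_field(FieldSpec(rng_seed=907))
    dets = detect(toy_model, field.image)
    records = detections_to_coco({"img0": dets})
    assert len(records) == len(dets)
    for r in records:
        assert set(r) == {"image_id", "category_id", "bbox", "score"}
        assert r["category_id"] in (1, 2)
        assert r["bbox"][2] > 0 and r["bbox"][3] > 0
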