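"""Stage orchestration: synth → prepare → train → detect → evaluate → count.

Each stage writes its artifacts under the configured output directory plus a
JSON run record (configuration hash, seed, package and numpy versions,
artifact list).  Re-running a completed stage is a no-op unless forced, so a
partially finished pipeline can be resumed.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .data import AnnotatedImage, load_image, read_voc, split_6_3_1
from .detector import (CellDetector, DetectorConfig, TrainingSchedule, build_schedule,
                       detect, detections_to_coco, load_checkpoint, train)
from .evaluation import CountSummary, Detection, compare_counts, count_cells, evaluate
from .synth import write_fixture_set

log = logging.getLogger("dcrnet")

STAGES = ("synth", "prepare", "train", "detect", "evaluate", "count")


class StageDependencyError(RuntimeError):
    pass


def _record_path(out: Path, stage: str) -> Path:
    return out / f"{stage}.record.json"


def _stage_done(out: Path, stage: str, cfg: RunConfig) -> bool:
    rec = _record_path(out, stage)
    if not rec.exists():
        return False
    try:
        data = json.loads(rec.read_text())
    except json.JSONDecodeError:
        return False
    if data.get("config_hash") != cfg.hash():
        return False
    return all((out / a).exists() for a in data.get("artifacts", []))


def _write_record(out: Path, stage: str, cfg: RunConfig, artifacts: list[str]) -> None:
    rec = {"stage": stage, "config_hash": cfg.hash(), "seed": cfg.rng_seed,
           "dcrnet_version": __version__, "numpy_version": np.__version__,
           "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
           "artifacts": artifacts}
    _record_path(out, stage).write_text(json.dumps(rec, indent=2))


def _load_fixture_dir(d: Path) -> list[AnnotatedImage]:
    images = []
    for xml in sorted(d.glob("*.xml")):
        anns, _ = read_voc(xml)
        img = load_image(xml.with_suffix(".png"))
        images.append(AnnotatedImage(img, anns, source_id=xml.stem))
    return images


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None,
                 force: bool = False) -> dict[str, list[str]]:
    """Run the requested stages; returns the artifact lists per stage."""
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    done: dict[str, list[str]] = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        if not force and _stage_done(out, stage, cfg):
            log.info("stage %s: up to date, skipping", stage)
            done[stage] = json.loads(_record_path(out, stage).read_text())["artifacts"]
            continue
        runner = globals()[f"_stage_{stage}"]
        artifacts = runner(cfg, out)
        _write_record(out, stage, cfg, artifacts)
        done[stage] = artifacts
        log.info("stage %s: wrote %d artifacts", stage, len(artifacts))
    return done


def _require(out: Path, stage: str, cfg: RunConfig) -> None:
    if not _stage_done(out, stage, cfg):
        raise StageDependencyError(
            f"stage {stage!r} has not produced its artifacts yet; "
            f"run `dcrnet {stage}` first")


def _stage_synth(cfg: RunConfig, out: Path) -> list[str]:
    base = cfg.rng_seed * 10_000
    arts = []
    for name, n, first in (("train", cfg.synth.n_train, base),
                           ("test", cfg.synth.n_test, base + 1000)):
        d = out / f"fields_{name}"
        specs = [cfg.synth.field_spec(first + i) for i in range(n)]
        write_fixture_set(specs, d)
        arts.append(f"fields_{name}/manifest.csv")
    return arts


def _stage_prepare(cfg: RunConfig, out: Path) -> list[str]:
    _require(out, "synth", cfg)
    images = _load_fixture_dir(out / "fields_train")
    groups: dict[str, list[str]] = {}
    for im in images:
        groups.setdefault(im.resolution_tag, []).append(im.source_id)
    split = split_6_3_1(groups, seed=cfg.rng_seed)
    payload = {"train": split.train, "val": split.val, "test": split.test}
    (out / "split.json").write_text(json.dumps(payload, indent=2))
    return ["split.json"]


def _stage_train(cfg: RunConfig, out: Path) -> list[str]:
    _require(out, "synth", cfg)
    images = _load_fixture_dir(out / "fields_train")
    model = CellDetector(DetectorConfig.desk_scale(plain=cfg.train.plain_baseline),
                         seed=cfg.rng_seed)
    if cfg.train.schedule_scale is not None:
        groups: dict[str, list[AnnotatedImage]] = {}
        for im in images:
            groups.setdefault(im.resolution_tag, []).append(im)
        split = split_6_3_1(groups, seed=cfg.rng_seed)
        sched = build_schedule(split, scale=cfg.train.schedule_scale, seed=cfg.rng_seed)
        sched = replace(sched, batch_size=cfg.train.batch_size,
                        learning_rate=cfg.train.learning_rate,
                        max_iterations=cfg.train.iterations)
        images = split.train
    else:
        sched = TrainingSchedule(phases=[("all", 10_000)], batch_size=cfg.train.batch_size,
                                 max_iterations=cfg.train.iterations,
                                 learning_rate=cfg.train.learning_rate,
                                 warmup_iterations=cfg.train.warmup_iterations,
                                 rng_seed=cfg.rng_seed)
    trace = train(model, images, sched, checkpoint_path=out / "checkpoint.npz")
    with open(out / "loss_trace.csv", "w") as fh:
        fh.write("iteration,phase,epoch,total,rpn_cls,rpn_reg,roi_cls,roi_reg\n")
        for r in trace:
            fh.write(f"{r['iteration']},{r['phase']},{r['epoch']},{r['total']:.6f},"
                     f"{r['rpn_cls']:.6f},{r['rpn_reg']:.6f},"
                     f"{r.get('roi_cls', float('nan')):.6f},{r.get('roi_reg', float('nan')):.6f}\n")
    return ["checkpoint.npz", "loss_trace.csv"]


def _stage_detect(cfg: RunConfig, out: Path) -> list[str]:
    _require(out, "synth", cfg)
    _require(out, "train", cfg)
    model = load_checkpoint(out / "checkpoint.npz")
    dets_by_img = {}
    for im in _load_fixture_dir(out / "fields_test"):
        dets_by_img[im.source_id] = detect(model, im.image,
                                           score_threshold=cfg.score_threshold)
    (out / "detections.json").write_text(json.dumps(detections_to_coco(dets_by_img), indent=2))
    return ["detections.json"]


def _load_detections(out: Path) -> dict[str, list[Detection]]:
    from .detector import CLASS_NAMES
    records = json.loads((out / "detections.json").read_text())
    dets: dict[str, list[Detection]] = {}
    for r in records:
        x, y, w, h = r["bbox"]
        dets.setdefault(r["image_id"], []).append(
            Detection((x, y, x + w, y + h), CLASS_NAMES[r["category_id"] - 1], r["score"]))
    return dets


def _stage_evaluate(cfg: RunConfig, out: Path) -> list[str]:
    _require(out, "detect", cfg)
    dets = _load_detections(out)
    gts = {im.source_id: im.annotations for im in _load_fixture_dir(out / "fields_test")}
    for k in gts:
        dets.setdefault(k, [])
    report = evaluate(dets, gts)
    (out / "ap_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    return ["ap_report.json"]


def _stage_count(cfg: RunConfig, out: Path) -> list[str]:
    _require(out, "detect", cfg)
    dets = _load_detections(out)
    auto = count_cells([d for ds in dets.values() for d in ds], cfg.confidence_threshold)
    gt_imgs = _load_fixture_dir(out / "fields_test")
    ref = CountSummary(
        stained=sum(a.label == "stained" for im in gt_imgs for a in im.annotations),
        unstained=sum(a.label == "unstained" for im in gt_imgs for a in im.annotations))
    payload = {"automatic": auto.to_dict(), "reference": ref.to_dict()}
    if auto.total and ref.total:
        cmp_ = compare_counts(auto, ref)
        payload["rate_difference"] = cmp_.rate_difference
        payload["rate_difference_percent"] = cmp_.rate_difference_percent
    (out / "count_summary.json").write_text(json.dumps(payload, indent=2))
    return ["count_summary.json"]


def setup_logging(out_dir: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(out_dir / "run.log"))
    logging.basicConfig(level=logging.INFO, handlers=handlers, force=True,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
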