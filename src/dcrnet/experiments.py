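"""Desk-scale end-to-end experiments.

Bundles the workflow used by the CLI, the test suite and the reproduction
script: generate synthetic fields, train a miniature detector on a single
CPU core, and evaluate it COCO-style on held-out fields.
"""

from __future__ import annotations

from dataclasses import replace

from .data import AnnotatedImage
from .detector import (CellDetector, DetectorConfig, TrainingSchedule, detect, train)
from .evaluation import APReport, CountSummary, Detection, count_cells, evaluate
from .synth import FieldSpec, generate_field

# Conditions of the desk-scale study: 60 training and 20 held-out fields of
# 320x240 px with the default cell statistics (15 nuclei, stained fraction
# 0.19, 10% deformed, 20% adherent, 2 distractors).
N_TRAIN_FIELDS = 60
N_TEST_FIELDS = 20
DESK_ITERATIONS = 300
DESK_BATCH = 2
DESK_LR = 0.01


def make_fields(n: int, first_seed: int, template: FieldSpec | None = None,
                prefix: str = "field") -> list[AnnotatedImage]:
    """n fields rendered from consecutive seeds."""
    template = template or FieldSpec()
    return [generate_field(replace(template, rng_seed=first_seed + i))
            .to_annotated_image(f"{prefix}{first_seed + i}")
            for i in range(n)]


def desk_schedule(seed: int, iterations: int = DESK_ITERATIONS) -> TrainingSchedule:
    return TrainingSchedule(phases=[("all", 10_000)], batch_size=DESK_BATCH,
                            max_iterations=iterations, learning_rate=DESK_LR,
                            warmup_iterations=50, rng_seed=seed)


def train_desk_model(train_fields: list[AnnotatedImage], seed: int,
                     iterations: int = DESK_ITERATIONS, plain: bool = False,
                     checkpoint_path=None, progress: bool = False
                     ) -> tuple[CellDetector, list[dict]]:
    """Train a miniature detector (DCRNet or the plain-residual baseline)."""
    model = CellDetector(DetectorConfig.desk_scale(plain=plain), seed=seed)
    trace = train(model, train_fields, desk_schedule(seed, iterations),
                  checkpoint_path=checkpoint_path, progress=progress)
    return model, trace


def evaluate_on_fields(model: CellDetector, fields: list[AnnotatedImage]
                       ) -> tuple[APReport, dict[str, list[Detection]]]:
    dets = {f.source_id: detect(model, f.image) for f in fields}
    gts = {f.source_id: f.annotations for f in fields}
    return evaluate(dets, gts), dets


def desk_benchmark(model_seed: int, data_seed: int = 0,
                   iterations: int = DESK_ITERATIONS, plain: bool = False
                   ) -> dict:
    """Full desk-scale run: synthesise fields, train, evaluate.

    ``data_seed`` offsets the field seeds so independent replicates use
    independent fields; the held-out fields never overlap the training seeds.
    """
    base = data_seed * 10_000
    train_fields = make_fields(N_TRAIN_FIELDS, base, prefix="train")
    test_fields = make_fields(N_TEST_FIELDS, base + 1000, prefix="test")
    model, trace = train_desk_model(train_fields, model_seed,
                                    iterations=iterations, plain=plain)
    report, dets = evaluate_on_fields(model, test_fields)
    counts = count_cells([d for ds in dets.values() for d in ds],
                         model.cfg.confidence_threshold)
    gt_counts = CountSummary(
        stained=sum(a.label == "stained" for f in test_fields for a in f.annotations),
        unstained=sum(a.label == "unstained" for f in test_fields for a in f.annotations))
    return {"model": model, "trace": trace, "report": report,
            "detections": dets, "counts": counts, "gt_counts": gt_counts}
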