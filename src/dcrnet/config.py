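"""Run configuration: one YAML file drives every pipeline stage.

The schema is strict — unknown keys are rejected so typos fail loudly — and
every artifact a stage writes is accompanied by a run record carrying the
configuration hash and seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
import yaml

from .synth import FieldSpec


class ConfigSchemaError(ValueError):
    pass


def _from_mapping(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigSchemaError(f"{context}: expected a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigSchemaError(f"{context}: unknown keys {sorted(unknown)}; "
                                f"expected a subset of {sorted(known)}")
    return data


@dataclass(frozen=True)
class SynthSection:
    """Synthetic-dataset conditions (see :class:`dcrnet.synth.FieldSpec`)."""

    n_train: int = 60
    n_test: int = 20
    width: int = 320
    height: int = 240
    n_cells: int = 15
    stained_fraction: float = 0.19
    deformed_fraction: float = 0.10
    adhesion_fraction: float = 0.20
    n_distractors: int = 2
    cell_radius_min: float = 8.0
    cell_radius_max: float = 16.0

    def field_spec(self, seed: int = 0) -> FieldSpec:
        return FieldSpec(width=self.width, height=self.height, n_cells=self.n_cells,
                         stained_fraction=self.stained_fraction,
                         deformed_fraction=self.deformed_fraction,
                         adhesion_fraction=self.adhesion_fraction,
                         n_distractors=self.n_distractors,
                         cell_radius_range=(self.cell_radius_min, self.cell_radius_max),
                         rng_seed=seed)


@dataclass(frozen=True)
class TrainSection:
    iterations: int = 300
    batch_size: int = 2
    learning_rate: float = 0.01
    warmup_iterations: int = 50
    schedule_scale: float | None = None   # use the published 30/270-epoch curriculum, scaled
    plain_baseline: bool = False


@dataclass(frozen=True)
class RunConfig:
    out_dir: str = "runs/desk"
    rng_seed: int = 0
    synth: SynthSection = field(default_factory=SynthSection)
    train: TrainSection = field(default_factory=TrainSection)
    score_threshold: float = 0.05
    confidence_threshold: float = 0.5

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(_from_mapping(cls, data, "config"))
        if "synth" in data:
            data["synth"] = SynthSection(**_from_mapping(SynthSection, data["synth"], "config.synth"))
        if "train" in data:
            data["train"] = TrainSection(**_from_mapping(TrainSection, data["train"], "config.train"))
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_overrides(self, seed: int | None = None, scale: float | None = None) -> "RunConfig":
        cfg = self
        if seed is not None:
            cfg = replace(cfg, rng_seed=seed)
        if scale is not None:
            cfg = replace(cfg, train=replace(cfg.train, schedule_scale=scale))
        return cfg
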