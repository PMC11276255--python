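"""The DCRNet backbone.

Three departures from a plain residual backbone define DCRNet:

1. **Aggregated residual blocks** — the bottleneck transform is split into
   many parallel low-width paths (the *cardinality*), implemented here, as in
   the aggregated-residual-transformations literature, as a grouped 3×3
   convolution between 1×1 reduce/expand layers.  At cardinality 64 and path
   width 2 the block has *fewer* weights than the plain 64-wide bottleneck
   while doing essentially the same number of multiply–adds.
2. **Information-preserving down-sampling** — stage transitions use a 2×2
   average pool (stride 2) followed by a stride-1 1×1 convolution, so every
   input grid position influences the output; a strided 1×1 convolution by
   contrast reads only one pixel in four.
3. **Deformable 3×3 convolutions** — in the configured stages the 3×3 kernel
   samples the input at learned fractional per-location displacements
   (bilinear interpolation), letting the receptive field follow deformed,
   spindle- or bar-shaped cells.

A feature pyramid (FPN) over the four stage outputs yields maps at strides
4, 8, 16 and 32 for the detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import BatchNorm2d, Conv2d, DeformableConv2d, Module, ModuleList


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture hyper-parameters of DCRNet.

    Defaults follow the full-scale network (ResNet-101-style stage layout,
    cardinality 64, path width 2, deformable 3×3 convolutions in the last two
    stages).  ``desk_scale`` returns a configuration small enough to train on
    a single CPU core in minutes.
    """

    stem_channels: int = 64
    stage_depths: tuple[int, ...] = (3, 4, 23, 3)
    stage_channels: tuple[int, ...] = (256, 512, 1024, 2048)
    cardinality: int = 64
    path_width: int = 2
    stage_mid_channels: tuple[int, ...] | None = None
    deformable_stages: frozenset[int] = frozenset({2, 3})
    downsample_mode: str = "dcr"
    fpn_channels: int = 256

    def __post_init__(self):
        if self.cardinality < 1 or self.path_width < 1:
            raise ConfigError("cardinality and path_width must be >= 1")
        if len(self.stage_depths) != len(self.stage_channels):
            raise ConfigError("stage_depths and stage_channels length mismatch")
        if any(d < 1 for d in self.stage_depths):
            raise ConfigError("stage depths must be positive")
        ns = len(self.stage_depths)
        if any(not (0 <= s < ns) for s in self.deformable_stages):
            raise ConfigError(f"deformable_stages must be stage indices in [0, {ns})")
        if self.downsample_mode not in ("dcr", "strided"):
            raise ConfigError(f"unknown downsample_mode {self.downsample_mode!r}")
        if self.stage_mid_channels is not None:
            if len(self.stage_mid_channels) != ns:
                raise ConfigError("stage_mid_channels length mismatch")
            if any(m % self.cardinality for m in self.stage_mid_channels):
                raise ConfigError("stage mid channels must be divisible by cardinality")

    def mid_channels(self, stage: int) -> int:
        if self.stage_mid_channels is not None:
            return self.stage_mid_channels[stage]
        return self.cardinality * self.path_width * (2 ** stage)

    @classmethod
    def desk_scale(cls, deformable: bool = True, plain: bool = False) -> "BackboneConfig":
        """A CPU-trainable miniature.

        ``plain=True`` degenerates to the ablation baseline: cardinality 1,
        strided down-sampling, no deformable convolutions.
        """
        if plain:
            return cls(stem_channels=8, stage_depths=(1, 1, 1, 1),
                       stage_channels=(24, 32, 48, 64), cardinality=1, path_width=16,
                       stage_mid_channels=(16, 16, 24, 32),
                       deformable_stages=frozenset(), downsample_mode="strided",
                       fpn_channels=32)
        return cls(stem_channels=8, stage_depths=(1, 1, 1, 1),
                   stage_channels=(24, 32, 48, 64), cardinality=8, path_width=2,
                   stage_mid_channels=(16, 16, 24, 32),
                   deformable_stages=frozenset({2, 3}) if deformable else frozenset(),
                   downsample_mode="dcr", fpn_channels=32)

    def to_dict(self) -> dict:
        return {
            "stem_channels": self.stem_channels,
            "stage_depths": list(self.stage_depths),
            "stage_channels": list(self.stage_channels),
            "cardinality": self.cardinality,
            "path_width": self.path_width,
            "stage_mid_channels": (list(self.stage_mid_channels)
                                   if self.stage_mid_channels is not None else None),
            "deformable_stages": sorted(self.deformable_stages),
            "downsample_mode": self.downsample_mode,
            "fpn_channels": self.fpn_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneConfig":
        d = dict(d)
        for key in ("stage_depths", "stage_channels"):
            d[key] = tuple(d[key])
        if d.get("stage_mid_channels") is not None:
            d["stage_mid_channels"] = tuple(d["stage_mid_channels"])
        d["deformable_stages"] = frozenset(d.get("deformable_stages", ()))
        return cls(**d)


class AggregatedResidualBlock(Module):
    """Split–transform–merge residual unit.

    1×1 reduce → grouped (cardinality-path) 3×3 → 1×1 expand, with batch
    normalisation after every convolution and a rectified-linear output.  The
    grouped convolution is mathematically identical to summing ``cardinality``
    independent low-width bottleneck paths.  Stride is always 1; spatial
    down-sampling lives in the stage transitions.
    """

    def __init__(self, in_ch: int, out_ch: int, mid_ch: int, cardinality: int,
                 rng: np.random.Generator, deformable: bool = False):
        super().__init__()
        if mid_ch % cardinality:
            raise ConfigError(f"mid channels {mid_ch} not divisible by cardinality {cardinality}")
        self.conv1 = Conv2d(in_ch, mid_ch, 1, rng)
        self.bn1 = BatchNorm2d(mid_ch)
        if deformable:
            self.conv2 = DeformableConv2d(mid_ch, mid_ch, 3, rng, padding=1, groups=cardinality)
        else:
            self.conv2 = Conv2d(mid_ch, mid_ch, 3, rng, padding=1, groups=cardinality)
        self.bn2 = BatchNorm2d(mid_ch)
        self.conv3 = Conv2d(mid_ch, out_ch, 1, rng)
        self.bn3 = BatchNorm2d(out_ch)
        if in_ch != out_ch:
            self.proj = Conv2d(in_ch, out_ch, 1, rng)
            self.proj_bn = BatchNorm2d(out_ch)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        y = ag.relu(self.bn1(self.conv1(x)))
        y = ag.relu(self.bn2(self.conv2(y)))
        y = self.bn3(self.conv3(y))
        sc = x if self.proj is None else self.proj_bn(self.proj(x))
        return ag.relu(ag.add(y, sc))

    def conv_weight_count(self) -> int:
        """Number of convolution-kernel weights (main path + projection),
        excluding normalisation affines, biases and the offset branch."""
        n = self.conv1.weight.data.size + self.conv2.weight.data.size + self.conv3.weight.data.size
        if self.proj is not None:
            n += self.proj.weight.data.size
        return n

    def mac_count(self, h: int, w: int) -> int:
        """Multiply–accumulate operations of the main-path convolutions for an
        h×w input (all convolutions are stride 1 and padding-preserving)."""
        return self.conv_weight_count() * h * w


def block_accounting(in_ch: int = 256, cardinality: int = 64, path_width: int = 2,
                     plain_mid: int = 64) -> dict[str, int | float]:
    """Weight/MAC accounting of the aggregated block versus the plain
    bottleneck of equal input/output width, computed from instantiated blocks.
    """
    rng = np.random.default_rng(0)
    agg = AggregatedResidualBlock(in_ch, in_ch, cardinality * path_width, cardinality, rng)
    plain = AggregatedResidualBlock(in_ch, in_ch, plain_mid, 1, rng)
    pa, pp = agg.conv_weight_count(), plain.conv_weight_count()
    return {
        "aggregated_weights": pa,
        "plain_weights": pp,
        "mac_ratio": agg.mac_count(1, 1) / plain.mac_count(1, 1),
        "fewer_parameters": pa < pp,
    }


class DcrDownsample(Module):
    """Stage-transition down-sampling.

    ``mode="dcr"``: 2×2 average pool (stride 2) then a stride-1 1×1
    convolution — every input position contributes to the output.
    ``mode="strided"``: the conventional stride-2 1×1 convolution, which reads
    only the top-left pixel of each 2×2 block (the ablation baseline).
    Odd spatial dimensions are replicate-padded before pooling.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 mode: str = "dcr", bn: bool = True):
        super().__init__()
        if mode not in ("dcr", "strided"):
            raise ConfigError(f"unknown downsample mode {mode!r}")
        self.mode = mode
        stride = 1 if mode == "dcr" else 2
        self.conv = Conv2d(in_ch, out_ch, 1, rng, stride=stride)
        self.bn = BatchNorm2d(out_ch) if bn else None

    def forward(self, x: Tensor) -> Tensor:
        if self.mode == "dcr":
            x = ag.avg_pool2d(x, 2)
            y = self.conv(x)
        else:
            xd = x.data
            if xd.shape[2] % 2 or xd.shape[3] % 2:
                ph = (-xd.shape[2]) % 2
                pw = (-xd.shape[3]) % 2
                pad = Tensor(np.pad(xd, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge"))
                # padding is outside the graph; gradients for the replicated
                # row/col are dropped (baseline only, never trained alone)
                pad.requires_grad = x.requires_grad
                pad._parents = (x,)
                H, W = xd.shape[2], xd.shape[3]
                pad._backward = lambda g, _x=x, _H=H, _W=W: _x.accumulate(g[:, :, :_H, :_W])
                x = pad
            y = self.conv(x)
        if self.bn is not None:
            y = ag.relu(self.bn(y))
        return y


class DCRNet(Module):
    """Stem + four stages of aggregated residual blocks with DCR stage
    transitions, topped with a feature pyramid.

    ``forward`` maps an image batch (N, 3, H, W) to pyramid levels P2..P5 at
    strides 4/8/16/32, each with ``cfg.fpn_channels`` channels.
    """

    STRIDES = (4, 8, 16, 32)

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.stem_conv = Conv2d(3, cfg.stem_channels, 7, rng, stride=2, padding=3)
        self.stem_bn = BatchNorm2d(cfg.stem_channels)
        self.stages = ModuleList()
        self.transitions = ModuleList()
        in_ch = cfg.stem_channels
        for si, (depth, out_ch) in enumerate(zip(cfg.stage_depths, cfg.stage_channels)):
            if si > 0:
                self.transitions.append(
                    DcrDownsample(in_ch, out_ch, rng, mode=cfg.downsample_mode))
                in_ch = out_ch
            blocks = ModuleList()
            for bi in range(depth):
                blocks.append(AggregatedResidualBlock(
                    in_ch, out_ch, cfg.mid_channels(si), cfg.cardinality, rng,
                    deformable=si in cfg.deformable_stages))
                in_ch = out_ch
            self.stages.append(blocks)
        self.laterals = ModuleList(
            [Conv2d(c, cfg.fpn_channels, 1, rng, bias=True) for c in cfg.stage_channels])
        self.smooths = ModuleList(
            [Conv2d(cfg.fpn_channels, cfg.fpn_channels, 3, rng, padding=1, bias=True)
             for _ in cfg.stage_channels])

    def forward(self, x: Tensor) -> list[Tensor]:
        y = ag.relu(self.stem_bn(self.stem_conv(x)))
        y = ag.avg_pool2d(y, 2)
        cs = []
        for si, blocks in enumerate(self.stages):
            if si > 0:
                y = self.transitions[si - 1](y)
            for blk in blocks:
                y = blk(y)
            cs.append(y)
        # top-down pyramid
        ms = [None] * len(cs)
        ms[-1] = self.laterals[-1](cs[-1])
        for i in range(len(cs) - 2, -1, -1):
            lat = self.laterals[i](cs[i])
            up = ag.upsample_nearest2x(ms[i + 1], out_hw=lat.data.shape[2:])
            ms[i] = ag.add(lat, up)
        return [self.smooths[i](ms[i]) for i in range(len(cs))]


def build_backbone(cfg: BackboneConfig, seed: int = 0) -> DCRNet:
    """Construct a DCRNet with reproducible random initialisation."""
    return DCRNet(cfg, np.random.default_rng(seed))
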