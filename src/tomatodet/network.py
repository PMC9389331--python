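"""Attentive aggregation backbone and circle-detection heads.

The backbone follows the deep-layer-aggregation pattern: a stack of
strided stages whose features are fused back to the output stride by
iterative upsample-and-merge (IDA), with tree-style aggregation nodes
inside multi-block stages (HDA).  A convolutional block attention module
(CBAM) — channel attention followed by spatial attention, each a sigmoid
gate multiplied element-wise onto the features — is applied to every stage
output.  Three sibling heads predict the keypoint heatmap (sigmoid), the
sub-cell center offsets, and the object size (radius, or width/height for
the box-head ablation).

Two presets are provided: ``dla34_cbam`` mirrors the full six-stage layout,
and ``tiny`` is a four-stage reduction small enough to train on a CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import BatchNorm2d, Conv2d, Module, Tensor, concat, upsample2x

__all__ = [
    "NetworkConfig",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "CircleDetector",
    "build_network",
    "save_checkpoint",
    "load_checkpoint",
]

_PRESETS = {
    "dla34_cbam": dict(
        stage_channels=[16, 32, 64, 128, 256, 512],
        cbam_reduction=16,
        head_channels=256,
        blocks_per_stage=2,
    ),
    "tiny": dict(
        stage_channels=[8, 16, 32, 64],
        cbam_reduction=4,
        head_channels=32,
        blocks_per_stage=1,
    ),
}


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``output_stride`` must divide the input dimensions; ``head_type`` is
    ``"circle"`` (1-channel radius head) or ``"box"`` (2-channel
    width/height head, the ablation baseline).
    """

    preset: str = "tiny"
    stage_channels: list[int] = field(default_factory=list)
    cbam_reduction: int = 0
    cbam_spatial_kernel: int = 7
    output_stride: int = 4
    num_classes: int = 1
    head_channels: int = 0
    blocks_per_stage: int = 0
    use_cbam: bool = True
    head_type: str = "circle"
    seed: int = 0

    def __post_init__(self):
        if self.preset not in _PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        defaults = _PRESETS[self.preset]
        if not self.stage_channels:
            self.stage_channels = list(defaults["stage_channels"])
        if not self.cbam_reduction:
            self.cbam_reduction = defaults["cbam_reduction"]
        if not self.head_channels:
            self.head_channels = defaults["head_channels"]
        if not self.blocks_per_stage:
            self.blocks_per_stage = defaults["blocks_per_stage"]
        if self.cbam_spatial_kernel % 2 == 0:
            raise ValueError("cbam_spatial_kernel must be odd")
        if self.output_stride & (self.output_stride - 1):
            raise ValueError("output_stride must be a power of two")
        if self.head_type not in ("circle", "box"):
            raise ValueError(f"head_type must be 'circle' or 'box', got {self.head_type!r}")


class ChannelAttention(Module):
    """Channel gate: shared bottleneck MLP over avg- and max-pooled descriptors.

    Produces a (N, C, 1, 1) map in (0, 1): ``sigmoid(MLP(avgpool F) +
    MLP(maxpool F))`` with a two-layer MLP of bottleneck width C/rho.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Conv2d(channels, hidden, 1, pad=0, bias=True, rng=rng)
        self.fc2 = Conv2d(hidden, channels, 1, pad=0, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3), keepdims=True)
        mx = x.max(axis=3, keepdims=True).max(axis=2, keepdims=True)
        gate = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return gate.sigmoid()


class SpatialAttention(Module):
    """Spatial gate: k x k conv over the channel-wise mean and max maps."""

    def __init__(self, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel, pad=kernel // 2, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(concat([avg, mx], axis=1)).sigmoid()


class CBAM(Module):
    """Sequential channel-then-spatial attention, multiplied onto the input."""

    def __init__(self, channels: int, reduction: int, spatial_kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng)
        self.spatial = SpatialAttention(spatial_kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.channel(x) * x
        return self.spatial(x) * x


class _ConvBNReLU(Module):
    def __init__(self, cin, cout, kernel, stride, rng):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, stride=stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()


class _ResidualBlock(Module):
    def __init__(self, channels, rng):
        super().__init__()
        self.conv1 = Conv2d(channels, channels, 3, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(channels)
        self.conv2 = Conv2d(channels, channels, 3, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(channels)

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        return (out + x).relu()


class _Stage(Module):
    """Strided stage: downsample, residual blocks, tree aggregation node."""

    def __init__(self, cin, cout, blocks, rng):
        super().__init__()
        self.down = _ConvBNReLU(cin, cout, 3, stride=2, rng=rng)
        self.blocks = [_ResidualBlock(cout, rng) for _ in range(blocks)]
        # HDA-style node fusing the block outputs when the stage has depth
        self.agg = _ConvBNReLU(cout * blocks, cout, 1, stride=1, rng=rng) if blocks > 1 else None

    def forward(self, x):
        x = self.down(x)
        outs = []
        for blk in self.blocks:
            x = blk(x)
            outs.append(x)
        if self.agg is not None:
            x = self.agg(concat(outs, axis=1))
        return x


class _Head(Module):
    def __init__(self, cin, mid, cout, rng, bias_init: float = 0.0):
        super().__init__()
        self.conv1 = Conv2d(cin, mid, 3, bias=True, rng=rng)
        self.conv2 = Conv2d(mid, cout, 1, pad=0, bias=True, rng=rng)
        self.conv2.bias.data[:] = bias_init

    def forward(self, x):
        return self.conv2(self.conv1(x).relu())


class CircleDetector(Module):
    """Full detector: attentive aggregation backbone plus three heads.

    ``forward`` maps a (N, 3, H, W) image batch (H, W divisible by the
    output stride) to ``(heatmap, offsets, size)`` tensors of shapes
    (N, C, H/K, W/K), (N, 2, H/K, W/K) and (N, S, H/K, W/K), where S is 1
    for the radius head and 2 for the box head.  The heatmap is
    post-sigmoid; its final bias starts at ``-log(99)`` so the initial
    foreground probability is about 0.01, which keeps the focal loss from
    saturating early in training.
    """

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.stage_channels
        self.stem = _ConvBNReLU(3, ch[0], 3, stride=1, rng=rng)
        self.stages = [
            _Stage(ch[i - 1], ch[i], cfg.blocks_per_stage, rng) for i in range(1, len(ch))
        ]
        self.cbams = (
            [CBAM(c, cfg.cbam_reduction, cfg.cbam_spatial_kernel, rng) for c in ch]
            if cfg.use_cbam
            else []
        )
        k_idx = int(np.log2(cfg.output_stride))
        if k_idx >= len(ch):
            raise ValueError("output_stride too large for stage list")
        self._k_idx = k_idx
        # IDA: project deeper features up and merge iteratively down to stride K
        self.proj = []
        self.merge = []
        for i in range(len(ch) - 1, k_idx, -1):
            self.proj.append(_ConvBNReLU(ch[i], ch[i - 1], 1, stride=1, rng=rng))
            self.merge.append(_ConvBNReLU(ch[i - 1] * 2, ch[i - 1], 3, stride=1, rng=rng))
        feat_ch = ch[k_idx]
        size_out = 1 if cfg.head_type == "circle" else 2
        self.head_hm = _Head(feat_ch, cfg.head_channels, cfg.num_classes, rng,
                             bias_init=-float(np.log(99.0)))
        self.head_off = _Head(feat_ch, cfg.head_channels, 2, rng)
        self.head_size = _Head(feat_ch, cfg.head_channels, size_out, rng)

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    @property
    def input_divisor(self) -> int:
        """Input dims must be divisible by the deepest stage stride so the
        upsample-and-merge path realigns exactly."""
        return 2 ** len(self.stages)

    def forward(self, images) -> tuple[Tensor, Tensor, Tensor]:
        x = images if isinstance(images, Tensor) else Tensor(np.asarray(images, np.float32))
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        n, c, h, w = x.shape
        div = self.input_divisor
        if h % div or w % div:
            raise ValueError(f"input dims {w}x{h} not divisible by {div}")
        feats = []
        out = self.stem(x)
        if self.cbams:
            out = self.cbams[0](out)
        feats.append(out)
        for i, stage in enumerate(self.stages, start=1):
            out = stage(out)
            if self.cbams:
                out = self.cbams[i](out)
            feats.append(out)
        agg = feats[-1]
        for step, i in enumerate(range(len(feats) - 1, self._k_idx, -1)):
            agg = upsample2x(self.proj[step](agg))
            agg = self.merge[step](concat([agg, feats[i - 1]], axis=1))
        hm = self.head_hm(agg).sigmoid()
        off = self.head_off(agg)
        size = self.head_size(agg)
        return hm, off, size


def build_network(cfg: NetworkConfig | None = None, **overrides) -> CircleDetector:
    if cfg is None:
        cfg = NetworkConfig(**overrides)
    return CircleDetector(cfg)


def save_checkpoint(path: str | Path, model: CircleDetector) -> None:
    """Write weights (npz) with the architecture config embedded as JSON."""
    path = Path(path)
    arrays = {f"a{i}": arr for i, arr in enumerate(model.state_arrays())}
    cfg_json = json.dumps(asdict(model.cfg))
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> CircleDetector:
    with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path) as z:
        cfg = NetworkConfig(**json.loads(bytes(z["__config__"]).decode()))
        model = CircleDetector(cfg)
        arrays = [z[f"a{i}"] for i in range(len(z.files) - 1)]
    model.load_state_arrays(arrays)
    model.eval()
    return model
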