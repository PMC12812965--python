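"""3-D densely connected convolutional encoder for MRI volumes.

A dense block stacks composite layers (batch-norm -> ReLU -> 3x3x3 conv),
each consuming the channel-concatenation of every earlier feature map and
emitting `growth_rate` new channels.  Transition layers between blocks halve
the channel count (1x1x1 conv) and the spatial side (2x2x2 average pool).
A final adaptive average pool plus 1x1x1 projection yields a fixed
out_channels x pooled_side^3 feature map regardless of input side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from ._autograd import Tensor, concat, no_grad
from .exceptions import CheckpointError, DimensionError
from .preprocess import VolumeImage

__all__ = ["DenseNetConfig", "FeatureMap3D", "DenseBlock", "DenseNet3D",
           "dense_block_forward", "encode_mri", "save_checkpoint",
           "load_checkpoint"]

CHECKPOINT_VERSION = 1


@dataclass
class DenseNetConfig:
    block_layers: list[int] = field(default_factory=lambda: [6, 12, 24, 16])
    growth_rate: int = 32
    init_channels: int = 64
    dropout: float = 0.2
    pooled_side: int = 7
    out_channels: int = 256
    seed: int = 0

    def __post_init__(self):
        if not self.block_layers:
            raise ValueError("block_layers must be non-empty")
        if self.growth_rate < 1 or self.pooled_side < 1:
            raise ValueError("growth_rate and pooled_side must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @classmethod
    def tiny(cls, seed: int = 0) -> "DenseNetConfig":
        """Desk-scale preset: side-16 inputs, two small blocks."""
        return cls(block_layers=[2, 2], growth_rate=8, init_channels=16,
                   dropout=0.2, pooled_side=2, out_channels=32, seed=seed)

    @property
    def min_input_side(self) -> int:
        # stem divides the side by 4; each transition by a further 2
        return 4 * 2 ** (len(self.block_layers) - 1)


@dataclass
class FeatureMap3D:
    """Channels-first (C, D, H, W) activation tensor for one patient."""

    tensor: np.ndarray
    patient_id: str = ""

    def __post_init__(self):
        self.tensor = np.asarray(self.tensor, dtype=np.float64)
        if self.tensor.ndim != 4 or min(self.tensor.shape) < 1:
            raise DimensionError(
                f"feature map must be (C, D, H, W), got {self.tensor.shape}")
        if not np.isfinite(self.tensor).all():
            raise ValueError("feature map contains non-finite values")


class _DenseLayer(nn.Module):
    """BN -> ReLU -> 3x3x3 conv emitting `growth_rate` channels."""

    def __init__(self, in_channels: int, growth_rate: int,
                 rng: np.random.Generator):
        super().__init__()
        self.bn = nn.BatchNorm3d(in_channels)
        self.conv = nn.Conv3d(in_channels, growth_rate, kernel=3, padding=1,
                              rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(self.bn(x).relu())


class DenseBlock(nn.Module):
    """`n_layers` dense layers; layer l consumes the concatenation of the
    block input and all previous layers' outputs (channel growth = k/layer)."""

    def __init__(self, in_channels: int, n_layers: int, growth_rate: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.growth_rate = growth_rate
        self.n_layers = n_layers
        for i in range(n_layers):
            setattr(self, f"dense{i}",
                    _DenseLayer(in_channels + i * growth_rate, growth_rate, rng))

    @property
    def out_channels(self) -> int:
        return self.in_channels + self.n_layers * self.growth_rate

    def forward(self, x: Tensor) -> Tensor:
        feats = [x]
        for i in range(self.n_layers):
            layer = getattr(self, f"dense{i}")
            inp = feats[0] if len(feats) == 1 else concat(feats, axis=1)
            feats.append(layer(inp))
        return concat(feats, axis=1) if len(feats) > 1 else feats[0]

    def channel_trace(self) -> list[int]:
        """Channel count entering each layer and leaving the block."""
        trace = [self.in_channels + i * self.growth_rate
                 for i in range(self.n_layers)]
        trace.append(self.out_channels)
        return trace


class _Transition(nn.Module):
    """BN -> ReLU -> 1x1x1 conv (0.5 compression) -> 2x2x2 avg-pool."""

    def __init__(self, in_channels: int, rng: np.random.Generator):
        super().__init__()
        self.out_channels = in_channels // 2
        self.bn = nn.BatchNorm3d(in_channels)
        self.conv = nn.Conv3d(in_channels, self.out_channels, kernel=1, rng=rng)
        self.pool = nn.AvgPool3d(kernel=2, stride=2)

    def forward(self, x: Tensor) -> Tensor:
        return self.pool(self.conv(self.bn(x).relu()))


class DenseNet3D(nn.Module):
    """Volumetric dense encoder: stem -> dense blocks/transitions ->
    adaptive pool -> 1x1x1 projection to `out_channels`."""

    def __init__(self, cfg: DenseNetConfig | None = None, in_channels: int = 1):
        super().__init__()
        cfg = cfg or DenseNetConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.stem_conv = nn.Conv3d(in_channels, cfg.init_channels, kernel=7,
                                   stride=2, padding=3, rng=rng)
        self.stem_bn = nn.BatchNorm3d(cfg.init_channels)
        self.stem_pool = nn.MaxPool3d(kernel=3, stride=2, padding=1)
        channels = cfg.init_channels
        self.blocks: list[DenseBlock] = []
        self.transitions: list[_Transition] = []
        for b, n_layers in enumerate(cfg.block_layers):
            block = DenseBlock(channels, n_layers, cfg.growth_rate, rng)
            setattr(self, f"block{b}", block)
            self.blocks.append(block)
            channels = block.out_channels
            if b < len(cfg.block_layers) - 1:
                trans = _Transition(channels, rng)
                setattr(self, f"transition{b}", trans)
                self.transitions.append(trans)
                channels = trans.out_channels
        self.final_bn = nn.BatchNorm3d(channels)
        self.dropout = nn.Dropout(cfg.dropout,
                                  rng=np.random.default_rng(cfg.seed + 1))
        self.adaptive_pool = nn.AdaptiveAvgPool3d(cfg.pooled_side)
        self.project = nn.Conv3d(channels, cfg.out_channels, kernel=1,
                                 bias=True, rng=rng)
        self.pre_projection_channels = channels

    def forward(self, x: Tensor) -> Tensor:
        """(B, 1, S, S, S) -> (B, out_channels, p, p, p)."""
        side = x.shape[2]
        if side < self.cfg.min_input_side:
            raise DimensionError(
                f"input side {side} below the architecture minimum "
                f"{self.cfg.min_input_side}")
        x = self.stem_pool(self.stem_bn(self.stem_conv(x)).relu())
        for b, block in enumerate(self.blocks):
            x = self.dropout(block(x))
            if b < len(self.transitions):
                x = self.transitions[b](x)
        x = self.final_bn(x).relu()
        return self.project(self.adaptive_pool(x))

    # -- architecture introspection (no arithmetic duplicated elsewhere) ------
    def trace_shapes(self, input_side: int) -> list[tuple[str, tuple]]:
        """Walk the real layers, recording (stage, (C, side)) without
        allocating activations — used for conformance checks on large inputs."""
        if input_side < self.cfg.min_input_side:
            raise DimensionError(
                f"input side {input_side} below minimum {self.cfg.min_input_side}")
        trace: list[tuple[str, tuple]] = [("input", (1, input_side))]
        side = self.stem_conv.output_side(input_side)
        side = self.stem_pool.output_side(side)
        c = self.stem_conv.weight.shape[0]
        trace.append(("stem", (c, side)))
        for b, block in enumerate(self.blocks):
            for i, c_in in enumerate(block.channel_trace()[:-1]):
                layer = getattr(block, f"dense{i}")
                assert layer.conv.weight.shape[1] == c_in
                trace.append((f"block{b}.layer{i}.in", (c_in, side)))
            c = block.out_channels
            trace.append((f"block{b}.out", (c, side)))
            if b < len(self.transitions):
                c = self.transitions[b].out_channels
                side = side // 2
                trace.append((f"transition{b}", (c, side)))
        trace.append(("adaptive_pool", (c, self.cfg.pooled_side)))
        trace.append(("projection",
                      (self.project.weight.shape[0], self.cfg.pooled_side)))
        return trace


def dense_block_forward(fmap: FeatureMap3D, layers: int, growth_rate: int,
                        seed: int = 0) -> FeatureMap3D:
    """Run one freshly initialized dense block over a feature map
    (eval mode); output channels = input channels + layers * growth_rate."""
    block = DenseBlock(fmap.tensor.shape[0], layers, growth_rate,
                       rng=np.random.default_rng(seed))
    block.eval()
    with no_grad():
        out = block(Tensor(fmap.tensor[None]))
    return FeatureMap3D(tensor=out.data[0], patient_id=fmap.patient_id)


def encode_mri(volume: VolumeImage, cfg: DenseNetConfig | None = None,
               model: DenseNet3D | None = None) -> FeatureMap3D:
    """Encode one preprocessed cubic volume into its spatial feature map."""
    if model is None:
        model = DenseNet3D(cfg)
    model.eval()
    x = Tensor(volume.data[None, None])
    with no_grad():
        out = model(x)
    return FeatureMap3D(tensor=out.data[0], patient_id=volume.id)


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(model: nn.Module, path: str,
                    meta: dict | None = None) -> None:
    """Single-file .npz container with a version field and JSON metadata."""
    state = model.state_dict()
    header = json.dumps({"version": CHECKPOINT_VERSION, "meta": meta or {}})
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(model: nn.Module, path: str) -> dict:
    try:
        archive = np.load(path)
    except (IOError, ValueError) as exc:
        raise CheckpointError(f"cannot read checkpoint {path!r}: {exc}") from exc
    if "__header__" not in archive:
        raise CheckpointError("checkpoint missing version header")
    header = json.loads(bytes(archive["__header__"]).decode())
    if header.get("version") != CHECKPOINT_VERSION:
        raise CheckpointError(
            f"checkpoint version {header.get('version')} unsupported")
    state = {k: archive[k] for k in archive.files if k != "__header__"}
    model.load_state_dict(state)
    return header.get("meta", {})
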