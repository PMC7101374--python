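"""The four U-shaped segmentation architectures.

All variants share an encoder-decoder core with skip connections and differ
in their convolution blocks and stage count:

- ``unet``: plain double-conv blocks.
- ``all_dropout``: double-conv blocks with dropout after every convolution.
- ``bru_net``: residual blocks with 1x1 bottlenecks.
- ``u2net``: two cascaded U-shaped stages, the second refining the first.

Networks are fully convolutional; inputs padded to a multiple of
``2**(depth-1)`` upstream (see :mod:`prlquant.networks.training`).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from prlquant.networks import ops
from prlquant.networks.ops import Tensor

ARCH_NAMES = ("unet", "all_dropout", "bru_net", "u2net")


@dataclass
class ModelConfig:
    arch_name: str = "unet"
    depth: int = 3  # resolution levels (>= 2)
    base_channels: int = 8
    dropout_rate: float = 0.2
    loss_name: str = "bce_dice"
    learning_rate: float = 1e-3
    batch_size: int = 4
    max_epochs: int = 30
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch_name not in ARCH_NAMES:
            raise ValueError(
                f"unknown arch_name {self.arch_name!r}; expected one of {ARCH_NAMES}"
            )
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class Ctx:
    """Forward-pass context: training flag and dropout RNG."""

    training: bool = False
    rng: np.random.Generator | None = None


class Module:
    """Base class; parameters collected recursively from attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            params.extend(_collect(value))
        return params

    def forward(self, x: Tensor, ctx: Ctx) -> Tensor:  # pragma: no cover
        raise NotImplementedError

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _collect(value) -> list[Tensor]:
    if isinstance(value, Tensor) and value.requires_grad:
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out: list[Tensor] = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        std = np.sqrt(2.0 / fan_in)  # He initialization
        self.w = Tensor(rng.normal(0.0, std, size=(cout, cin, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.pad = k // 2

    def forward(self, x: Tensor, ctx: Ctx) -> Tensor:
        return ops.conv2d(x, self.w, self.b, self.pad)


class DoubleConv(Module):
    """conv3x3-ReLU twice; optional dropout after each convolution."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 dropout_rate: float = 0.0):
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.dropout_rate = dropout_rate

    def forward(self, x: Tensor, ctx: Ctx) -> Tensor:
        h = ops.relu(self.conv1.forward(x, ctx))
        h = ops.dropout(h, self.dropout_rate, ctx.rng, ctx.training)
        h = ops.relu(self.conv2.forward(h, ctx))
        h = ops.dropout(h, self.dropout_rate, ctx.rng, ctx.training)
        return h


class ResBottleneck(Module):
    """Residual block with a 1x1 -> 3x3 -> 1x1 bottleneck."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 dropout_rate: float = 0.0):
        mid = max(cout // 4, 4)
        self.reduce = Conv2d(cin, mid, 1, rng)
        self.conv = Conv2d(mid, mid, 3, rng)
        self.expand = Conv2d(mid, cout, 1, rng)
        self.proj = Conv2d(cin, cout, 1, rng) if cin != cout else None

    def forward(self, x: Tensor, ctx: Ctx) -> Tensor:
        h = ops.relu(self.reduce.forward(x, ctx))
        h = ops.relu(self.conv.forward(h, ctx))
        h = self.expand.forward(h, ctx)
        skip = x if self.proj is None else self.proj.forward(x, ctx)
        return ops.relu(ops.add(h, skip))


class UCore(Module):
    """Encoder-decoder with skip connections; emits base_channels features."""

    def __init__(self, cin: int, depth: int, base: int, rng: np.random.Generator,
                 block_cls=DoubleConv, dropout_rate: float = 0.0):
        self.depth = depth
        ch = [base * 2 ** i for i in range(depth)]
        self.enc = [
            block_cls(cin if i == 0 else ch[i - 1], ch[i], rng, dropout_rate)
            for i in range(depth - 1)
        ]
        self.bottom = block_cls(ch[depth - 2], ch[depth - 1], rng, dropout_rate)
        self.upconvs = [Conv2d(ch[i + 1], ch[i], 3, rng) for i in range(depth - 2, -1, -1)]
        self.dec = [
            block_cls(2 * ch[i], ch[i], rng, dropout_rate)
            for i in range(depth - 2, -1, -1)
        ]

    def forward(self, x: Tensor, ctx: Ctx) -> Tensor:
        skips: list[Tensor] = []
        h = x
        for block in self.enc:
            h = block.forward(h, ctx)
            skips.append(h)
            h = ops.maxpool2(h)
        h = self.bottom.forward(h, ctx)
        for upconv, block, skip in zip(self.upconvs, self.dec, reversed(skips)):
            h = upconv.forward(ops.upsample2(h), ctx)
            h = block.forward(ops.concat(skip, h), ctx)
        return h


class UNet(Module):
    def __init__(self, config: ModelConfig):
        rng = np.random.default_rng(config.seed)
        self.core = UCore(1, config.depth, config.base_channels, rng)
        self.head = Conv2d(config.base_channels, 1, 1, rng)

    def forward(self, x: Tensor, ctx: Ctx) -> Tensor:
        return self.head.forward(self.core.forward(x, ctx), ctx)


class AllDropout(Module):
    """U-shaped net with dropout after every convolution block."""

    def __init__(self, config: ModelConfig):
        rng = np.random.default_rng(config.seed)
        self.core = UCore(1, config.depth, config.base_channels, rng,
                          dropout_rate=config.dropout_rate)
        self.head = Conv2d(config.base_channels, 1, 1, rng)

    def forward(self, x: Tensor, ctx: Ctx) -> Tensor:
        return self.head.forward(self.core.forward(x, ctx), ctx)


class BRUNet(Module):
    """U-shaped net built from residual bottleneck blocks."""

    def __init__(self, config: ModelConfig):
        rng = np.random.default_rng(config.seed)
        self.core = UCore(1, config.depth, config.base_channels, rng,
                          block_cls=ResBottleneck)
        self.head = Conv2d(config.base_channels, 1, 1, rng)

    def forward(self, x: Tensor, ctx: Ctx) -> Tensor:
        return self.head.forward(self.core.forward(x, ctx), ctx)


class U2Net(Module):
    """Two cascaded U-shaped stages; stage 2 refines stage-1 features."""

    def __init__(self, config: ModelConfig):
        rng = np.random.default_rng(config.seed)
        base = config.base_channels
        self.stage1 = UCore(1, config.depth, base, rng)
        self.stage2 = UCore(1 + base, config.depth, base, rng)
        self.head = Conv2d(base, 1, 1, rng)

    def forward(self, x: Tensor, ctx: Ctx) -> Tensor:
        f1 = self.stage1.forward(x, ctx)
        f2 = self.stage2.forward(ops.concat(x, f1), ctx)
        return self.head.forward(f2, ctx)


_ARCH_CLASSES = {
    "unet": UNet,
    "all_dropout": AllDropout,
    "bru_net": BRUNet,
    "u2net": U2Net,
}


def build_model(config: ModelConfig) -> Module:
    """Instantiate an untrained model for ``config.arch_name``."""
    cls = _ARCH_CLASSES.get(config.arch_name)
    if cls is None:
        raise ValueError(f"unknown arch_name {config.arch_name!r}")
    model = cls(config)
    model.config = config  # type: ignore[attr-defined]
    return model
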