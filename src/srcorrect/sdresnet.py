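"""SD-ResNet: residual encoder + anti-checkerboard transposed-convolution decoder.

The encoder is a standard residual network producing a feature pyramid
{C2, C3, C4, C5} at strides {4, 8, 16, 32}.  Only the deepest map C5 feeds
the decoder: scanning-radius artifacts are global, spatially correlated
distortions best captured at a large receptive field, and skipping C2–C4
keeps the decoder compact.  The decoder restores the input resolution in
five stages, each a stride-2 transposed convolution (kernel 4, padding 1 —
exact spatial doubling) followed by a 3×3 smoothing convolution with batch
normalization and ReLU that homogenizes kernel overlap and suppresses
checkerboard artifacts.  The final layer is a linear 3×3 convolution to one
output channel.

Two encoder variants share the interface: ``resnet50`` (bottleneck blocks
[3, 4, 6, 3], C5 width 2048) and ``small`` (one basic block per stage,
widths 16/32/64/128) for CPU-scale work.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from srcorrect.errors import ConfigurationError, ShapeError
from srcorrect.nn import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
)

logger = logging.getLogger(__name__)

_ENCODERS = ("resnet50", "small")


@dataclass(frozen=True)
class ModelConfig:
    encoder_variant: str = "resnet50"
    pretrained: bool = False
    pretrained_path: str | None = None
    decoder_stages: int = 5
    upkernel: int = 4
    upstride: int = 2
    smooth_kernel: int = 3
    base_decoder_channels: int | None = None
    smoothing: bool = True
    small_width_base: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.encoder_variant not in _ENCODERS:
            raise ConfigurationError(f"unknown encoder variant {self.encoder_variant!r}")
        if self.decoder_stages < 1:
            raise ConfigurationError("decoder needs at least one stage")
        if self.small_width_base < 4:
            raise ConfigurationError("small encoder width base must be >= 4")
        if self.upstride != 2 or self.upkernel != 4:
            raise ConfigurationError("decoder stages are defined for kernel 4 / stride 2")


class _BasicBlock(Module):
    def __init__(self, cin, cout, stride, rng):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, pad=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, stride=1, pad=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down = Sequential(Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng),
                                   BatchNorm2d(cout))
        else:
            self.down = None
        self.relu_out = ReLU()

    def forward(self, x, train=False):
        identity = self.down.forward(x, train=train) if self.down is not None else x
        y = self.bn1.forward(self.conv1.forward(x, train=train), train=train)
        y = self.relu1.forward(y, train=train)
        y = self.bn2.forward(self.conv2.forward(y, train=train), train=train)
        return self.relu_out.forward(y + identity, train=train)

    def backward(self, dy):
        dy = self.relu_out.backward(dy)
        d_main = self.conv1.backward(self.bn1.backward(
            self.relu1.backward(self.conv2.backward(self.bn2.backward(dy)))))
        d_skip = self.down.backward(dy) if self.down is not None else dy
        return d_main + d_skip


class _Bottleneck(Module):
    def __init__(self, cin, mid, cout, stride, rng):
        self.conv1 = Conv2d(cin, mid, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(mid)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(mid, mid, 3, stride=stride, pad=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(mid)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(mid, cout, 1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down = Sequential(Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng),
                                   BatchNorm2d(cout))
        else:
            self.down = None
        self.relu_out = ReLU()

    def forward(self, x, train=False):
        identity = self.down.forward(x, train=train) if self.down is not None else x
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train=train), train=train), train=train)
        y = self.relu2.forward(self.bn2.forward(self.conv2.forward(y, train=train), train=train), train=train)
        y = self.bn3.forward(self.conv3.forward(y, train=train), train=train)
        return self.relu_out.forward(y + identity, train=train)

    def backward(self, dy):
        dy = self.relu_out.backward(dy)
        d = self.bn3.backward(dy)
        d = self.conv3.backward(d)
        d = self.relu2.backward(d)
        d = self.conv2.backward(self.bn2.backward(d))
        d = self.relu1.backward(d)
        d_main = self.conv1.backward(self.bn1.backward(d))
        d_skip = self.down.backward(dy) if self.down is not None else dy
        return d_main + d_skip


class ResNetEncoder(Module):
    """Residual encoder exposing the {C2, C3, C4, C5} feature pyramid."""

    def __init__(self, variant: str, rng: np.random.Generator, width_base: int = 16):
        self.variant = variant
        if variant == "resnet50":
            self.stem = Sequential(Conv2d(3, 64, 7, stride=2, pad=3, bias=False, rng=rng),
                                   BatchNorm2d(64), ReLU())
            self.pool = MaxPool2d(3, 2, 1)
            blocks_per_stage = (3, 4, 6, 3)
            mids = (64, 128, 256, 512)
            outs = (256, 512, 1024, 2048)
            cin = 64
            self.stages = []
            for s, (nb, mid, cout) in enumerate(zip(blocks_per_stage, mids, outs)):
                stage = []
                for b in range(nb):
                    stride = 2 if (s > 0 and b == 0) else 1
                    stage.append(_Bottleneck(cin, mid, cout, stride, rng))
                    cin = cout
                self.stages.append(Sequential(*stage))
            self.pyramid_channels = outs
        else:
            b = width_base
            self.stem = Sequential(Conv2d(3, b, 3, stride=2, pad=1, bias=False, rng=rng),
                                   BatchNorm2d(b), ReLU())
            self.pool = MaxPool2d(3, 2, 1)
            outs = (b, 2 * b, 4 * b, 8 * b)
            cin = b
            self.stages = []
            for s, cout in enumerate(outs):
                stride = 2 if s > 0 else 1
                self.stages.append(Sequential(_BasicBlock(cin, cout, stride, rng)))
                cin = cout
            self.pyramid_channels = outs

    @property
    def c5_channels(self) -> int:
        return self.pyramid_channels[-1]

    def forward_pyramid(self, x, train=False) -> dict[str, np.ndarray]:
        y = self.pool.forward(self.stem.forward(x, train=train), train=train)
        pyramid = {}
        for i, stage in enumerate(self.stages):
            y = stage.forward(y, train=train)
            pyramid[f"C{i + 2}"] = y
        return pyramid

    def forward(self, x, train=False):
        return self.forward_pyramid(x, train=train)["C5"]

    def backward(self, dy):
        for stage in reversed(self.stages):
            dy = stage.backward(dy)
        return self.stem.backward(self.pool.backward(dy))


class Decoder(Module):
    """Five doubling stages from C5, then a linear 3×3 head to one channel."""

    def __init__(self, c5: int, stages: int, channels: list[int], smoothing: bool,
                 smooth_kernel: int, rng: np.random.Generator):
        cin = c5
        layers = []
        for cout in channels[:stages]:
            layers += [ConvTranspose2d(cin, cout, 4, 2, 1, rng=rng), BatchNorm2d(cout), ReLU()]
            if smoothing:
                layers += [Conv2d(cout, cout, smooth_kernel, stride=1,
                                  pad=smooth_kernel // 2, rng=rng),
                           BatchNorm2d(cout), ReLU()]
            cin = cout
        self.body = Sequential(*layers)
        self.head = Conv2d(cin, 1, 3, stride=1, pad=1, rng=rng)

    def forward(self, x, train=False):
        return self.head.forward(self.body.forward(x, train=train), train=train)

    def backward(self, dy):
        return self.body.backward(self.head.backward(dy))


class SDResNet(Module):
    """Encoder–decoder mapping a 3-channel degraded image to a 1-channel correction."""

    def __init__(self, config: ModelConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.encoder = ResNetEncoder(config.encoder_variant, rng,
                                     width_base=config.small_width_base)
        c5 = self.encoder.c5_channels
        if config.base_decoder_channels is not None:
            base = config.base_decoder_channels
            channels = [max(base // (2 ** i), 8) for i in range(config.decoder_stages)]
        elif config.encoder_variant == "resnet50":
            channels = [512, 256, 128, 64, 32]
        else:
            b = config.small_width_base
            channels = [4 * b, 2 * b, b, b, b]
        self.decoder = Decoder(c5, config.decoder_stages, channels, config.smoothing,
                               config.smooth_kernel, rng)

    def forward(self, x, train=False):
        if x.ndim != 4 or x.shape[1] != 3:
            raise ShapeError("input must be (B, 3, H, W)")
        factor = 2 ** (self.config.decoder_stages)
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ShapeError(f"H and W must be divisible by 32, got {x.shape[2:]}")
        del factor
        c5 = self.encoder.forward(x, train=train)
        return self.decoder.forward(c5, train=train)

    def forward_pyramid(self, x, train=False):
        """Feature pyramid plus output; the decoder consumes only C5."""
        pyramid = self.encoder.forward_pyramid(x, train=train)
        return pyramid, self.decoder.forward(pyramid["C5"], train=train)

    def backward(self, dy):
        return self.encoder.backward(self.decoder.backward(dy))

    def freeze_encoder_bn(self) -> None:
        for mod in self.encoder.modules():
            if isinstance(mod, BatchNorm2d):
                mod.frozen = True


def build_model(config: ModelConfig) -> SDResNet:
    """Instantiate SD-ResNet; falls back to random init when pretrained
    encoder weights are requested but unavailable."""
    model = SDResNet(config)
    if config.pretrained:
        loaded = False
        if config.pretrained_path:
            try:
                state = dict(np.load(config.pretrained_path))
                enc_state = {k[len("encoder."):]: v for k, v in state.items()
                             if k.startswith("encoder.")}
                model.encoder.load_state_dict(enc_state or state)
                loaded = True
            except (OSError, KeyError, ValueError) as exc:
                logger.warning("could not load pretrained encoder weights: %s", exc)
        if not loaded:
            msg = "pretrained encoder weights unavailable; using random initialization"
            logger.warning(msg)
            warnings.warn(msg)
    return model


def checkerboard_energy(image: np.ndarray) -> float:
    """Fraction of spectral energy in the Nyquist (alternating ±1) component.

    0 for constant images; maximal (among equal-power single-frequency
    patterns) for a perfect checkerboard.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 4:
        raise ShapeError("checkerboard energy needs a 2D image of at least 4x4")
    spec = np.fft.fft2(img)
    total = float(np.sum(np.abs(spec) ** 2))
    if total == 0.0:
        return 0.0
    return float(np.abs(spec[img.shape[0] // 2, img.shape[1] // 2]) ** 2 / total)


def save_checkpoint(path, model: SDResNet, extra: dict[str, np.ndarray] | None = None) -> None:
    state = {f"model.{k}": v for k, v in model.state_dict().items()}
    if extra:
        state.update(extra)
    np.savez(path, **state)


def load_checkpoint(path, model: SDResNet, key_prefix: str = "model.") -> dict:
    archive = dict(np.load(path))
    model_state = {k[len(key_prefix):]: v for k, v in archive.items()
                   if k.startswith(key_prefix)}
    model.load_state_dict(model_state)
    return {k: v for k, v in archive.items() if not k.startswith(key_prefix)}
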