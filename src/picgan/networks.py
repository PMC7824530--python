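"""Generator (residual U-Net with refinement learning) and discriminator.

Both networks operate on two-channel real/imaginary representations of
complex images.  The generator is an encoder-decoder with shortcut
concatenations; its final convolution has two output channels, no
activation, and is zero-initialized so that at step 0 the refined
reconstruction x_hat = G(x_u) + x_u equals the zero-filled input exactly —
the generator only has to synthesize the information that was not sampled.

The discriminator mirrors the encoder: four stride-2 3x3 convolutions with
64/128/256/512 feature maps (batch norm + ReLU), a fifth 3x3 convolution,
a final 1x1 convolution to one channel with no activation, and a global
spatial average producing one unbounded logit per batch element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .types import ComplexImage, ValidationError, from_channels, to_channels

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "refine",
]


@dataclass(frozen=True)
class GeneratorConfig:
    depth: int = 4
    base_features: int = 64
    convs_per_block: int = 4
    kernel: int = 3

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_features < 1 or self.convs_per_block < 2:
            raise ValidationError("invalid generator config")


@dataclass(frozen=True)
class DiscriminatorConfig:
    features: tuple[int, ...] = (64, 128, 256, 512)
    kernel: int = 3
    final_kernel: int = 1

    def __post_init__(self) -> None:
        if len(self.features) == 0:
            raise ValidationError("discriminator needs at least one feature count")


def _conv_bn_relu(c_in, c_out, k, stride, rng, dtype):
    """Discriminator unit: convolution + batch norm + ReLU."""
    return [
        nn.Conv2d(c_in, c_out, k=k, stride=stride, rng=rng, dtype=dtype),
        nn.BatchNorm2d(c_out, dtype=dtype),
        nn.ReLU(),
    ]


def _conv_act(c_in, c_out, k, stride, rng, dtype):
    """Generator unit: convolution + LeakyReLU, no normalization.

    The residual generator regresses small complex-valued corrections from
    tiny batches; batch normalization destabilizes that regime, so the
    generator path is norm-free (the discriminator keeps BN + ReLU).
    """
    return [
        nn.Conv2d(c_in, c_out, k=k, stride=stride, rng=rng, dtype=dtype),
        nn.LeakyReLU(0.1),
    ]


class Generator:
    """Residual U-Net over (N, 2, H, W) grids.

    Encoder block i (features f_i = base * 2**i): convs_per_block - 1
    stride-1 convolutions then one stride-2 convolution doubling the
    features.  Decoder block i: 2x up-convolution halving the features,
    concatenation of the same-resolution encoder skip, then
    convs_per_block - 1 convolutions.  All convolutions are followed by
    LeakyReLU (no normalization) except the final two-channel output
    convolution, which is linear and zero-initialized.
    """

    def __init__(self, config: GeneratorConfig, in_ch: int = 2, out_ch: int = 2,
                 seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(np.random.SeedSequence([seed, 10]))
        d, base, k = config.depth, config.base_features, config.kernel
        self.enc_blocks: list[nn.Sequential] = []
        self.down_convs: list[nn.Sequential] = []
        c = in_ch
        for i in range(d):
            f = base * 2 ** i
            layers = []
            for j in range(config.convs_per_block - 1):
                layers += _conv_act(c if j == 0 else f, f, k, 1, rng, dtype)
            self.enc_blocks.append(nn.Sequential(*layers))
            self.down_convs.append(nn.Sequential(*_conv_act(f, 2 * f, k, 2, rng, dtype)))
            c = 2 * f
        self.up_convs: list[nn.ConvTranspose2x] = []
        self.dec_blocks: list[nn.Sequential] = []
        for i in reversed(range(d)):
            f = base * 2 ** i
            self.up_convs.append(nn.ConvTranspose2x(2 * f, f, rng=rng, dtype=dtype))
            layers = []
            for j in range(config.convs_per_block - 1):
                layers += _conv_act(2 * f if j == 0 else f, f, k, 1, rng, dtype)
            self.dec_blocks.append(nn.Sequential(*layers))
        self.final = nn.Conv2d(base, out_ch, k=k, rng=rng, zero_init=True, dtype=dtype)
        self._skips: list[np.ndarray] | None = None

    def _check_input(self, x: np.ndarray) -> None:
        h, w = x.shape[-2:]
        f = 2 ** self.config.depth
        if h % f or w % f:
            raise ValidationError(
                f"input {h}x{w} must be divisible by 2**depth = {f}"
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._check_input(x)
        x = x.astype(self.dtype, copy=False)
        skips = []
        for enc, down in zip(self.enc_blocks, self.down_convs):
            x = enc.forward(x, train)
            skips.append(x)
            x = down.forward(x, train)
        for up, dec, skip in zip(self.up_convs, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([x, skip], axis=1)
            x = dec.forward(x, train)
        self._skips = skips
        return self.final.forward(x, train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = self.final.backward(gy.astype(self.dtype, copy=False))
        skip_grads: list[np.ndarray] = []
        d = self.config.depth
        # decoder ran up_convs[0]..up_convs[d-1]; traverse in reverse
        for i in reversed(range(d)):
            gy = self.dec_blocks[i].backward(gy)
            f = self.up_convs[i].c_out
            g_up, g_skip = gy[:, :f], gy[:, f:]
            skip_grads.append(g_skip)
            gy = self.up_convs[i].backward(np.ascontiguousarray(g_up))
        # skip_grads[j] belongs to encoder block d-1-j... reversed(skips) pairing:
        # up_convs[i] consumed skips[d-1-i]; backward loop i = d-1..0 appended
        # grads for skips[0], skips[1], ..., skips[d-1] in that order.
        for i in reversed(range(d)):
            gy = self.down_convs[i].backward(gy)
            gy = gy + skip_grads[i]
            gy = self.enc_blocks[i].backward(gy)
        return gy

    def params(self) -> list[nn.Param]:
        mods = self.enc_blocks + self.down_convs + self.up_convs + self.dec_blocks + [self.final]
        return [p for m in mods for p in m.params()]

    def buffers(self) -> list[np.ndarray]:
        mods = self.enc_blocks + self.down_convs + self.up_convs + self.dec_blocks + [self.final]
        return [b for m in mods for b in m.buffers()]

    def set_buffers(self, arrays: list[np.ndarray]) -> None:
        mods = self.enc_blocks + self.down_convs + self.up_convs + self.dec_blocks + [self.final]
        i = 0
        for m in mods:
            n = len(m.buffers())
            if n:
                m.set_buffers(arrays[i : i + n])
                i += n

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())


class Discriminator:
    """Patch-to-logit classifier over (N, 2, H, W) grids; returns (N,) logits."""

    def __init__(self, config: DiscriminatorConfig, in_ch: int = 2, seed: int = 0,
                 dtype=np.float32):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
        layers: list[nn.Layer] = []
        c = in_ch
        for f in config.features:
            layers += _conv_bn_relu(c, f, config.kernel, 2, rng, dtype)
            c = f
        layers += _conv_bn_relu(c, c, config.kernel, 1, rng, dtype)
        layers.append(nn.Conv2d(c, 1, k=config.final_kernel, rng=rng, dtype=dtype))
        layers.append(nn.GlobalAvgPool())
        self.net = nn.Sequential(*layers)
        self.n_downsample = len(config.features)
        self.dtype = dtype

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h, w = x.shape[-2:]
        need = 2 ** self.n_downsample
        if h < need or w < need:
            raise ValidationError(
                f"discriminator input {h}x{w} below the receptive-field minimum {need}"
            )
        return self.net.forward(x.astype(self.dtype, copy=False), train)[:, 0]

    def backward(self, g_logits: np.ndarray) -> np.ndarray:
        return self.net.backward(np.asarray(g_logits, dtype=self.dtype)[:, None])

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def buffers(self) -> list[np.ndarray]:
        return self.net.buffers()

    def set_buffers(self, arrays: list[np.ndarray]) -> None:
        self.net.set_buffers(arrays)

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())


def build_generator(config: GeneratorConfig | None = None, seed: int = 0,
                    dtype=np.float32) -> Generator:
    return Generator(config or GeneratorConfig(), seed=seed, dtype=dtype)


def build_discriminator(config: DiscriminatorConfig | None = None, seed: int = 0,
                        dtype=np.float32) -> Discriminator:
    return Discriminator(config or DiscriminatorConfig(), seed=seed, dtype=dtype)


def refine(generator: Generator, xu) -> ComplexImage:
    """Refinement learning: x_hat = G(x_u) + x_u on a single complex image."""
    arr = np.asarray(getattr(xu, "data", xu), dtype=np.complex128)
    if arr.ndim != 2:
        raise ValidationError(f"refine expects a 2-D complex image, got shape {arr.shape}")
    batch = to_channels(arr)[None]
    residual = generator.forward(batch, train=False)[0]
    return ComplexImage(from_channels(residual.astype(np.float64)) + arr)
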