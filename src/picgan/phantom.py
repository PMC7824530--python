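"""Synthetic multi-coil phantom simulator.

Generates random-ellipse complex phantoms with smooth phase, border-centered
Gaussian coil sensitivity profiles (surface-coil-like geometry, jointly
normalized so sum_q |S_q|^2 = 1 everywhere), and noisy fully sampled k-space
under the additive model y_q = F(S_q x) + n_q.  Every draw is controlled by
an explicit seed, so datasets are reproducible and every training sample is
a distinct image — a GAN needs a distribution, not a single phantom.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as picio
from .encoding import fft2c
from .sampling import poisson_mask, random_mask, regular_mask
from .types import (
    ComplexImage,
    MultiCoilKSpace,
    Sample,
    SamplingMask,
    SensitivityMaps,
    ValidationError,
)

__all__ = [
    "PhantomSpec",
    "MaskConfig",
    "generate_phantom",
    "generate_sensitivities",
    "simulate_kspace",
    "make_sample",
    "make_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration of one simulated slice.

    ``noise_sigma`` is the per-coil complex-noise standard deviation in
    k-space, relative to the peak k-space magnitude of the phantom.
    """

    size: tuple[int, int] = (64, 64)
    n_ellipses: int = 6
    n_coils: int = 4
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_coils < 1:
            raise ValidationError("n_coils must be >= 1")
        if self.n_ellipses < 1:
            raise ValidationError("n_ellipses must be >= 1")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class MaskConfig:
    """How each simulated sample is retrospectively undersampled.

    By default a dataset shares one trajectory (the sampling pattern is a
    property of the acquisition protocol, not of the slice): ``seed`` pins
    the pattern, and :func:`make_dataset` fills it with the dataset seed
    when unset.  ``per_sample=True`` instead draws an independent pattern
    per slice.
    """

    kind: str = "random"
    af: float = 4.0
    acs_lines: int = 8
    acs_block: tuple[int, int] = (24, 20)
    seed: int | None = None
    per_sample: bool = False

    def build(self, shape: tuple[int, int], seed: int) -> SamplingMask:
        if self.kind == "regular":
            return regular_mask(shape, int(self.af), self.acs_lines)
        if self.kind == "random":
            return random_mask(shape, self.af, self.acs_lines, seed=seed)
        if self.kind == "poisson":
            return poisson_mask(shape, self.af, self.acs_block, seed=seed)
        raise ValidationError(f"unknown mask kind {self.kind!r}")


def _ellipse_mask(h, w, cy, cx, ry, rx, theta) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    y0, x0 = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * x0 + st * y0
    v = -st * x0 + ct * y0
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _smooth_phase(h: int, w: int, rng: np.random.Generator, order: int = 2,
                  scale: float = 1.5) -> np.ndarray:
    """Low-order 2-D polynomial phase surface on [-1, 1]^2."""
    u = np.linspace(-1.0, 1.0, w)[None, :]
    v = np.linspace(-1.0, 1.0, h)[:, None]
    phi = np.zeros((h, w))
    for i in range(order + 1):
        for j in range(order + 1 - i):
            phi = phi + rng.normal(0.0, scale) * (v ** i) * (u ** j)
    return phi


def generate_phantom(spec: PhantomSpec, ellipses=None) -> ComplexImage:
    """Random-ellipse phantom: magnitude = clipped sum of ellipses in [0, 1],
    phase = smooth random polynomial surface.

    ``ellipses`` optionally fixes the geometry as a list of
    (cy, cx, ry, rx, theta, intensity) tuples; by default ``spec.n_ellipses``
    ellipses are drawn from the seeded generator.
    """
    h, w = spec.size
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    if ellipses is None:
        ellipses = [
            (
                rng.uniform(0.25 * h, 0.75 * h),
                rng.uniform(0.25 * w, 0.75 * w),
                rng.uniform(0.08 * h, 0.35 * h),
                rng.uniform(0.08 * w, 0.35 * w),
                rng.uniform(0.0, np.pi),
                rng.uniform(0.2, 1.0),
            )
            for _ in range(spec.n_ellipses)
        ]
    mag = np.zeros((h, w))
    for cy, cx, ry, rx, theta, intensity in ellipses:
        mag += intensity * _ellipse_mask(h, w, cy, cx, ry, rx, theta)
    mag = np.clip(mag, 0.0, 1.0)
    phase = _smooth_phase(h, w, rng)
    return ComplexImage(mag * np.exp(1j * phase))


def generate_sensitivities(size: tuple[int, int], n_coils: int, seed: int = 0) -> SensitivityMaps:
    """Border-centered Gaussian coil profiles with smooth random phase,
    jointly normalized so sum_q |S_q|^2 = 1 at every pixel."""
    if n_coils < 1:
        raise ValidationError("n_coils must be >= 1")
    h, w = size
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    yy, xx = np.mgrid[0:h, 0:w]
    sigma = 0.55 * min(h, w)
    ring = 0.55 * max(h, w)
    raw = np.empty((n_coils, h, w), dtype=np.complex128)
    for q in range(n_coils):
        ang = 2.0 * np.pi * q / n_coils + rng.uniform(-0.2, 0.2)
        cy = h / 2.0 + ring * np.sin(ang)
        cx = w / 2.0 + ring * np.cos(ang)
        bump = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma ** 2))
        raw[q] = bump * np.exp(1j * _smooth_phase(h, w, rng, scale=0.8))
    sos = np.sqrt(np.sum(np.abs(raw) ** 2, axis=0))
    return SensitivityMaps(raw / sos)


def simulate_kspace(
    phantom: ComplexImage,
    maps: SensitivityMaps,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> MultiCoilKSpace:
    """Fully sampled multi-coil acquisition y_q = F(S_q x) + n_q.

    Noise is i.i.d. circular complex Gaussian per coil with complex standard
    deviation noise_sigma * max|F x| (sqrt(E|n|^2); each real component has
    std noise_sigma * max|F x| / sqrt(2)).
    """
    if maps.shape[1:] != phantom.shape:
        raise ValidationError(
            f"maps grid {maps.shape[1:]} does not match phantom {phantom.shape}"
        )
    clean = fft2c(maps.data * phantom.data[None])
    if noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
        scale = noise_sigma * float(np.max(np.abs(fft2c(phantom.data))))
        noise = rng.normal(0.0, scale / np.sqrt(2.0), size=clean.shape + (2,))
        clean = clean + noise[..., 0] + 1j * noise[..., 1]
    return MultiCoilKSpace(clean)


def make_sample(spec: PhantomSpec, mask_config: MaskConfig | None = None) -> Sample:
    """Simulate one complete sample (phantom, maps, full k-space, mask)."""
    mask_config = mask_config or MaskConfig()
    phantom = generate_phantom(spec)
    maps = generate_sensitivities(spec.size, spec.n_coils, seed=spec.seed)
    kspace = simulate_kspace(phantom, maps, spec.noise_sigma, seed=spec.seed)
    mask_seed = spec.seed if (mask_config.per_sample or mask_config.seed is None) else mask_config.seed
    mask = mask_config.build(spec.size, seed=mask_seed)
    return Sample(kspace, maps, mask, phantom, seed=spec.seed)


def make_dataset(
    n_samples: int,
    spec: PhantomSpec,
    mask_config: MaskConfig | None = None,
    out_dir: str | os.PathLike = "data",
) -> list[Path]:
    """Write ``n_samples`` simulated slices to ``out_dir`` (seeds spec.seed+i)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mask_config = mask_config or MaskConfig()
    if not mask_config.per_sample and mask_config.seed is None:
        # shared trajectory for the whole dataset, pinned by the dataset seed
        mask_config = MaskConfig(**{**mask_config.__dict__, "seed": spec.seed})
    paths = []
    for i in range(n_samples):
        spec_i = PhantomSpec(
            size=spec.size,
            n_ellipses=spec.n_ellipses,
            n_coils=spec.n_coils,
            noise_sigma=spec.noise_sigma,
            seed=spec.seed + i,
        )
        sample = make_sample(spec_i, mask_config)
        paths.append(picio.write_sample(sample, out / f"sample_{i:04d}.h5"))
    return paths
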