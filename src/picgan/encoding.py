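"""Sensitivity-encoded forward model y = E x = R F S x and its adjoint.

All transforms are centered (DC at grid index (H//2, W//2)) and orthonormal
(unitary scaling 1/sqrt(HW) in both directions), so the adjoint of the
Fourier step equals its inverse and adjoint identities hold exactly up to
floating-point rounding.
"""

from __future__ import annotations

import numpy as np

from .types import (
    ComplexImage,
    MultiCoilKSpace,
    Sample,
    SamplingMask,
    SensitivityMaps,
    ValidationError,
)

__all__ = [
    "fft2c",
    "ifft2c",
    "expand_coils",
    "combine_coils",
    "forward_encode",
    "adjoint_encode",
    "zero_filled_recon",
]


def _as_array(x, kind: str = "image") -> np.ndarray:
    if isinstance(x, ComplexImage):
        return x.data
    if isinstance(x, (MultiCoilKSpace, SensitivityMaps)):
        return x.data
    arr = np.asarray(x, dtype=np.complex128)
    if not np.all(np.isfinite(arr.view(np.float64))):
        raise ValidationError(f"{kind} contains non-finite values")
    return arr


def fft2c(image) -> np.ndarray:
    """Centered orthonormal 2-D DFT over the last two axes."""
    x = _as_array(image)
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), axes=(-2, -1), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(kspace) -> np.ndarray:
    """Centered orthonormal 2-D inverse DFT; exact inverse of :func:`fft2c`."""
    y = _as_array(kspace, "kspace")
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(y, axes=(-2, -1)), axes=(-2, -1), norm="ortho"),
        axes=(-2, -1),
    )


def _check_grid(maps: SensitivityMaps, grid_shape: tuple[int, int]) -> None:
    if maps.shape[1:] != grid_shape:
        raise ValidationError(
            f"maps grid {maps.shape[1:]} does not match image grid {grid_shape}"
        )


def expand_coils(image, maps: SensitivityMaps) -> np.ndarray:
    """Apply the sensitivity operator S: x -> {S_q * x}, shape (C, H, W)."""
    x = _as_array(image)
    _check_grid(maps, x.shape[-2:])
    return maps.data * x[..., None, :, :]


def combine_coils(maps: SensitivityMaps, coil_images) -> np.ndarray:
    """Apply S^H: {z_q} -> sum_q conj(S_q) z_q (sensitivity-weighted combination).

    Adjoint of :func:`expand_coils`; a left inverse on the support because
    sum_q |S_q|^2 = 1 there.
    """
    z = _as_array(coil_images, "coil images")
    if z.shape[-3:] != maps.shape:
        raise ValidationError(
            f"coil image shape {z.shape[-3:]} does not match maps {maps.shape}"
        )
    return np.sum(np.conj(maps.data) * z, axis=-3)


def forward_encode(image, maps: SensitivityMaps, mask: SamplingMask) -> np.ndarray:
    """Full forward operator E = R F S; unacquired entries are exactly zero."""
    x = _as_array(image)
    _check_grid(maps, x.shape[-2:])
    if mask.shape != x.shape[-2:]:
        raise ValidationError(f"mask shape {mask.shape} does not match grid {x.shape[-2:]}")
    return mask.data * fft2c(expand_coils(x, maps))


def adjoint_encode(kspace, maps: SensitivityMaps, mask: SamplingMask) -> np.ndarray:
    """Adjoint E^H = S^H F^H R: y -> sum_q conj(S_q) ifft2c(R * y_q)."""
    y = _as_array(kspace, "kspace")
    if y.shape[-3:] != maps.shape:
        raise ValidationError(f"kspace shape {y.shape[-3:]} does not match maps {maps.shape}")
    if mask.shape != maps.shape[1:]:
        raise ValidationError(f"mask shape {mask.shape} does not match maps grid")
    return combine_coils(maps, ifft2c(mask.data * y))


def zero_filled_recon(sample: Sample) -> ComplexImage:
    """Zero-filled reconstruction x_u = E^H (R y): the generator input and the
    ZF baseline."""
    xu = adjoint_encode(sample.kspace_full.data, sample.maps, sample.mask)
    return ComplexImage(xu)
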