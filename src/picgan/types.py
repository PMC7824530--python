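"""Shared domain types for multi-coil MRI reconstruction.

The objects here mirror the quantities of sensitivity-encoded parallel
imaging: a complex-valued image slice ``x``, its multi-coil k-space
measurements ``y``, the coil sensitivity profiles ``S_q``, and the binary
k-space sampling pattern ``R``.  Each type validates its own invariants at
construction so that downstream operators can assume well-formed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "ComplexImage",
    "MultiCoilKSpace",
    "SensitivityMaps",
    "SamplingMask",
    "Sample",
    "to_channels",
    "from_channels",
]

MAPS_NORM_TOL = 1e-6
MIN_IMAGE_DIM = 8

PATTERN_KINDS = ("regular", "random", "poisson")


class ValidationError(ValueError):
    """An input violated a domain-type invariant."""


def _require_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr.view(np.float64) if np.iscomplexobj(arr) else arr)):
        raise ValidationError(f"{name} contains non-finite values")


@dataclass(frozen=True)
class ComplexImage:
    """A single 2-D complex-valued slice (reconstruction, ground truth or
    zero-filled input).

    The grid is (H, W); axis 0 is the phase-encode direction.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.complex128)
        if data.ndim != 2:
            raise ValidationError(f"ComplexImage must be 2-D, got shape {data.shape}")
        h, w = data.shape
        if h < MIN_IMAGE_DIM or w < MIN_IMAGE_DIM:
            raise ValidationError(
                f"ComplexImage must be at least {MIN_IMAGE_DIM}x{MIN_IMAGE_DIM}, got {data.shape}"
            )
        _require_finite(data, "ComplexImage.data")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class MultiCoilKSpace:
    """Coil-indexed complex k-space samples, shape (C, H, W); coil axis first."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.complex128)
        if data.ndim != 3:
            raise ValidationError(f"MultiCoilKSpace must be 3-D, got shape {data.shape}")
        if data.shape[0] < 1:
            raise ValidationError("MultiCoilKSpace needs at least one coil")
        _require_finite(data, "MultiCoilKSpace.data")
        object.__setattr__(self, "data", data)

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class SensitivityMaps:
    """Complex coil sensitivity profiles S_q, shape (C, H, W).

    Inside ``support`` the maps are jointly normalized, sum_q |S_q|^2 = 1
    (so that the sensitivity-weighted coil combination S^H is a left inverse
    of the coil expansion S); outside the support all maps vanish.
    """

    data: np.ndarray
    support: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.complex128)
        if data.ndim != 3 or data.shape[0] < 1:
            raise ValidationError(f"SensitivityMaps must be (C,H,W), got shape {data.shape}")
        _require_finite(data, "SensitivityMaps.data")
        sos = np.sum(np.abs(data) ** 2, axis=0)
        if self.support is None:
            support = sos > 0.5  # normalized pixels sit at 1, empty ones at 0
        else:
            support = np.asarray(self.support, dtype=bool)
            if support.shape != data.shape[1:]:
                raise ValidationError(
                    f"support shape {support.shape} does not match maps {data.shape[1:]}"
                )
        if np.any(np.abs(sos[support] - 1.0) > MAPS_NORM_TOL):
            worst = float(np.max(np.abs(sos[support] - 1.0))) if support.any() else 0.0
            raise ValidationError(
                "sensitivity maps are not normalized: max |sum_q |S_q|^2 - 1| = "
                f"{worst:.3e} inside support (tol {MAPS_NORM_TOL:g})"
            )
        if np.any(sos[~support] > MAPS_NORM_TOL):
            raise ValidationError("sensitivity maps must vanish outside the support")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "support", support)

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class SamplingMask:
    """Binary k-space inclusion pattern R with a fully sampled ACS block.

    ``acs_lines`` central phase-encode lines (axis 0) are always acquired;
    ``nominal_af`` records the requested acceleration factor, which the
    realized ``sampled_fraction`` generally undershoots once the ACS is added.
    """

    data: np.ndarray
    nominal_af: float = 1.0
    acs_lines: int = 0
    pattern_kind: str = "regular"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise ValidationError(f"SamplingMask must be 2-D, got shape {data.shape}")
        vals = np.unique(data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError(f"SamplingMask values must be binary, got {vals}")
        data = data.astype(np.uint8)
        if self.nominal_af <= 0:
            raise ValidationError("nominal_af must be positive")
        if self.acs_lines < 0:
            raise ValidationError("acs_lines must be non-negative")
        if self.pattern_kind not in PATTERN_KINDS:
            raise ValidationError(
                f"pattern_kind must be one of {PATTERN_KINDS}, got {self.pattern_kind!r}"
            )
        h = data.shape[0]
        if self.acs_lines > h:
            raise ValidationError("acs_lines exceeds the number of phase-encode lines")
        lo, hi = acs_bounds(h, self.acs_lines)
        if self.acs_lines and not np.all(data[lo:hi, :] == 1):
            raise ValidationError("the ACS region must be fully sampled")
        frac = float(data.mean())
        if frac <= 0:
            raise ValidationError("mask must sample at least one k-space location")
        object.__setattr__(self, "data", data)

    @property
    def sampled_fraction(self) -> float:
        return float(self.data.mean())

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


def acs_bounds(h: int, acs_lines: int) -> tuple[int, int]:
    """Row range [lo, hi) of the central auto-calibration block."""
    lo = h // 2 - acs_lines // 2
    return lo, lo + acs_lines


@dataclass(frozen=True)
class Sample:
    """One fully characterized slice: fully sampled k-space, maps, mask and
    the coil-combined ground-truth image."""

    kspace_full: MultiCoilKSpace
    maps: SensitivityMaps
    mask: SamplingMask
    ground_truth: ComplexImage
    seed: int = 0

    def __post_init__(self) -> None:
        c, h, w = self.kspace_full.shape
        if self.maps.shape != (c, h, w):
            raise ValidationError(
                f"maps shape {self.maps.shape} does not match k-space {self.kspace_full.shape}"
            )
        if self.mask.shape != (h, w):
            raise ValidationError(
                f"mask shape {self.mask.shape} does not match k-space grid {(h, w)}"
            )
        if self.ground_truth.shape != (h, w):
            raise ValidationError(
                f"ground truth shape {self.ground_truth.shape} does not match grid {(h, w)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.kspace_full.shape


def to_channels(image: np.ndarray) -> np.ndarray:
    """Stack real and imaginary parts as two leading channels.

    (..., H, W) complex -> (..., 2, H, W) real.  The inverse is
    :func:`from_channels`; the round trip is exact.
    """
    image = np.asarray(image)
    return np.stack([image.real, image.imag], axis=-3)


def from_channels(channels: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_channels`: (..., 2, H, W) real -> (..., H, W) complex."""
    channels = np.asarray(channels)
    if channels.shape[-3] != 2:
        raise ValidationError(
            f"expected a 2-channel real/imaginary array, got shape {channels.shape}"
        )
    return channels[..., 0, :, :] + 1j * channels[..., 1, :, :]
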