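"""On-disk sample layout (HDF5) and magnitude-image export.

One file per slice with datasets ``/kspace`` (complex, C x H x W), ``/maps``
(complex, C x H x W), ``/mask`` (uint8, H x W), ``/ground_truth`` (complex,
H x W) and attributes ``nominal_af``, ``acs_lines``, ``pattern_kind`` and
``seed``.  Complex data use the container's native complex dtype; the
two-channel real/imaginary split exists only at the network boundary.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
from PIL import Image

from .types import (
    ComplexImage,
    MultiCoilKSpace,
    Sample,
    SamplingMask,
    SensitivityMaps,
)

__all__ = ["write_sample", "read_sample", "export_magnitude", "FormatError"]

_DATASETS = ("kspace", "maps", "mask", "ground_truth")


class FormatError(IOError):
    """The file does not conform to the documented sample layout."""


def write_sample(sample: Sample, path: str | os.PathLike) -> Path:
    """Write one validated :class:`~picgan.types.Sample` to ``path``."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=sample.kspace_full.data)
        f.create_dataset("maps", data=sample.maps.data)
        f.create_dataset("mask", data=sample.mask.data.astype(np.uint8))
        f.create_dataset("ground_truth", data=sample.ground_truth.data)
        f.attrs["nominal_af"] = float(sample.mask.nominal_af)
        f.attrs["acs_lines"] = int(sample.mask.acs_lines)
        f.attrs["pattern_kind"] = sample.mask.pattern_kind
        f.attrs["seed"] = int(sample.seed)
    return path


def read_sample(path: str | os.PathLike) -> Sample:
    """Read a sample written by :func:`write_sample`; all type invariants are
    re-validated on load."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in _DATASETS:
            if name not in f:
                raise FormatError(f"{path}: missing dataset /{name}")
        kspace = np.asarray(f["kspace"])
        maps = np.asarray(f["maps"])
        mask = np.asarray(f["mask"])
        gt = np.asarray(f["ground_truth"])
        af = float(f.attrs.get("nominal_af", 1.0))
        acs = int(f.attrs.get("acs_lines", 0))
        kind = str(f.attrs.get("pattern_kind", "regular"))
        seed = int(f.attrs.get("seed", 0))
    return Sample(
        MultiCoilKSpace(kspace),
        SensitivityMaps(maps),
        SamplingMask(mask, nominal_af=af, acs_lines=acs, pattern_kind=kind),
        ComplexImage(gt),
        seed=seed,
    )


def export_magnitude(image: ComplexImage, path: str | os.PathLike) -> Path:
    """Save |image| as an 8-bit grayscale PNG, linearly scaled min->0, max->255.

    A constant image maps to all zeros (no division-by-zero failure).
    """
    path = Path(path)
    mag = np.abs(image.data if isinstance(image, ComplexImage) else np.asarray(image))
    lo, hi = float(mag.min()), float(mag.max())
    if hi > lo:
        scaled = (mag - lo) / (hi - lo) * 255.0
    else:
        scaled = np.zeros_like(mag)
    Image.fromarray(np.round(scaled).astype(np.uint8), mode="L").save(path)
    return path
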