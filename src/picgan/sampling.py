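"""Retrospective k-space undersampling pattern generators.

Three families used in accelerated Cartesian/3-D acquisitions:

* ``regular_mask`` — uniform line skipping along the phase-encode axis,
* ``random_mask`` — variable-density random line selection,
* ``poisson_mask`` — 2-D Poisson-disc (dart-throwing) point patterns,

each with a fully sampled central auto-calibration (ACS) region and
reproducible under an explicit seed.  Nominal acceleration counts only the
line/point budget; the realized factor (reported by
:func:`effective_acceleration`) is lower once the ACS block is added.
"""

from __future__ import annotations

import numpy as np

from .types import SamplingMask, ValidationError, acs_bounds

__all__ = [
    "regular_mask",
    "random_mask",
    "poisson_mask",
    "effective_acceleration",
]


def regular_mask(shape: tuple[int, int], af: int, acs_lines: int = 0) -> SamplingMask:
    """Uniformly undersample phase-encode lines: every ``af``-th line starting
    at line 0, plus the fully sampled central ``acs_lines`` block."""
    h, w = shape
    if af < 1:
        raise ValidationError("acceleration factor must be >= 1")
    if acs_lines > h:
        raise ValidationError(f"acs_lines={acs_lines} exceeds H={h}")
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[::af, :] = 1
    lo, hi = acs_bounds(h, acs_lines)
    mask[lo:hi, :] = 1
    return SamplingMask(mask, nominal_af=float(af), acs_lines=acs_lines, pattern_kind="regular")


def random_mask(
    shape: tuple[int, int],
    af: float,
    acs_lines: int = 0,
    seed: int = 0,
    density_exponent: float = 2.0,
) -> SamplingMask:
    """Variable-density random Cartesian mask.

    Lines outside the ACS are drawn without replacement with probability
    proportional to w(k) = (1 - |k - H/2| / (H/2))**p (default p = 2, denser
    near the k-space center) until the total sampled-line count, ACS
    included, equals round(H / af).
    """
    h, w = shape
    if af < 1:
        raise ValidationError("acceleration factor must be >= 1")
    budget = int(round(h / af))
    if budget < acs_lines:
        raise ValidationError(
            f"line budget round(H/af)={budget} is below acs_lines={acs_lines}"
        )
    lo, hi = acs_bounds(h, acs_lines)
    sampled = np.zeros(h, dtype=bool)
    sampled[lo:hi] = True
    n_extra = budget - acs_lines
    candidates = np.flatnonzero(~sampled)
    if n_extra > candidates.size:
        n_extra = candidates.size
    if n_extra > 0:
        weight = (1.0 - np.abs(candidates - h / 2.0) / (h / 2.0)) ** density_exponent
        weight = np.maximum(weight, 1e-12)
        rng = np.random.default_rng(seed)
        chosen = rng.choice(candidates, size=n_extra, replace=False, p=weight / weight.sum())
        sampled[chosen] = True
    mask = np.repeat(sampled[:, None].astype(np.uint8), w, axis=1)
    return SamplingMask(mask, nominal_af=float(af), acs_lines=acs_lines, pattern_kind="random")


def _dart_throw(h: int, w: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Maximal-ish Poisson-disc point set on the integer grid via rejection."""
    n_attempts = 12 * h * w
    ii = rng.integers(0, h, size=n_attempts)
    jj = rng.integers(0, w, size=n_attempts)
    pts: list[tuple[int, int]] = []
    arr = np.empty((0, 2), dtype=np.int64)
    r2 = radius * radius
    for i, j in zip(ii, jj):
        if arr.size:
            d2 = (arr[:, 0] - i) ** 2 + (arr[:, 1] - j) ** 2
            if float(d2.min()) < r2:
                continue
        pts.append((int(i), int(j)))
        arr = np.asarray(pts, dtype=np.int64)
    mask = np.zeros((h, w), dtype=np.uint8)
    if pts:
        a = np.asarray(pts)
        mask[a[:, 0], a[:, 1]] = 1
    return mask


def poisson_mask(
    shape: tuple[int, int],
    af: float,
    acs_block: tuple[int, int] = (24, 20),
    seed: int = 0,
    rel_tol: float = 0.10,
    max_bisect: int = 24,
) -> SamplingMask:
    """2-D Poisson-disc mask with a fully sampled central ACS block.

    The minimum-distance radius is chosen by bisection so that the total
    sampled fraction (ACS included) lies within ``rel_tol`` of 1/af.  Points
    are placed by seeded dart throwing; the pairwise minimum distance among
    non-ACS points is at least the chosen radius.
    """
    h, w = shape
    if af <= 1:
        raise ValidationError("poisson_mask requires af > 1")
    bh, bw = acs_block
    if bh > h or bw > w:
        raise ValidationError(f"ACS block {acs_block} does not fit in grid {shape}")
    target = 1.0 / af
    rlo, rhi = 0.5, float(max(h, w))
    acs = np.zeros((h, w), dtype=np.uint8)
    lo_r, hi_r = acs_bounds(h, bh)
    lo_c, hi_c = acs_bounds(w, bw)
    acs[lo_r:hi_r, lo_c:hi_c] = 1

    best = None
    for it in range(max_bisect):
        r = 0.5 * (rlo + rhi)
        rng = np.random.default_rng(np.random.SeedSequence([seed, it]))
        pts = _dart_throw(h, w, r, rng)
        frac = float(np.maximum(pts, acs).mean())
        if abs(frac - target) <= rel_tol * target:
            best = (pts, r)
            break
        if frac > target:  # too dense -> larger exclusion radius
            rlo = r
        else:
            rhi = r
    if best is None:
        raise ValidationError(
            f"could not reach sampled fraction 1/af={target:.4f} within "
            f"{rel_tol:.0%} after {max_bisect} bisection steps"
        )
    pts, radius = best
    mask = np.maximum(pts, acs)
    out = SamplingMask(
        mask, nominal_af=float(af), acs_lines=0, pattern_kind="poisson"
    )
    # the chosen radius is useful for diagnostics/tests
    object.__setattr__(out, "radius", radius)
    object.__setattr__(out, "acs_block", (bh, bw))
    return out


def effective_acceleration(mask: SamplingMask) -> float:
    """Realized acceleration 1 / sampled_fraction (<= nominal once ACS added)."""
    frac = mask.sampled_fraction
    if frac <= 0:
        raise ValidationError("mask samples nothing")
    return 1.0 / frac
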