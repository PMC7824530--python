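"""Adversarial and dual-domain data-fidelity losses.

The generator objective combines four terms

    L_total = L_adv + alpha * L_iMAE + beta * L_fMAE,R + gamma * L_fMAE,1-R

where L_iMAE is a coil-wise image-domain mean absolute error against the
fully sampled coil images, L_fMAE,R penalizes mismatch on acquired k-space
entries and L_fMAE,1-R on the unacquired complement.  All MAE terms sum the
complex modulus of the residual and are normalized by C*H*W so the weights
transfer across image sizes.  The adversarial pieces use binary
cross-entropy with logits; the generator side defaults to the
non-saturating -log D(G(x_u)) form (a ``form`` flag restores the literal
minimax log(1 - D)).

Analytic gradients with respect to the complex reconstruction are provided
for training; they follow from Wirtinger calculus (for real f and residual
r, the gradient direction of |r| is r/|r|) and are verified against finite
differences in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .encoding import fft2c, ifft2c
from .types import SamplingMask, SensitivityMaps, ValidationError

__all__ = [
    "LossWeights",
    "adv_loss_d",
    "adv_loss_g",
    "adv_grad_d",
    "adv_grad_g",
    "image_mae",
    "kspace_acquired_mae",
    "kspace_unacquired_mae",
    "total_g_loss",
    "fidelity_losses_and_grad",
]


@dataclass(frozen=True)
class LossWeights:
    """Trade-off weights (alpha, beta, gamma) of the total generator loss.

    Defaults are the study settings alpha=1, beta=gamma=10 (chosen for
    unnormalized sums at full image scale; see the methods note on scaling
    them when the normalized losses are used on small images).
    """

    alpha: float = 1.0
    beta: float = 10.0
    gamma: float = 10.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _check_logits(x, name: str) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    if x.size == 0:
        raise ValidationError(f"{name}: empty logit batch")
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"{name}: non-finite logits")
    return x


def adv_loss_d(d_real, d_fake) -> float:
    """Discriminator loss: BCE-with-logits pushing D(real) -> 1, D(fake) -> 0."""
    r = _check_logits(d_real, "d_real")
    f = _check_logits(d_fake, "d_fake")
    return float(np.mean(_softplus(-r)) + np.mean(_softplus(f)))


def adv_grad_d(d_real, d_fake) -> tuple[np.ndarray, np.ndarray]:
    """d adv_loss_d / d logits, matching :func:`adv_loss_d`."""
    r = _check_logits(d_real, "d_real")
    f = _check_logits(d_fake, "d_fake")
    return (_sigmoid(r) - 1.0) / r.size, _sigmoid(f) / f.size


def adv_loss_g(d_fake, form: str = "nonsaturating") -> float:
    """Generator adversarial loss.

    ``nonsaturating`` (default): mean -log sigmoid(D(fake));
    ``minimax``: the literal mean log(1 - sigmoid(D(fake))).
    """
    f = _check_logits(d_fake, "d_fake")
    if form == "nonsaturating":
        return float(np.mean(_softplus(-f)))
    if form == "minimax":
        return float(np.mean(-_softplus(f)))
    raise ValidationError(f"unknown adversarial form {form!r}")


def adv_grad_g(d_fake, form: str = "nonsaturating") -> np.ndarray:
    """d adv_loss_g / d logits."""
    f = _check_logits(d_fake, "d_fake")
    if form == "nonsaturating":
        return (_sigmoid(f) - 1.0) / f.size
    if form == "minimax":
        return -_sigmoid(f) / f.size
    raise ValidationError(f"unknown adversarial form {form!r}")


def _csign(z: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """z / |z| with the subgradient 0 at z = 0."""
    mag = np.abs(z)
    out = np.zeros_like(z)
    nz = mag > eps
    out[nz] = z[nz] / mag[nz]
    return out


def _coil_grid(x, maps: SensitivityMaps, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.complex128)
    if x.shape != maps.shape:
        raise ValidationError(f"{name} shape {x.shape} does not match maps {maps.shape}")
    return x


def _x_hat(x_hat, maps: SensitivityMaps) -> np.ndarray:
    arr = np.asarray(getattr(x_hat, "data", x_hat), dtype=np.complex128)
    if arr.shape != maps.shape[1:]:
        raise ValidationError(
            f"reconstruction shape {arr.shape} does not match maps grid {maps.shape[1:]}"
        )
    return arr


def image_mae(x_coils, x_hat, maps: SensitivityMaps) -> float:
    """Image-domain MAE: sum_q |x_q - S_q x_hat|, normalized by C*H*W.

    ``x_coils`` holds the fully sampled coil images x_q = F^-1(y_q^full).
    """
    x = _coil_grid(x_coils, maps, "x_coils")
    xh = _x_hat(x_hat, maps)
    resid = x - maps.data * xh[None]
    return float(np.sum(np.abs(resid)) / resid.size)


def kspace_acquired_mae(y, x_hat, maps: SensitivityMaps, mask: SamplingMask) -> float:
    """Acquired-entry frequency MAE: sum_q |R y_q - R F S_q x_hat| / (C*H*W)."""
    yk = _coil_grid(getattr(y, "data", y), maps, "y")
    xh = _x_hat(x_hat, maps)
    if not np.any(mask.data):
        warnings.warn("kspace_acquired_mae: empty mask, no acquired entries")
        return 0.0
    resid = mask.data * (yk - fft2c(maps.data * xh[None]))
    return float(np.sum(np.abs(resid)) / resid.size)


def kspace_unacquired_mae(y_full, x_hat, maps: SensitivityMaps, mask: SamplingMask) -> float:
    """Unacquired-entry frequency MAE:
    sum_q |(1-R) y_q^full - (1-R) F S_q x_hat| / (C*H*W).

    Needs the fully sampled k-space, so it is a training-time (simulation)
    loss, not a deployment quantity.
    """
    yk = _coil_grid(getattr(y_full, "data", y_full), maps, "y_full")
    xh = _x_hat(x_hat, maps)
    inv = 1 - mask.data
    resid = inv * (yk - fft2c(maps.data * xh[None]))
    return float(np.sum(np.abs(resid)) / resid.size)


def total_g_loss(l_adv: float, l_i: float, l_fr: float, l_f1r: float,
                 w: LossWeights) -> float:
    """Weighted total: l_adv + alpha*l_i + beta*l_fr + gamma*l_f1r."""
    parts = np.array([l_adv, l_i, l_fr, l_f1r], dtype=np.float64)
    if not np.all(np.isfinite(parts)):
        raise ValidationError(f"non-finite loss component in {parts}")
    return float(l_adv + w.alpha * l_i + w.beta * l_fr + w.gamma * l_f1r)


def fidelity_losses_and_grad(
    x_hat: np.ndarray,
    x_coils: np.ndarray,
    y_full: np.ndarray,
    maps: SensitivityMaps,
    mask: SamplingMask,
    w: LossWeights,
) -> tuple[float, float, float, np.ndarray]:
    """All three fidelity terms and the complex gradient of their weighted sum
    with respect to ``x_hat``.

    Returns (l_i, l_fr, l_f1r, grad) where grad is the (H, W) complex array
    d(alpha*l_i + beta*l_fr + gamma*l_f1r)/d x_hat in the convention
    grad = dL/d(Re x) + i dL/d(Im x).
    """
    xh = _x_hat(x_hat, maps)
    S = maps.data
    n = float(S.size)

    resid_i = np.asarray(x_coils, dtype=np.complex128) - S * xh[None]
    l_i = float(np.sum(np.abs(resid_i)) / n)
    grad = -w.alpha * np.sum(np.conj(S) * _csign(resid_i), axis=0) / n

    pred_k = fft2c(S * xh[None])
    yk = np.asarray(y_full, dtype=np.complex128)
    resid_r = mask.data * (yk - pred_k)
    resid_1r = (1 - mask.data) * (yk - pred_k)
    l_fr = float(np.sum(np.abs(resid_r)) / n)
    l_f1r = float(np.sum(np.abs(resid_1r)) / n)
    back = w.beta * mask.data * _csign(resid_r) + w.gamma * (1 - mask.data) * _csign(resid_1r)
    grad = grad - np.sum(np.conj(S) * ifft2c(back), axis=0) / n
    return l_i, l_fr, l_f1r, grad
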