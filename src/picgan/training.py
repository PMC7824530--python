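"""Alternating generator/discriminator optimization and reconstruction.

Each batch performs one discriminator update (binary cross-entropy on
ground-truth vs refined reconstructions) followed by one generator update
on the total loss (adversarial + weighted dual-domain fidelity).  The
learning rate decays linearly to zero over the configured epochs; after
every epoch the mean validation PSNR of the refined reconstruction is
computed and the best-scoring parameters are checkpointed.  All shuffling
and initialization derive from the config seed, so fixed-seed runs are
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .encoding import adjoint_encode, ifft2c
from .losses import (
    LossWeights,
    adv_grad_d,
    adv_grad_g,
    adv_loss_d,
    adv_loss_g,
    fidelity_losses_and_grad,
    total_g_loss,
)
from .networks import (
    Discriminator,
    DiscriminatorConfig,
    Generator,
    GeneratorConfig,
    build_discriminator,
    build_generator,
    refine,
)
from . import nn
from .sampling import random_mask
from .types import (
    ComplexImage,
    MultiCoilKSpace,
    Sample,
    SensitivityMaps,
    ValidationError,
    from_channels,
    to_channels,
)
from .evaluation import psnr

__all__ = [
    "TrainConfig",
    "TrainReport",
    "train",
    "reconstruct",
    "save_checkpoint",
    "load_generator",
    "desk_profile",
    "zf_gan_view",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    The study-scale settings are batch 32, initial learning rate 1e-4
    decaying over 2000 epochs with alpha=1, beta=gamma=10 on unnormalized
    loss sums.  The defaults here are a desk-scale profile (small batch,
    few epochs, larger rate, weights rescaled for the C*H*W-normalized
    losses) sized for CPU runs; see :func:`desk_profile`.
    """

    batch_size: int = 4
    lr_initial: float = 1e-3
    epochs: int = 30
    lr_schedule: str = "linear_decay"
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    val_fraction: float = 0.1
    mask_policy: str = "fixed"
    adversarial_form: str = "nonsaturating"
    augment: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.lr_initial <= 0:
            raise ValidationError("batch_size, epochs must be >= 1 and lr_initial > 0")
        if self.lr_schedule != "linear_decay":
            raise ValidationError(f"unknown lr_schedule {self.lr_schedule!r}")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValidationError("val_fraction must be in (0, 1)")
        if self.mask_policy not in ("fixed", "resampled_per_epoch"):
            raise ValidationError(f"unknown mask_policy {self.mask_policy!r}")


@dataclass
class TrainReport:
    records: list[dict]
    best_epoch: int
    checkpoint_path: Path
    val_psnr_init: float


def desk_profile() -> tuple[GeneratorConfig, DiscriminatorConfig, TrainConfig]:
    """CPU-sized configuration: narrow networks on 64x64 phantoms.

    The fidelity weights are the study constants with the C*H*W
    normalization of the MAE terms undone (alpha=1, beta=gamma=10 on
    unnormalized sums correspond to ~1.6e4 / 1.6e5 at 4 coils x 64 x 64),
    so the adversarial:fidelity gradient balance matches the full-scale
    setting.
    """
    gen = GeneratorConfig(depth=3, base_features=8)
    disc = DiscriminatorConfig(features=(8, 16, 32, 64))
    cfg = TrainConfig(
        batch_size=4,
        lr_initial=3e-3,
        epochs=60,
        weights=LossWeights(alpha=1e4, beta=1e5, gamma=1e5),
    )
    return gen, disc, cfg


def _flip_views(sample: Sample):
    """The sample plus its three spatial flips, each re-simulated as a fresh
    acquisition with the same trajectory (exact in the noiseless model and
    consistent under noise, since the flip is applied to the coil images)."""
    from .encoding import fft2c

    yield sample
    coil_imgs = ifft2c(sample.kspace_full.data)
    for fy, fx in ((True, False), (False, True), (True, True)):
        ys = slice(None, None, -1) if fy else slice(None)
        xs = slice(None, None, -1) if fx else slice(None)
        yield Sample(
            MultiCoilKSpace(fft2c(coil_imgs[:, ys, xs].copy())),
            SensitivityMaps(sample.maps.data[:, ys, xs].copy()),
            sample.mask,
            ComplexImage(sample.ground_truth.data[ys, xs].copy()),
            seed=sample.seed,
        )


def _prepare(sample: Sample) -> dict:
    xu = adjoint_encode(sample.kspace_full.data, sample.maps, sample.mask)
    return {
        "sample": sample,
        "xu": xu,
        "gt": sample.ground_truth.data,
        "y_full": sample.kspace_full.data,
        "x_coils": ifft2c(sample.kspace_full.data),
        "maps": sample.maps,
        "mask": sample.mask,
    }


def _resample_mask(entry: dict, epoch: int, seed: int) -> None:
    mask = entry["mask"]
    if mask.pattern_kind != "random":
        return
    h, w = mask.shape
    new = random_mask(
        (h, w), mask.nominal_af, mask.acs_lines,
        seed=int(np.random.SeedSequence([seed, epoch, entry["sample"].seed]).generate_state(1)[0] % (2**31)),
    )
    entry["mask"] = new
    entry["xu"] = adjoint_encode(entry["y_full"], entry["maps"], new)


def _check_finite(value: float, term: str, epoch: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(f"training diverged: non-finite {term} at epoch {epoch}")


def train(
    train_samples: list[Sample],
    val_samples: list[Sample] | None,
    gen_config: GeneratorConfig,
    disc_config: DiscriminatorConfig,
    cfg: TrainConfig,
    out_dir: str | Path = "runs/train",
) -> TrainReport:
    """Train PIC-GAN on in-memory samples; returns per-epoch records and the
    path of the best-validation-PSNR checkpoint."""
    if not train_samples:
        raise ValidationError("train: empty training set")
    shapes = {s.shape for s in train_samples + (val_samples or [])}
    if len(shapes) != 1:
        raise ValidationError(f"train: samples must share (C,H,W), got {shapes}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 100]))

    if val_samples is None:
        n_val = max(1, int(round(cfg.val_fraction * len(train_samples))))
        if n_val >= len(train_samples):
            raise ValidationError("val_fraction leaves no training samples")
        perm = rng.permutation(len(train_samples))
        val_samples = [train_samples[i] for i in perm[:n_val]]
        train_samples = [train_samples[i] for i in perm[n_val:]]

    if cfg.augment:
        data = [_prepare(v) for s in train_samples for v in _flip_views(s)]
    else:
        data = [_prepare(s) for s in train_samples]
    val_data = [_prepare(s) for s in val_samples]

    gen = build_generator(gen_config, seed=cfg.seed)
    disc = build_discriminator(disc_config, seed=cfg.seed)
    opt_g = nn.Adam(gen.params(), lr=cfg.lr_initial)
    opt_d = nn.Adam(disc.params(), lr=cfg.lr_initial)

    def val_psnr() -> float:
        return float(np.mean([
            psnr(e["gt"], refine(gen, e["xu"]).data) for e in val_data
        ]))

    val_psnr_init = val_psnr()
    ckpt_path = out_dir / "checkpoint.npz"
    best = (-np.inf, -1)
    records: list[dict] = []

    for epoch in range(cfg.epochs):
        lr = cfg.lr_initial * (1.0 - epoch / cfg.epochs)
        opt_g.lr = opt_d.lr = lr
        if cfg.mask_policy == "resampled_per_epoch":
            for e in data:
                _resample_mask(e, epoch, cfg.seed)
        order = rng.permutation(len(data))
        sums = {"g_loss": 0.0, "d_loss": 0.0, "l_adv": 0.0,
                "l_i": 0.0, "l_fr": 0.0, "l_f1r": 0.0}
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            batch = [data[i] for i in order[start : start + cfg.batch_size]]
            nb = len(batch)
            xu = np.stack([e["xu"] for e in batch])
            x_in = to_channels(xu).astype(np.float32)

            # --- discriminator update ---
            g_out = gen.forward(x_in, train=True)
            x_hat = from_channels(g_out.astype(np.float64)) + xu
            real = to_channels(np.stack([e["gt"] for e in batch])).astype(np.float32)
            fake = to_channels(x_hat).astype(np.float32)
            d_real = disc.forward(real, train=True)
            gr, _ = adv_grad_d(d_real, np.zeros(nb))
            disc.backward(gr)
            d_fake = disc.forward(fake, train=True)
            _, gf = adv_grad_d(np.zeros(nb), d_fake)
            disc.backward(gf)
            d_loss = adv_loss_d(d_real, d_fake)
            opt_d.step()
            opt_d.zero_grad()

            # --- generator update ---
            g_out = gen.forward(x_in, train=True)
            x_hat = from_channels(g_out.astype(np.float64)) + xu
            l_i = l_fr = l_f1r = 0.0
            grad_c = np.empty_like(x_hat)
            for i, e in enumerate(batch):
                li, lfr, lf1r, g = fidelity_losses_and_grad(
                    x_hat[i], e["x_coils"], e["y_full"], e["maps"], e["mask"], cfg.weights
                )
                l_i += li / nb
                l_fr += lfr / nb
                l_f1r += lf1r / nb
                grad_c[i] = g / nb
            d_fake = disc.forward(to_channels(x_hat).astype(np.float32), train=True)
            l_adv = adv_loss_g(d_fake, cfg.adversarial_form)
            g_in = disc.backward(adv_grad_g(d_fake, cfg.adversarial_form))
            opt_d.zero_grad()  # discard D grads from the generator pass
            grad_channels = to_channels(grad_c).astype(np.float32) + g_in
            gen.backward(grad_channels)
            opt_g.step()
            opt_g.zero_grad()

            g_loss = total_g_loss(l_adv, l_i, l_fr, l_f1r, cfg.weights)
            for term, value in (("g_loss", g_loss), ("d_loss", d_loss)):
                _check_finite(value, term, epoch)
            sums["g_loss"] += g_loss
            sums["d_loss"] += d_loss
            sums["l_adv"] += l_adv
            sums["l_i"] += l_i
            sums["l_fr"] += l_fr
            sums["l_f1r"] += l_f1r
            n_batches += 1

        record = {k: v / n_batches for k, v in sums.items()}
        record["epoch"] = epoch
        record["lr"] = lr
        record["val_psnr"] = val_psnr()
        _check_finite(record["val_psnr"], "val_psnr", epoch)
        records.append(record)
        if record["val_psnr"] > best[0]:
            best = (record["val_psnr"], epoch)
            save_checkpoint(ckpt_path, gen, gen_config, disc_config, cfg, epoch)

    return TrainReport(
        records=records,
        best_epoch=best[1],
        checkpoint_path=ckpt_path,
        val_psnr_init=val_psnr_init,
    )


def save_checkpoint(
    path: str | Path,
    gen: Generator,
    gen_config: GeneratorConfig,
    disc_config: DiscriminatorConfig,
    cfg: TrainConfig,
    best_epoch: int,
) -> Path:
    """Single-file checkpoint: generator parameters + buffers + full config."""
    path = Path(path)
    meta = {
        "gen_config": asdict(gen_config),
        "disc_config": asdict(disc_config),
        "train_config": {
            **{k: v for k, v in asdict(cfg).items() if k != "weights"},
            "weights": asdict(cfg.weights),
        },
        "best_epoch": int(best_epoch),
    }
    arrays = {f"param_{i}": p.value for i, p in enumerate(gen.params())}
    arrays.update({f"buffer_{i}": b for i, b in enumerate(gen.buffers())})
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_generator(path: str | Path) -> tuple[Generator, dict]:
    """Rebuild the generator stored by :func:`save_checkpoint`."""
    with np.load(Path(path)) as f:
        meta = json.loads(bytes(f["meta"]).decode())
        gen = build_generator(GeneratorConfig(**meta["gen_config"]))
        params = gen.params()
        for i, p in enumerate(params):
            p.value[...] = f[f"param_{i}"]
        buffers = []
        i = 0
        while f"buffer_{i}" in f:
            buffers.append(np.asarray(f[f"buffer_{i}"]))
            i += 1
        gen.set_buffers(buffers)
    return gen, meta


def reconstruct(checkpoint: str | Path, sample: Sample) -> ComplexImage:
    """End-to-end reconstruction x_hat = G(x_u) + x_u with a stored generator;
    deterministic in evaluation mode."""
    gen, meta = load_generator(checkpoint)
    depth = meta["gen_config"]["depth"]
    _, h, w = sample.shape
    if h % 2 ** depth or w % 2 ** depth:
        raise ValidationError(
            f"checkpoint expects dimensions divisible by {2 ** depth}, got {h}x{w}"
        )
    xu = adjoint_encode(sample.kspace_full.data, sample.maps, sample.mask)
    return refine(gen, xu)


def zf_gan_view(sample: Sample) -> Sample:
    """Degenerate single-channel view for the ZF-GAN baseline: the 'coil'
    image is the unweighted coil sum and the sensitivity map is 1 everywhere
    (no parallel-imaging information)."""
    coil_sum = np.sum(ifft2c(sample.kspace_full.data), axis=0)
    ones = SensitivityMaps(np.ones((1,) + sample.ground_truth.shape, dtype=np.complex128))
    from .encoding import fft2c

    return Sample(
        MultiCoilKSpace(fft2c(coil_sum)[None]),
        ones,
        sample.mask,
        ComplexImage(coil_sum),
        seed=sample.seed,
    )
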