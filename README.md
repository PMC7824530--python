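# picgan

Parallel-imaging coupled GAN reconstruction for undersampled multi-coil
MRI — a pure-scientific-Python implementation with a synthetic multi-coil
phantom simulator, so the entire method is trainable and testable on a
laptop CPU without any scanner data.

## Who this is for

Researchers and students working on accelerated MRI reconstruction who
want a transparent, fully seeded reference implementation of a
sensitivity-encoded GAN reconstructor: every operator (encoding, masks,
losses, networks, optimization) is explicit numpy with hand-derived
gradients, verified against brute-force oracles in the test suite.

## The method

Accelerated parallel MRI measures undersampled k-space on C coils:

    y = E x + n,    E = R F S

(R: binary sampling mask with a fully sampled auto-calibration (ACS)
center; F: centered orthonormal 2-D Fourier transform; S_q: coil
sensitivities with sum_q |S_q|^2 = 1).  The zero-filled reconstruction
x_u = E^H y is aliased; a residual U-Net generator G de-aliases it by
refinement learning

    x_hat = G(x_u) + x_u,

trained adversarially against a convolutional discriminator with a
dual-domain data-fidelity objective

    L_total = L_adv + alpha ||x_q - S_q x_hat||_1
                    + beta ||R y - R F S x_hat||_1
                    + gamma ||(1-R) y_full - (1-R) F S x_hat||_1,

i.e. image-domain MAE against the fully sampled coil images, consistency
with the acquired k-space, and (during retrospective-undersampling
training) agreement with the unacquired k-space.  See `docs/methods.md`
for conventions, parameter defaults and limitations.

## Worked example

Train the desk-scale profile on 20 simulated 64x64, 4-coil phantoms with
4-fold variable-density random Cartesian undersampling (8 ACS lines), then
reconstruct held-out phantoms:

```python
import numpy as np
from dataclasses import replace
from picgan import (PhantomSpec, MaskConfig, make_sample, zero_filled_recon,
                    desk_profile, train, reconstruct, psnr)

mask_cfg = MaskConfig(kind="random", af=4.0, acs_lines=8, seed=1)
mk = lambda s: make_sample(PhantomSpec(size=(64, 64), n_coils=4, seed=s), mask_cfg)
train_set = [mk(1 + i) for i in range(20)]
val_set   = [mk(101 + i) for i in range(4)]
test_set  = [mk(201 + i) for i in range(5)]

gen_cfg, disc_cfg, cfg = desk_profile()
cfg = replace(cfg, seed=1)
report = train(train_set, val_set, gen_cfg, disc_cfg, cfg, out_dir="runs/demo")

zf  = np.mean([psnr(s.ground_truth, zero_filled_recon(s)) for s in test_set])
rec = np.mean([psnr(s.ground_truth, reconstruct(report.checkpoint_path, s))
               for s in test_set])
print(f"zero-filled {zf:.2f} dB -> PIC-GAN {rec:.2f} dB")
```

On this corpus (seed 1) the run prints

```
zero-filled 22.48 dB -> PIC-GAN 25.58 dB
```

a gain of about +3.1 dB held-out after ~5 minutes on one CPU core: the
trained generator removes most of the structured aliasing that
zero-filling leaves behind (SSIM rises from 0.63 to 0.68 and NMSE drops by
roughly half).  `report.val_psnr_init` equals the zero-filled baseline
exactly — the final generator convolution is zero-initialized, so training
starts from the identity on x_u.

The same pipeline is scriptable from the shell:

```
picgan simulate --n 20 --size 64 64 --coils 4 --af 4 --kind random --acs 8 --seed 1 --out data/train
picgan train --data data/train --out runs/demo
picgan evaluate --ref data/test --checkpoint runs/demo/checkpoint.npz --out results.csv
```

Samples are single-slice HDF5 files (`/kspace`, `/maps`, `/mask`,
`/ground_truth` plus mask attributes); `picgan mask` generates regular,
variable-density random Cartesian, and Poisson-disc patterns.

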