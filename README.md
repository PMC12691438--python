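# zsrecon

Scan-specific self-supervised reconstruction of accelerated multicoil MRI,
with conventional and **log-scaled** k-space training losses.

Accelerated MRI acquires only a subset Ω of k-space through C receiver
coils (`y_c = P_Ω F S_c x + ε`). `zsrecon` reconstructs the image with an
unrolled model-based network — conjugate-gradient SENSE data consistency
alternating with small residual CNNs in the image and k-space domains,
wrapped in virtual-coil conjugate-symmetry augmentation — trained **only on
the undersampled measurements of the scan itself**: the acquired samples
are partitioned into input (Λ), training-loss (Θ) and validation (Ψ)
subsets, so no fully sampled reference is ever needed. Because k-space
energy is concentrated at low frequencies, the package also provides a
log-compressed loss, `‖log(1+|ŷ−y|)‖_p^p / ‖log(1+|y|)‖_p^p`, that
re-weights high-frequency residuals and targets fine-structure fidelity.

Everything runs on CPU with numpy: the package ships its own compact
reverse-mode autodiff engine (finite-difference-verified), a synthetic
multicoil scan generator, 1-D and CAIPI undersampling masks with partial
Fourier, and the metric stack (NRMSE, PSNR, SSIM, HFEN, GMSD) validated
against reference implementations. See [docs/methods.md](docs/methods.md)
for the model and every default's rationale.

## Worked example

```python
import numpy as np
import zsrecon as z

# synthetic 64x64, 8-coil scan; R=4 lattice with 6/8 partial Fourier + 8 ACS lines
mask = z.make_1d_mask(64, 64, R=4, pf_fraction=6/8, acs_width=8)
ksp, S, gt, mask = z.simulate_dataset("desk", mask=mask, sigma=0.005,
                                      seed=1, n_slices=1)

# partition the acquired samples: Psi once, 50 (Lambda, Theta) pairs
parts = [z.partition_kspace(mask, ratios=(0.48, 0.32, 0.20), n_pairs=50, seed=1)]

model = z.UnrolledModel("zero_mirid", n_unrolls=3, n_cg=5, lambda_init=0.05,
                        denoiser_config=z.DenoiserConfig(n_layers=5, channels=8))
cfg = z.TrainConfig(lr=3e-3, max_epochs=15, patience=15, seed=1,
                    loss=z.LossSpec(kind="log_scaled"))
model, hist = z.train_scan_specific(ksp, S, mask, parts, model, cfg)

recon = z.reconstruct_inference(ksp[0], S, mask, model)
zf = np.asarray(z.adjoint_op(ksp[0], S, mask.as_float()))
sense = np.asarray(z.cg_sense(ksp[0], S, mask.as_float(), n_iter=15))
for name, img in [("zero-filled", zf), ("CG-SENSE", sense), ("zero-MIRID", recon)]:
    print(f"{name:12s} NRMSE {z.compute_metric(img, gt[0], 'nrmse'):6.2f} %"
          f"  SSIM {z.compute_metric(img, gt[0], 'ssim'):.4f}")
```

## Command line

```bash
zsrecon simulate --preset desk --r 4 --pf 6/8 --acs 8 --seed 1 --out scan.h5
zsrecon train --data scan.h5 --loss log --epochs 15 --lr 3e-3 --unrolls 3 \
              --cg 5 --layers 5 --channels 8 --out model.npz
zsrecon reconstruct --checkpoint model.npz --input scan.h5 --out recon.h5
zsrecon metrics --recon recon.h5 --reference scan.h5
zsrecon run --quick --seed 1 --out results/   # full comparative experiment
```

`zsrecon run` trains one model per configured loss from identical seeds and
writes a results bundle: resolved `config.yaml`, `metrics.csv` (one row per
method), per-epoch training histories, reconstructions (`.npy` + PNG).

## License / scope

Research code for method study at desk scale; not a medical device, not
validated for clinical use.
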