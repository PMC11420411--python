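# flowdenoise

Unsupervised denoising of CT-like images with a Poisson-flow generative
prior. An unconditional generative model is trained on *clean* image
patches only (no pairs, no noisy data); a single noisy image is then
denoised by **hijacking** the deterministic sampling ODE at its last step
(injecting the noisy image in place of a prior sample) and
**regularizing** each step by mixing the iterate with the input
(`x ← w·x + (1−w)·c`). With the hijack point at `τ = T − 1` the whole
procedure costs exactly one network evaluation (NFE = 1).

The augmented-dimension parameter `D` interpolates between heavy-tailed
Poisson-flow dynamics (small `D`) and ordinary Gaussian diffusion
(`D → ∞`), connected by the translation `r = σ·√D`. Both branches are
first-class: every component accepts a finite `D` or the `INFINITE`
sentinel.

Everything runs on one CPU with no external data: a synthetic CT phantom
module generates piecewise-constant ellipse anatomy in Hounsfield units,
and an **analytic field oracle** (the exact posterior mean for a discrete
dataset, computed in the log domain) serves as ground truth for every
learned component. The neural denoiser is a small fully-convolutional
U-Net written in numpy with a built-in reverse-mode autodiff engine —
no deep-learning framework required.

## Layout

| module | contents |
|---|---|
| `flowdenoise.pfgmpp` | σ↔r translation, perturbation kernel, prior, training target, exact field oracle |
| `flowdenoise.denoiser` | preconditioned denoiser contract, analytic oracle denoiser, checkpoints |
| `flowdenoise.backbone` / `autodiff` | numpy U-Net / MLP backbones and the autodiff engine behind them |
| `flowdenoise.training` | unsupervised patch training loop (Adam + EMA + augmentation) |
| `flowdenoise.sampler` | Karras-style schedule, Heun integrator, hijacking, regularization, NFE accounting |
| `flowdenoise.synthetic_ct` | ellipse phantoms, correlated-noise degradation, patch extraction, paired eval sets |
| `flowdenoise.metrics` | PSNR, SSIM, ROI noise SD, (T, w) grid search; LPIPS as an optional external hook |
| `flowdenoise.workflow` | YAML config, manifests, CLI |

## CLI

```bash
flowdenoise make-data  --config cfg.yaml --out runs/data
flowdenoise train      --config cfg.yaml --data runs/data --out runs/model
flowdenoise denoise    --config cfg.yaml --checkpoint runs/model/checkpoint.npz \
                       --out runs/denoised runs/data/eval_noisy_000.npy
flowdenoise sample     --config cfg.yaml --checkpoint runs/model/checkpoint.npz --out runs/samples
flowdenoise evaluate   --estimates runs/denoised --references runs/data --out runs/eval
flowdenoise gridsearch --config cfg.yaml --checkpoint runs/model/checkpoint.npz \
                       --data runs/data --out runs/grid
```

A minimal config:

```yaml
seed: 0
data:      {n_images: 8, image_size: 64, noise_sd: 50.0, n_eval_pairs: 4}
geometry:  {aug_dim: 128}        # or "inf" for the diffusion branch
training:  {patch_size: 16, batch_size: 8, n_iterations: 500,
            hu_offset: -450.0, hu_scale: 550.0}
sampler:   {T: 8, w: 0.5}        # tau defaults to T-1  =>  NFE = 1
```

Every subcommand writes a `manifest.json` (config, derived seeds, file
checksums, NFE, per-step σ values) from which its outputs can be
regenerated exactly. Images are stored as float-HU `.npy` (source of
truth) plus windowed 8-bit PNGs (default window [−160, 240] HU) for
inspection; lossless 16-bit PNG and optional DICOM readers live in
`flowdenoise.io`.

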