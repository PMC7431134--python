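# qpol

Joint reconstruction of phase, retardance, slow-axis orientation,
brightfield and degree of polarization from five-state
polarization-resolved defocus stacks, plus multi-channel 2D / 2.5D / 3D
residual U-Net models that translate the label-free channels into
fluorescence predictions.  Everything is exercised end-to-end on
synthetic phantoms rendered through the package's own forward models —
no external data is required.

## What's inside

| module | role |
| --- | --- |
| `qpol.polarization` | 5x4 instrument matrix (parameterized by the LC compensatory retardance chi), per-voxel forward model `I = A m` and least-squares inversion |
| `qpol.background` | transformed-coefficient (`m1/m3`, `m2/m3`) background correction, one or two rounds (round 2 fits a median-binned order-2 polynomial surface to the residual), and extraction of brightfield / retardance / slow axis / DOP |
| `qpol.phase` | partially coherent weak-object transfer functions (source-pupil cross-correlation), 3D Tikhonov / total-variation phase deconvolution, joint 2D phase+absorption solve |
| `qpol.phantom` | synthetic specimens (beads, star, spokes, layered tissue), rendering to five-state stacks with optional backgrounds and shot noise, paired label-free/fluorescence datasets with 70/15/15 splits |
| `qpol.nn` | NumPy implementation (custom reverse-mode autodiff) of the residual U-Net variants, foreground median/IQR normalization, tiling with foreground filtering, Adam + cyclic LR + early-stopping training, stitched inference with linear blending |
| `qpol.metrics` | Pearson correlation and SSIM per XY slice / XZ slice / volume, Otsu and Rosin foreground thresholds |
| `qpol.cli` / `qpol.config` / `qpol.io` | `qpol` command-line tool, strict YAML/JSON run configs, 32-bit float TIFF and CSV I/O |

The neural networks run on plain NumPy (no GPU framework needed): the
single-channel 2D, 2.5D (N=5) and 3D variants count 2.0 M, 4.8 M and
1.5 M trainable parameters respectively.

## CLI

Every sub-command reads one flat YAML/JSON config (`--seed` / `--out`
override file values) and writes its artifacts, the resolved config and
a log into the output directory:

```bash
qpol simulate    --config run.yaml --seed 1 --out out/sim
qpol reconstruct --config run.yaml --out out/recon
qpol phase       --config run.yaml --out out/phase
qpol train       --config run.yaml --out out/train
qpol predict     --config run.yaml --out out/pred
qpol evaluate    --config run.yaml --out out/eval
```

Minimal config for `simulate` + `reconstruct`:

```yaml
command: simulate
seed: 1
optics:
  wavelength: 0.532     # um
  na_detection: 0.55
  na_illumination: 0.4
  pixel_size: 0.25      # um, object space
  z_step: 1.0           # um
phantom: {kind: spokes, shape: [3, 64, 64], rho: 0.15}
paths: {output: out/sim}
```

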