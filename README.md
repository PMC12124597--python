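# risp

Coherence-prior artifact removal for photoacoustic tomography.

Sparse or limited-view photoacoustic systems produce streak artifacts when
reconstructed with analytic algorithms such as delay-and-sum (DAS) or
universal back-projection (UBP). This package implements RISP — a
regularized iteration with a structural prior — which exploits the fact
that true absorbers reconstruct consistently across different detector
subsets while artifacts fluctuate with the detection configuration. It is
aimed at researchers working with ring (2D) or hemispherical (3D) arrays
who want an artifact-suppression step that never solves the acoustic
forward model inside the iteration.

## Method

From k reconstructions R₁…R_k of random s-element subsets (s < N), a
pixelwise coherence map is built,

    D = (R₁ + … + R_k)² / (k (R₁² + … + R_k²)) ∈ [0, 1],

weighted by a Gaussian-CDF integral over its own distribution
(μ = (vmax+vmin)/2, σ = (vmax−vmin)/6),

    P = D · ∫_{vmin}^{D} Φ(v | μ, σ) dv,    Pnorm = (P − min P)/(max P − min P),

and Pnorm regularizes the full-array reconstruction R_N (normalized to
[0, 1]) through the convex objective

    L(R_op) = λ_con ‖R_N − R_op‖²_F + λ_reg ‖(1 − Pnorm) ⊙ R_op‖²_F,

minimized with Adam from R_op = R_N. Low-coherence (artifact/noise) pixels
are shrunk toward zero; high-coherence pixels stay anchored to R_N. The
pixelwise minimizer λ_con R_N / (λ_con + λ_reg (1 − Pnorm)²) is available
in closed form as an oracle. See `docs/methods.md` for the full model,
parameter guidance, and limitations.

The package also ships everything needed to run self-contained studies:
ring/hemisphere geometries, disk and random-vessel phantoms, an analytic
circular/spherical-mean forward simulator, DAS/UBP reconstruction, and
PSNR/SSIM/CNR/line-correlation metrics. Channel data are exchanged as
HDF5, images as float32 TIFF (2D) or NIfTI-1 (3D).

## Worked example

Run the bundled ring demonstration (64-element ring, 128×128 grid,
three-disk phantom, prior from k=30 subsets of s=8 elements):

```sh
risp run-all --outdir demo
```

which prints

```
psnr(ubp)=16.72 dB  psnr(risp)=16.81 dB
```

and writes `demo/metrics.json` with the full report; from the same run:

```
ssim(ubp)=0.048  ssim(risp)=0.519
background energy: 0.444 -> 0.179
```

Reading: the refined image keeps the phantom's PSNR while the structural
similarity rises from 0.05 to 0.52 and the fraction of image energy lying
outside the true objects — the streak artifacts — drops from 44% to 18%.
The directory also contains the channel data (`channel_data.h5`), the UBP
reconstruction (`rn.tiff`), the prior (`pnorm.tiff`), the refined image
(`rop.tiff`), the subset plan, and the loss trace.

The same stages are available as separate subcommands
(`simulate`, `reconstruct`, `prior`, `optimize`, `metrics`) and as library
functions:

```python
from risp import build_prior, make_subset_plan, normalize_image, run_risp, ubp_reconstruct

rn = ubp_reconstruct(data, grid)                      # full-array image
plan = make_subset_plan(data.n_elements, s=8, k=30, seed=7)
pnorm = build_prior(data, grid, plan, algo="ubp")     # structural prior
rn01, record = normalize_image(rn)
result = run_risp(rn01, pnorm)                        # refined image + loss trace
```

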