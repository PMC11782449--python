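# scorerecon

Score-based generative priors for accelerated Cartesian MRI reconstruction,
at desk scale.

Accelerated MRI acquires only a fraction of the k-space (spatial-frequency)
lines and reconstructs the image from the incomplete measurement
`y = M F x`, where `F` is the 2-D Fourier transform and `M` keeps
`round(n/R)` of the `n` phase-encode columns at acceleration factor `R`.
Plain zero-filled inversion of such data is riddled with aliasing artifacts.
This package resolves the missing information with a *score-based generative
prior*: a convolutional network trained by multi-noise-level denoising score
matching to estimate `∇_x log p_σ(x)`, the score of the noise-perturbed
distribution of breast-MRI-like slices, with T1/T2 contrast supplied as a
class label. Reconstruction runs annealed Langevin dynamics

```
x ← x + (α_i/2)·s_θ(x, σ_i, c) + √α_i·z,    α_i = ε σ_i² / σ_L²,
```

over a decreasing geometric noise schedule σ_1 > … > σ_L, and after every
step enforces *data consistency* by overwriting the kept k-space columns of
the iterate with the measured values, so the result agrees exactly with the
acquired lines and the prior fills in only what was never measured.

Because clinical breast MRI cannot be redistributed, the package ships a
seeded phantom generator (smooth breast-shaped envelope, band-limited
texture, focal elliptical structures, two contrast classes) plus cohort
fixtures, so the whole pipeline — undersampling, training, reconstruction,
PSNR/SSIM evaluation, and the two-reader rating statistics (Cohen's κ with
bootstrap CI, Mann–Whitney U, high-rating fractions) — runs end to end on a
laptop CPU in minutes. An analytic Gaussian prior with a closed-form
posterior mean serves as an exact oracle for the sampler.

Intended users: researchers prototyping score-based inverse-problem solvers
for MRI, and anyone who needs a fully reproducible, dependency-light
reference implementation of the annealed-Langevin reconstruction loop and
its evaluation stack.

## Worked example

```python
import scorerecon as sr

# a phantom volume and one z-normalized slice
vol = sr.generate_phantom(seed=3, size=64, depth=8, sequence_class=sr.SequenceClass.T2)
image = sr.slice_volume(vol, n_slices=1, seed=1)[0].pixels

# undersample its k-space at R = 5 (80% of lines deleted)
mask = sr.make_cartesian_mask(64, R=5, seed=0)
print(mask.n_kept, f"{100*mask.deleted_fraction:.1f}%")      # 13 79.7%
meas = sr.undersample(sr.forward_fourier(image), mask)

# the artifact-laden zero-fill baseline
zf = sr.zero_fill_reconstruct(meas)
print(f"{sr.psnr(image, zf):.2f} dB")                        # 15.20 dB
```

Training a small prior and reconstructing a 20-phantom test set at
R ∈ {1, 2, 5, 20} (the `monotone_degradation_study` experiment) prints, for
seed 1:

```
   R   psnr_mean  ssim_mean
 1.0      321.17      1.000
 2.0       20.79      0.549
 5.0       13.32      0.181
20.0        9.30      0.021
```

i.e. full sampling is recovered to machine precision and quality declines
monotonically as fewer k-space lines are kept — the directional behaviour
expected of any measurement-consistent reconstruction. Every reconstruction
satisfies `‖M·F(x̂) − y‖ ≤ 1e-8` on the kept columns by construction.

## Command line

```
scorerecon fixtures --n-studies 9916 --n-missing-t2 165 --size 64 --out fx/
scorerecon undersample --R 5 --seed 0 --in fx/phantom_000_T1.nii.gz --out meas.h5
scorerecon train --data fx/ --size 64 --steps 500 --out ckpt.zip
scorerecon sample --checkpoint ckpt.zip --class T2 --out sample.npy
scorerecon reconstruct --checkpoint ckpt.zip --measurement meas.h5 --out recon.nii.gz
scorerecon evaluate --pairs-manifest pairs.csv --out metrics.csv
scorerecon reader-stats --ratings ratings.csv --out stats.json
```

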