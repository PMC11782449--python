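# Methods

## The reconstruction model

MRI acquisition is modelled as a noiseless masked Fourier measurement of a
real 2-D slice: `y = M F x`, with `F` the **centered orthonormal** 2-D DFT
(zero frequency at the grid center, `norm="ortho"` so Parseval holds
exactly) and `M` a vertical-line mask that keeps whole phase-encode columns.
This centered/orthonormal pair is the single spectrum dialect supported
throughout the package. The mask keeps exactly `max(1, round(n/R))`
uniformly random distinct columns at acceleration factor `R`; the rounding
rule makes line counts exact and testable (384 columns at R = 5 keep 77,
i.e. 79.95% ≈ 80% deleted; at R = 20 they keep 19). No autocalibration
band is forced — kept positions are purely random — but a `keep_center`
option can pin low-frequency columns. Masks are redrawn per image from the
seed. Rows are never masked. The measurement model adds no noise.

## The score prior

The prior over z-normalized slices is learned by multi-noise-level denoising
score matching over a geometric schedule σ_1 > … > σ_L (defaults L = 10,
σ_1 = 1.0 — the data scale after z-normalization — down to σ_L = 0.01).
The per-level objective uses the λ(σ) = σ² weighting:

    L_i = σ_i² · E‖ s_θ(x + σ_i z, σ_i, c) + z/σ_i ‖²,   z ~ N(0, I).

The network parameterization folds the σ-conditioning into an output
scaling, `s_θ(x, σ, c) = f_θ(x, c)/σ`, which turns every level's weighted
objective into the same noise-prediction problem ‖f + z‖² — a standard
construction for multi-scale score networks. Contrast class (T1-like vs
T2-like) conditions the network through a learned per-class channel bias
added after every convolution.

`f_θ` is a small U-shaped encoder–decoder: a 3×3 convolution stack with one
stride-2 downsampling stage, a skip connection across it, nearest-neighbour
upsampling, and a final 1-channel projection (default 12–16 base channels at
64×64). It is implemented directly in numpy with im2col convolutions,
hand-written backpropagation and Adam (lr 1e-3); every layer's gradients are
validated against central finite differences in the test suite. Weight
initialization is He-scaled except the output projection, which starts near
zero so the initial score field is approximately null. All randomness
(initialization, batch order, noise draws) flows from a single run seed, and
training trajectories are bit-reproducible. Checkpoints are a zip archive
of parameter arrays plus schedule/config JSON with a CRC32 checksum;
save/load round-trips preserve score outputs bitwise.

Training at desk scale deliberately replaces the full-scale regime (tens of
thousands of 384×384 slices, days of GPU time) with minutes of CPU time:
the default study trains on 90 slices (30 volumes × 3) at 64×64 for 400
Adam steps. That is enough for the prior to clearly reduce its held-out
DSM loss and to separate the two contrast classes, not to reach a
clinically meaningful prior; the evaluation claims are correspondingly
directional, not absolute.

## Annealed Langevin reconstruction

Sampling runs, per level i, `steps_per_level` updates

    x ← x + (α_i/2)·s(x, σ_i, c) + √α_i·z,   α_i = ε σ_i²/σ_L²,

with defaults ε = 2e-5 and 30 steps per level (15 in the batch study) at
unit data scale. ε = 2e-5 keeps the first-level step α_1 = ε σ_1²/σ_L²
(= 0.2 at the default schedule) safely inside the stability region of the
dynamics; the sampler retains noise injection at the last level (pure
annealed Langevin), and no final "σ → 0" denoising half-step is applied.

For reconstruction, each Langevin step is followed by hard data consistency:
the iterate's spectrum is overwritten on the kept columns with the measured
values and inverted back (replacement mode). Because the image is real, a
measured line at frequency +k also determines the line at −k by conjugate
symmetry, and replacement enforces those Hermitian-implied mirror lines
too; this makes replace-then-take-real-part an exact orthogonal projection
onto the measurement-consistent set (without it, kept columns whose
mirrors are unkept are only partially enforced and the sampled posterior
acquires a bias). A soft mode that instead takes a gradient step on
‖M F x − y‖² is available behind a flag. The iterate is kept real during
the loop (real part after each consistency inversion); at the end a
terminal projection produces the final complex iterate, whose spectrum
equals the measurement exactly on kept columns — the reported residual
`‖M F x̂ − y‖ ≤ 1e-8` is computed there — and whose real part is the
output image, with the imaginary residue logged in the result. The
initial iterate is the zero-filled reconstruction plus σ_1-scaled noise
(pure-noise initialization is available); starting from the zero-fill
shortens burn-in without changing the stationary behaviour. Batch
reconstruction derives per-item seeds as `crc32(f"{run_seed}:{item_id}")`,
so results are independent of batch order and stable under permutation.

## The Gaussian oracle

Validating a stochastic sampler against a learned network is circular, so
the sampler is checked against an analytic prior: N(μ, Σ) over flattened
8×8 images (smooth bump mean, squared-exponential covariance of amplitude
0.15 and length scale 0.4 in normalized coordinates, plus a white-noise
floor of pixel variance 0.01). Its σ-perturbed score −(Σ + σ²I)⁻¹(x − μ)
is exact, and the posterior mean given the masked Fourier measurement has
the closed form μ + ΣBᵀ(BΣBᵀ)⁺(ỹ − Bμ), where B stacks the real and
imaginary parts of the kept Fourier rows (a pseudo-inverse is required
because the Hermitian symmetry of a real image's spectrum makes B
rank-deficient).

The instance and sampler settings are designed from an error budget rather
than tuned: (i) the covariance floor keeps every prior eigenvalue far
above the terminal annealing scale σ_L² = 1e-4, so the σ_L-smoothed
conditional mean coincides with the exact one to ~0.01%; (ii) a prior
eigenmode of variance v mixes at rate α_i/(2(v + σ_i²)) per Langevin step
and effectively freezes once the anneal passes
σ_f² ≈ 2 v σ_L²/(ε·steps) — 300 steps per level at ε = 5e-5 push σ_f² for
the slowest mode to ~0.02, where the residual smoothing bias is ~1%,
while remaining a factor ~8 inside the step-size stability bound
α_i < 4(v_min + σ_i²); (iii) the mean image dominates the posterior
spread, so the Monte-Carlo error of a 50-seed average is ~2% of the mean
norm. The seed-averaged Langevin reconstruction at R = 2 then agrees with
the closed form to ~1–2% relative error; the same check passes on
additional randomly drawn (μ, Σ, mask) instances.

## Quality metrics

PSNR = 10·log10(range²/MSE) with a +inf sentinel at MSE = 0. SSIM uses the
original constants K1 = 0.01, K2 = 0.03, uniform (unweighted) 7×7 windows,
sample (N−1) covariances, and averages over the interior where the window
fits; the implementation agrees with scikit-image's to 1e-6 on random
pairs (asserted in the suite — scikit-image is the independent oracle, not
a runtime dependency). Because z-normalized slices have no nominal
intensity range, `data_range` defaults to max − min of the *reference*
image of each pair and is recorded per item; this declared convention keeps
PSNR and SSIM comparable across slices. Set-level aggregation reports mean
and population standard deviation per R, excluding infinite-PSNR items from
means with a logged count.

## Reader-study statistics

Ratings (1–5, 5 = perfect match to the reference) are ingested from CSV
with key (reader, case, R). Cohen's κ is unweighted by default — a
linear-weighted variant sits behind a flag — with a 95% CI from a
2000-replicate nonparametric bootstrap over rating pairs (the percentile
interval, widened if necessary to contain the point estimate). The
Mann–Whitney U test is two-sided with midrank tie handling; "exact" mode
enumerates all C(n_a+n_b, n_a) group assignments of the pooled midranks
(permutation-exact, limited to combined n ≤ 25 by default) and the
asymptotic mode applies the tie-corrected normal approximation with a 0.5
continuity correction. The test which two samples to compare is left to the
caller; the operation is generic. A rater simulator (discretized latent
quality declining log-linearly in R, plus per-reader Gaussian noise)
generates fixtures with tunable agreement for the tests.

## The phantom generator

The generator emulates the *statistical* structure of breast MRI slices,
not their anatomy: a soft-edged half-ellipsoid envelope with slight z-taper
(chest wall at one image edge), a band-limited texture compartment
(Gaussian-smoothed white noise) standing in for fibroglandular tissue, 0–3
bright elliptical focal structures, and a faint global gradient that keeps
every slice non-constant. T1-like and T2-like volumes at the same seed
share all random geometry and differ by a documented contrast inversion of
the texture compartment and a brighter focal compartment in T2. The recipe
is versioned (`PHANTOM_RECIPE_VERSION`); realism is explicitly a non-goal.
What passing tests therefore show is that the pipeline's machinery —
sampling, consistency, training dynamics, metric ordering — behaves
correctly on images with smooth backgrounds, sharp local features and two
contrast classes; they do not show that the learned prior would transfer to
clinical anatomy, coil effects, or acquisition noise, none of which the
generator emulates.

Cohort fixtures mirror a screening-cohort accounting flow: N studies,
a specified number lacking the T2 sequence, an eligibility filter that
drops them, and a train/test split of the remainder (defaults 9916 studies,
165 missing, 9549 train, 100 evaluation studies; configurable, since those
published-style counts do not reconcile exactly — 9751 eligible vs
9549 + 100 — and the generator should not hide that). Slices are drawn at
distinct random z positions (without replacement) and z-normalized with the
population (divide-by-N) standard deviation, so the worked normalization
example is exact.

## Numerical choices and degenerate inputs

- Constant images raise a degenerate-input error from `znormalize` rather
  than returning NaN.
- A mask must keep ≥ 1 column; R < 1 is rejected; an all-deleted mask is
  unrepresentable.
- Non-finite Langevin iterates raise a sampling failure carrying level and
  step; non-finite training loss raises a training failure carrying the
  last 50-step checkpoint.
- κ is undefined when all mass sits in one cell pair (p_e = 1) and raises;
  bootstrap replicates that degenerate are skipped.
- The DSM loss norm is the Euclidean norm over pixels averaged over the
  batch; the training log records the per-pixel mean, which differs only by
  the constant pixel count.

## Known limitations

Two-dimensional, single-coil, noiseless measurements only; the phantom
prior is far below clinical quality at desk scale; PSNR/SSIM with per-pair
data ranges are not directly comparable with fixed-range conventions; the
Hermitian-completion step in replacement consistency assumes a real-valued
underlying image (it would be wrong for complex-valued imaging, where
phase carries information); and absolute metric values at any R are
properties of the phantom distribution, not of clinical data — only their
ordering across R is claimed.
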