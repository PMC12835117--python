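# Methods

## Problem setting

Ultra-low-field (ULF, ~64 mT) point-of-care brain MRI trades image quality
for portability: compared with 1.5 T / 3 T acquisitions it has lower SNR,
a much coarser acquisition matrix (especially through-plane), and
compressed tissue contrast. `fieldlift` implements a conditional
adversarial diffusion translator that maps a low-quality volume to a
high-field-like volume, given training pairs of co-registered low-/
high-quality acquisitions, together with everything needed to exercise it
end to end without any data download: a paired synthetic phantom
generator, masked image-quality metrics, and volumetric agreement
analysis.

## Diffusion model

Let `x0` be a clean (high-field) slice on the `[-1, 1]` scale. The forward
process is a T-step variance-preserving Gaussian chain

    q(x_t | x_{t-1}) = N(x_t; sqrt(1 - beta_t) x_{t-1}, beta_t I),

with cumulative signal factor `alpha_bar_t = prod_{i<=t} (1 - beta_i)`.
The exact denoising posterior is

    q(x_{t-1} | x_t, x0) = N(mean_t, beta_tilde_t I)
    mean_t = sqrt(alpha_bar_{t-1}) beta_t / (1 - alpha_bar_t) * x0
           + sqrt(1 - beta_t) (1 - alpha_bar_{t-1}) / (1 - alpha_bar_t) * x_t
    beta_tilde_t = (1 - alpha_bar_{t-1}) / (1 - alpha_bar_t) * beta_t.

A unit test verifies this closed form against a brute-force Bayes product
integrated on a 1-D grid to 1e-8.

With only T = 4 steps the per-step denoising distribution is far from
Gaussian, so the reverse model is adversarial: a generator predicts the
clean slice directly (`x0`-parameterization), the predicted `x0` is pushed
through the exact posterior to propose `x_{t-1}`, and a time-conditioned
discriminator judges whether a candidate `x_{t-1}` is a plausible
denoised version of `x_t`. Because `alpha_bar_0 = 1` forces
`beta_tilde_1 = 0`, the final reverse step is deterministic; a predictor
that returns the true `x0` therefore reproduces it exactly, which the
test suite exploits as a plumbing oracle for the whole sampling path.

### Schedule discretization

The rate range is quoted as `beta_min = 0.1` to `beta_max = 20`. A value
of 20 cannot be the variance of the discrete kernel above (which needs
`beta_t < 1`), so it is read as a continuous variance-preserving rate
`beta(s) = beta_min + s (beta_max - beta_min)`, `s in (0, 1]`, discretized
by exponential integration:

    beta_t = 1 - exp( - integral_{(t-1)/T}^{t/T} beta(s) ds ).

This keeps every `beta_t` in (0, 1) for any positive rate range and gives
`alpha_bar_T = exp(-(beta_min + beta_max)/2) ~ 4.3e-5` at the defaults —
the terminal state is practically pure noise, as a diffusion chain
requires. The mapping from the printed range to discrete steps is a
declared design choice of this package; it is the standard one in
few-step adversarial diffusion and the only reading consistent with the
one-step kernel.

The printed form of the posterior mean uses the cumulative factor inside
both coefficients; the implementation uses the per-step factor
`sqrt(1 - beta_t)` on the `x_t` coefficient and the cumulative factor
elsewhere, which is the form that satisfies Bayes' rule — the grid-product
oracle test is the arbiter.

## Networks

Both networks are plain-numpy models differentiated with `autograd`;
convolutions are lowered to an im2col gather plus one BLAS sgemm with
hand-written adjoints, in channels-last layout (fastest on one CPU).

**Generator** `G(x_t, y, z, t)`: a dual-branch feature extractor applies
separate residual blocks (conv → group norm → ReLU → conv) to the noisy
target slice and to the 2.5D conditioning stack of `k` adjacent low-field
slices (default k = 3), so contrast-specific features are learned per
branch; the concatenated features feed a U-Net-style encoder–decoder with
skip connections. A 256-d standard-normal latent `z` passes through a
3-layer MLP and modulates every stage through adaptive group
normalization (per-stage scale/shift); the timestep enters as a
sinusoidal embedding mapped to a per-stage channel bias. The network
predicts the clean center slice directly. The 2.5D design injects local
through-plane context at 2D cost.

**Discriminator** `D(x_{t-1}, x_t, t)`: a strided convolutional
classifier on the channel concatenation of candidate and current state,
with the same sinusoidal time embedding added per stage, global average
pooling and a linear head. It sees single center slices.

Width/depth defaults (generator base 32 channels, depth 3; discriminator
base = half the generator base) are desk-scale choices — the layer
pattern, not the widths, is the architectural content. Group-norm groups
default to 8. The time-conditioning mechanism (sinusoidal embedding,
additive stage bias) is the community standard for time-dependent
networks; no attention, EMA, or perceptual losses are used.

## Training

Per step: draw `t` uniform on {1..T}; draw a jointly correct
`(x_{t-1}, x_t)` pair from the forward chain on the target slice
(`x_{t-1}` from the exact marginal at `t-1`, then `x_t` through the
one-step kernel); predict `x0_hat = G(x_t, y, z, t)`; form the fake
`x_{t-1}` through the posterior. The discriminator minimizes
`-log D(real) - log(1 - D(fake))` (real pairs contribute only the first
term, fakes only the second); the generator minimizes the non-saturating
`-log D(fake)` plus `lambda1 * L1(x0_hat, x0)` with `lambda1 = 0.5`.
Adam with learning rates 1.5e-4 (G) / 1e-4 (D) and momenta (0.5, 0.9).
Updates are D-then-G, one each per step; gradient isolation between the
two updates is structural (each update differentiates only its own
parameter set). Losses are computed from logits in softplus form for
stability; recorded values equal the textbook expressions.

Batch order shuffles slices across subjects within a contrast; each
epoch's permutation is a pure function of (seed, epoch), and checkpoints
store parameters, Adam moments, the RNG state and the loop position, so a
resumed run continues bit-identically. One model is trained per contrast.

## Inference

A volume is enhanced slice by slice along the axial (last) axis: per
slice, T reverse steps from a fresh Gaussian initial state, each step
drawing a fresh `z` (a `fixed_z` option keeps one `z` per slice for
smoother volumes). Per-slice RNGs derive from (global seed, slice index),
so enhancing a sub-range reproduces the corresponding slices of a
full-volume run exactly. Outputs are mapped back to `[0, 1]` and clipped,
with the clip fraction reported. No inter-slice smoothing or 3D
post-filtering is applied.

## Synthetic phantom generator

Real paired ULF/high-field acquisitions are not publicly available, so
the package ships a generator of paired multi-contrast phantoms with
known ground truth:

* **Geometry** — nested ellipsoidal shells (scalp/skull, CSF, grey
  matter, white matter) with a smooth random radial deformation
  (default scale 0.04 of the head semi-axis) and optional disjoint
  ellipsoidal lesions carved into white matter.
* **Appearance** — per-label mean/sd intensities on `[0, 1]` per contrast
  (T1: WM bright/CSF dark; T2: CSF bright/WM dark; FLAIR: CSF suppressed,
  lesions bright), sampled voxelwise with Gaussian intra-class noise.
* **Degradation** (high-field → ULF-like arm): anti-aliased downsampling
  to the low-field acquisition matrix, contrast shrinkage toward the
  in-brain mean (default 0.3), a multiplicative low-frequency bias field
  (default amplitude 0.1), additive noise (default sigma 0.05; Gaussian
  by default, Rician available), then trilinear upsampling back onto the
  common grid — so both arms are co-registered by construction. The
  per-contrast matrix ratios mirror the published acquisition geometry
  (e.g. T1 256×256×176 at 3 T versus 112×112×36 at the point of care, a
  ~2.3×, 2.3×, 4.9× coarsening), rescaled to the working grid.

The degradation reproduces the three stated ULF deficits — resolution,
SNR, contrast — qualitatively; it is calibration-free. It deliberately
omits Bloch-equation simulation, k-space sampling, motion and
interference artifacts, and real-scan preprocessing (bias correction,
registration). Passing tests on these phantoms therefore demonstrate
that the machinery is correct and that the translator learns and
generalizes on paired data with this kind of gap; they do not certify
performance on clinical scans.

## Evaluation

PSNR (`20 log10(MAX_I / sqrt(MSE))`), SSIM and MAE are computed inside a
brain mask. All package volumes live on `[0, 1]`, so `MAX_I = 1`
unambiguously; identical images report an infinite PSNR sentinel, never a
number. SSIM uses a uniform odd window (default 7) with population
statistics, evaluated at fully-interior window centers that fall inside
the mask, with the universal constants k1 = 0.01, k2 = 0.03; a literal
window-by-window transcription in the test suite is the reference
implementation (agreement to 1e-6). The window shape/size are declared
defaults, not inferred values. Per-contrast metrics are averaged across
available contrasts.

Volumetric agreement uses region volumes (voxel count × voxel volume),
Pearson correlation, and Bland–Altman limits of agreement at
`mean ± 1.96 sd` (sample sd; the multiplier is fixed at the conventional
1.96).

## Desk-scale study conditions

The end-to-end checks (test suite and `scripts/acceptance.py`) run a
scaled-down study chosen for single-CPU runtimes: six 64³ subjects (four
train, two held out), one contrast (T1), generator base width 16, batch
size 2, 1500 training steps, fixed seeds. On these conditions the
held-out masked PSNR of enhanced volumes exceeds the conditioning
baseline by several dB and SSIM improves; a single-slice overfit run
drives the L1 term well below a quarter of its initial value within 500
steps. The 64³ grid keeps the published acquisition-matrix ratios while
shrinking the field of view.

## Numerical choices and degenerate inputs

* float32 parameters/activations; schedule and metrics in float64.
* Probability outputs clipped to `(1e-12, 1 - 1e-12)` before logs.
* Empty masks, mismatched shapes, even `k`, out-of-range `t`, non-finite
  losses, unwritable output directories and malformed NIfTI files raise
  explicit errors.
* Pearson correlation of a constant series returns NaN (documented
  sentinel).
* Group-norm epsilon 1e-5; Adam epsilon 1e-8.

## Known limitations

* The phantom is a geometric stand-in: no real-brain anatomy, no
  pathology realism beyond blob lesions, no acquisition physics.
* Purely 2D + adjacent-slice conditioning; through-plane consistency
  relies on the 2.5D stack alone.
* CPU-bound numpy training: desk-scale widths and step counts, not
  GPU-cluster-scale runs on large cohorts.
* Metrics are pixel-level similarity measures; they do not measure
  clinical or diagnostic fidelity, and generative translation can
  hallucinate plausible-looking structure — outputs are research images,
  not diagnostic ones.
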