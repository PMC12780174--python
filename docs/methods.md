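# Methods

## Detector and noise model

The full energy-integrating detector model for the measurement in pixel
*i* is a Poisson draw of the incident photons plus zero-mean Gaussian
readout noise, mixed across neighbouring pixels by a cross-talk
operator:

    I_i = Poisson(A_i) + N(0, σ_e),        I = Γ_σ [I_1, …, I_D]ᵀ

with `A_i = flux · Σ_k w_k exp(−L_ik)` the expected counts from the
per-energy-bin line integrals `L_ik` (Beer–Lambert). Detector quantum
efficiency, energy-to-electron conversion and spatially resolved
scatter are fixed at their ideal values (1, 1, 0): these require
instrument-specific calibration and are deliberately outside the model.
The simulator adds the dark offset and per-pixel flat-field gains after
the detector path, so flat-field correction is a nontrivial but exact
inverse.

Two modes differ only in physics, never in interface:

- **monochromatic** — one energy bin, `σ_e = 0`. This is exactly the
  physics the parameterized noise model below can express.
- **experimental_surrogate** — a two-bin spectrum whose per-material
  attenuation differs across bins (stone: µ_low = 2 µ_high, matrix 10 %
  spread), plus `σ_e = 5` counts (2.5 % of the default noisy flux).
  This mode stands in for a real bench acquisition: it contains beam
  hardening (streaks between grouped dense objects, concave
  log-signal-vs-thickness) and a readout-noise floor at photon
  starvation — two effects the monochromatic model cannot produce, so a
  sim-to-real gap exists by construction and can be measured.

Paired clean/noisy acquisitions share one phantom and differ only in
tube current; the default dose ratio is 30 (clean flux 6000, noisy flux
200 photons per pixel in vacuum). The relative quantum-noise level of
an acquisition is `V^1.3 / sqrt(I·t·n_proj·n_avim)`.

### Parameterized noise injection

Simulated noisy data is generated from clean beam intensity loss images
(ILI = (S−D)/(F−D), clamped to [0, 1] before scaling):

    P = Poisson(I₀·ILI) − I₀·ILI,   ILI_noisy = ILI + Γ[P + N(0, σ_e)]/I₀

`I₀` (photons in vacuum) controls severity; noise std scales as
`I₀^(−1/2)`. The sign of P follows the decomposition of a counting
measurement into expectation plus noise, `Poisson(A) = A + P`: with it,
the simulated noisy ILI equals `Poisson(I₀·ILI)/I₀` (plus cross-talk),
which is statistically identical to a real acquisition at flux I₀ —
right-skewed and nonnegative at photon starvation. The reflected sign
would instead produce negative beam intensities whose log-clamp makes
simulated data systematically noisier than real data of the same flux.
Here Γ touches only the noise component — the clean signal is an
already-measured quantity — whereas the full acquisition path applies
Γ to the whole measurement. `σ_e` defaults to 0 in the parameterized
model (readout noise is negligible except at photon starvation, and
the parameterization has no access to the count floor).

### Cross-talk kernel

Γ is a banded row-stochastic matrix. The default kernel gives each
adjacent pixel the fraction σ (interior row `(σ, 1−2σ, σ)`, valid for
σ < 0.5); at the default σ = 0.05 this produces a lag-1 noise
correlation of ≈ 0.11. "Shared between adjacent pixels" can equally be
read as a *total* shared fraction; that kernel (`(σ/2, 1−σ, σ/2)`,
lag-1 correlation ≈ 0.05 at σ = 0.05) is available as
`mode="split"`. Per-neighbour is the default because the resulting
correlation signature is the one the package's own acceptance checks
for the operator are written against. Boundary rows are renormalized
(signal that would leave the detector stays put).

## Pre-processing conventions

`y = −log(max(ILI, ε))` with ε = 10⁻⁶; negative log values (ILI > 1
noise overshoot) are clamped to 0 after the log and counted. ILI values
above 1 are *retained* in ILI form — denoisers must see the unclipped
noise distribution — and only clamped at the absorption step. Every
denoising path consumes pre-log ILI; passing an absorption sinogram to
a trainer or denoiser is a type error.

## Reconstruction

Parallel-beam FBP delegates to scikit-image's `iradon` (ramp default;
Shepp-Logan and Hann available). A cutoff fraction below 1 hard-limits
each projection's spectrum before the ramp, which composes to a
band-limited ramp. Fan-beam sinograms are rebinned to parallel
(φ = β + γ, s = SOD·sin γ, two-pass linear interpolation); the
reconstruction grid spacing equals the (rebinned) detector pitch.
Pixels outside the inscribed circle are zero and excluded from all
reconstruction-domain metrics.

**Reference reconstructions.** Reconstruction-domain comparisons —
noise-level calibration, training targets of reconstruction-domain
models, and study evaluation — use the ramp-filtered FBP of the *clean
acquisition* of the same slice as reference, not the phantom. This
mirrors practice: the comparison target of a real study is a reference
reconstruction computed from the high-dose measurement, which is
reachable from the data, whereas the true object is not (it differs
from any reconstruction by the band limit and view sampling of the
system). The phantom itself remains the ground truth for projector and
FBP accuracy tests.

## Denoisers

Two families, built on an in-package numpy CNN engine (im2col
convolutions with dilation, manual backprop, Adam). Both are residual
(they predict a correction to their input; the final 1×1 convolution is
zero-initialized so training starts exactly at the identity):

- **U-Net**: depth-2 encoder/decoder, 8 base channels doubling per
  level, 2× average pooling / nearest-neighbour upsampling, skip
  concatenation (≈ 30k parameters at desk scale).
- **MSD-Net**: width-1 mixed-scale dense network, 20 layers, dilation
  of layer j = ((j−1) mod 10) + 1, dense connectivity to all previous
  layers and the input, final 1×1 convolution over the full stack
  (≈ 2k parameters).

Training: Adam at 10⁻³, MSE loss, batch size 1, 20 epochs, whole slices
(no patches, no augmentation), 80/10/10 split; the returned weights are
those of the epoch with minimal validation loss. Targets are normalized
to O(1) amplitude so one learning rate serves both domains. Sinogram-
domain models map noisy ILI → clean ILI. Reconstruction-domain ("FBP+")
models map an in-pipeline FBP of the noisy data to the reference
reconstruction; the in-pipeline FBP uses a **Hann** filter — the
standard apodization choice for low-dose FBP inputs, stabilizing the
network input — while every *evaluation* reconstruction uses the ramp
filter.

## Noise-level calibration

`noise_level_table` simulates noisy ILIs from clean ones at each
candidate I₀ and tabulates SSIM/PSNR against the clean sinogram
(sinogram domain) and the reference reconstruction (reconstruction
domain), mean ± std over slices, plus one row computed identically from
the experimental noisy data. `select_I0` returns the candidate whose
reconstruction-domain metric (PSNR by default, SSIM optional) is
closest to the experimental row's; ties break toward smaller I₀
(overestimating noise is the safer error for denoiser training). A
non-finite reference metric (experimental set identical to clean)
raises a degenerate-reference error.

## Metrics

PSNR = 20·log₁₀(range/RMSE); SSIM with a uniform 7×7 window and the
standard stabilization constants. CT images are unbounded, so the data
range is an explicit policy: per-slice max−min of the reference
(default) or a fixed value; values are never clipped, and the policy is
recorded with every metric. Identical images yield an infinity flag
(PSNR) and exactly 1.0 (SSIM). Reconstruction-domain metrics average
only inside the inscribed circle.

## The desk-scale study

`run_study` generates 60 paired slices (48×48 phantoms: low-attenuation
circular matrix, small stones, grouped large stones; 60-view
parallel-beam scans), calibrates I₀ on the validation slices against
the grid (150, 200, 250, 300), builds the simulated-noisy counterparts
at the selected I₀, trains the 8 models of the
2-architecture × 2-training-noise × 2-domain grid, and evaluates all of
them on both test sets. Problem sizes were fixed once so the full study
replicates across several seeds on a single CPU in minutes; they trade
absolute performance for repeatability, and the study's claims are the
qualitative orderings, never the metric values.

What the synthetic study does and does not show: the surrogate contains
one beam-hardening mechanism, one readout-noise floor and one
cross-talk kernel; real scanners add detector nonlinearity, scatter
fields, ring artifacts and alignment errors. Passing orderings here
demonstrate that the pipeline measures the sim-to-real gap and the
domain-optimization advantage when they exist; they do not predict
their magnitude on any real instrument.

## Numerical choices and degenerate inputs

- log clamping ε = 10⁻⁶; clamp counts reported on every absorption
  sinogram.
- Per-slice RNG streams derive from (master seed, slice index, role) via
  `SeedSequence`, so clean/noisy draws are independent and the whole
  dataset is a pure function of (spec, master seed).
- Poisson rates are clamped to [0, I₀]; zero-ILI pixels produce exactly
  zero noise.
- Empty splits, unpaired calibration sets, σ ≥ the kernel limit,
  F ≤ D flat/dark fields, negative expected counts and mismatched
  geometries are rejected with specific errors.

## Known limitations

- The fan-beam path reconstructs on the rebinned detector-pitch grid;
  choosing a different output pixel size requires resampling by the
  caller.
- The CNN engine trains single samples (no vectorized batching); wall
  clock, not memory, bounds network size.
- The two-energy surrogate is the *minimal* polychromatic model; it
  produces beam-hardening streaks but not cupping profiles of realistic
  spectra.
- MSE is the only implemented training loss (consistent with
  PSNR-centric evaluation).
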