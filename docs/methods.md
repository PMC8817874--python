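# Methods

## Problem

B-mode ultrasound images carry heavy multiplicative speckle that hides fine
anatomy (for the motivating application: renal stones and their acoustic
shadows in pediatric kidneys).  `shearkad` implements a two-branch
transform-domain denoiser: a nonsubsampled shearlet transform (NSST)
separates the image into directional high-frequency subbands, which are hard
thresholded, and a low-frequency band, which is smoothed with an
edge-preserving kernel anisotropic diffusion (KAD).  The inverse transform
recombines the branches.  Comparison baselines (Laplacian-pyramid nonlinear
diffusion, plain NSST thresholding, image-domain KAD, median filtering) and
a PSNR/SSIM/EPI evaluation harness are included so the relative merits can
be measured end to end on synthetic data.

## Nonsubsampled shearlet transform

The transform is built entirely in the frequency domain on the image's own
FFT grid, so every subband keeps the full image resolution (shift
invariance, no pseudo-Gibbs artifacts from decimation).

* Radial part: Meyer-type smooth windows partition the L∞ frequency radius
  into one band per scale plus a low-pass residual.  The squared low-pass at
  scale *j* falls from 1 at radius 2⁻ʲ to 0 at 2⁻ʲ⁺¹ through the Meyer
  polynomial ν(t) = t⁴(35 − 84t + 70t² − 20t³); consecutive low-passes
  telescope, so the squared band windows sum exactly to one.  The
  full-octave transition is deliberate: sharper (half-octave) transitions
  were tried and produced consistently worse PSNR/SSIM/EPI after
  thresholding, because the spatially longer filters ring around every kept
  coefficient.  The price — each band leaking into the neighboring octave —
  is absorbed by the per-subband noise calibration below.
* Angular part: smooth windows on orientation modulo π split each band into
  a power-of-two number of wedges; adjacent wedges overlap through the same
  ν so their squares also sum to one.  Windows are symmetrized under
  frequency negation (which only matters on the self-aliased Nyquist
  row/column), making coefficients of real images real.
* Because the squared analysis windows form a partition of unity, the system
  is a Parseval tight frame: synthesis is the adjoint of analysis, the
  round trip is exact to machine precision (measured ~1e-14), and subband
  energies sum to the image energy.

Defaults: 3 scales with (8, 8, 4) directions finest-to-coarsest — enough
directional selectivity for the test corpus while a 256² image transforms in
well under a second.  Boundary handling is periodic (native to FFT
filtering); metrics therefore support excluding an image border
(`auto_crop_width`, 2^(scales+1) pixels, capped at 1/8 of the image).

## High-band thresholding

The global noise level φ is estimated robustly as median(|c|)/0.6745 over
the pooled finest-scale directional coefficients — the standard
Gaussian-consistent MAD rule, applied in the subband domain where the
finest bands of natural images are sparse.

Each directional subband is then hard thresholded (coefficients with
magnitude below S set exactly to zero, the rest untouched).  The shipped
rule, `rule="noise_gain"`, sets

    S(r, d) = θ · φ · g(r, d) / ḡ₁

where g(r, d) = sqrt(mean |U_{r,d}|²) is the filter bank's RMS gain for
white noise into subband (r, d) and ḡ₁ the pooled finest-scale gain.
φ·g/ḡ₁ is exactly the noise std inside that subband, so every subband is
cut at the same multiple θ of its own noise level; θ defaults to 3, the
classic k-sigma working point for hard thresholding.  Since the gains fall
from fine to coarse scales, the absolute threshold decreases with scale —
the largest threshold is applied at the highest resolution where the noise
is strongest, progressively smaller ones at lower resolutions.  This is the
scale-weighting idea implemented with the bank's measured noise decay as
the weight.

Two alternative rules are kept behind `ThresholdParams.rule` because they
are instructive failure modes rather than recommendations:

* `"bayes"`: S = θ·W(r)·φ²/σ_signal with W(r) = α·ln(r+1)/r and σ_signal =
  sqrt(max(subband_var − φ², 0)) (a subband with no energy above the noise
  floor is zeroed outright).  This is the BayesShrink threshold; it is
  near-optimal for *soft* shrinkage but, combined with hard thresholding,
  keeps most of the noise in signal-rich subbands and measured 1–6 dB worse
  than even the uniform-threshold baseline.
* `"literal"`: S = θ·W(r)·φ·sqrt(subband_var).  Its threshold grows like
  the noise variance rather than the noise std, so it under-thresholds weak
  noise and over-smooths strong noise.

The scale weight W(r) = α·ln(r+1)/r itself (strictly decreasing in r) is
exposed as `scale_weight` and drives both alternative rules.

## Kernel anisotropic diffusion

The low-frequency band (and, for the KDA baseline, the raw image) is
smoothed by an explicit diffusion scheme whose conductivity is computed in
the feature space induced by a Gaussian kernel F(a, b) =
exp(−(a−b)²/(2h²)).  Via the kernel trick, the squared feature distance
between neighbors is 2 − 2F(a, b) ∈ [0, 2]; the per-pixel kernel gradient
modulus is the RMS of this distance over the 4- (or 8-) neighborhood and is
bounded by √2, so single outlier pixels cannot freeze diffusion the way
they can with raw-gradient Perona–Malik.

Per edge (u, v) the conductivity is c = exp(−(φ_F²·m²)/(4τ²)) with

* m the kernelized contrast on that edge,
* φ_F² the local grayscale variance over a w×w window (w = 5), normalized
  by its global mean so it acts as a dimensionless modulator — texture-rich
  neighborhoods diffuse less; the squared-argument form keeps the exponent
  dimensionless in the Perona–Malik manner (a literal first-power variant
  is available via `exponent="literal"`),
* τ the median absolute deviation of the modulus field, floored at
  1e-6 × dynamic range, re-estimated every iteration so the edge/flat
  discrimination tracks the shrinking residual noise (estimating it once
  up front would progressively over-smooth as the field's scale drops).

The update J ← J + Δt·Σ_v c_uv(J_v − J_u)/|N| uses mirrored boundaries and
symmetric edge conductivities, giving exact zero-flux mean conservation and
(for Δt ≤ 1, a fortiori the default 0.15) a convex-combination update that
can never overshoot the input extrema.  Defaults: h = 1.5× a robust noise
std (for the low band: the image noise estimate mapped through the
low-pass gain; standalone: MAD of horizontal pixel differences), 10
iterations, Δt = 0.15, 4-neighborhood.  With h → ∞ and a fixed τ floor the
scheme reduces to the linear 5-point heat iteration, which the tests verify
against an explicit convolution oracle.

## Baselines

* **LPND** — nonsubsampled frequency-domain Laplacian pyramid (radial
  windows only), classic exponential Perona–Malik diffusion on every level
  (per-iteration robust κ = 1.4826·MAD of neighbor differences), adjoint
  reconstruction.
* **NSST-only** — the same shearlet decomposition with a uniform 3φ hard
  threshold on all high bands and the low band untouched: the traditional
  non-scale-adaptive transform denoiser.
* **KDA-only** — the kernel diffusion above applied directly to the image.
* **median** — 3×3 median filter; **none** — identity.

The baselines exist to measure relative ordering under identical
conditions, not to re-derive their original publications.

## Metrics

PSNR = 10·log₁₀(peak²/MSE) in dB (∞ sentinel at identity); SSIM is the
canonical Gaussian-windowed formulation (11-pixel window, σ = 1.5,
C1 = (0.01·peak)², C2 = (0.03·peak)²), delegated to scikit-image and
cross-checked in the tests against an independent from-scratch
implementation of the windowed formula; EPI is the Pearson correlation of
3×3-Laplacian high-pass fields of reference and result (mean-centered,
mirrored boundary).  EPI is 1 at identity, invariant to constant offsets,
and decreases monotonically with blur — the properties an edge-preservation
score needs; directional high-pass variants would change the number but
not the ordering of smooth-vs-edge-preserving methods.

## Synthetic data

The corpus is fully procedural so the repository builds and tests offline:

* a textured target (smooth illumination gradient, a 70-level step edge,
  bright/dark discs, diagonal periodic stripes, faint smooth random
  texture) standing in for the non-redistributable Lena/Barbara pair; the
  stripes play Barbara's role of stressing edge preservation;
* a kidney phantom: elliptical organ over dark background, hyperechoic
  stone disc, hypoechoic shadow column from the stone to the image edge,
  2-pixel cosine-ramped region boundaries;
* additive Gaussian white noise at σ ∈ {5, 15, 25} on the 0–255 scale (the
  quantitative protocol) and unit-mean Gamma multiplicative speckle with
  std σ/255 (a fully-developed-speckle approximation, for qualitative
  ultrasound-like inputs).

All generators are pure functions of their spec including the seed.  What
the phantoms do **not** model: point-spread-function blur, log compression,
depth-dependent attenuation, or spatially correlated speckle.  Passing
benchmarks on this corpus therefore demonstrates the algorithmic ordering
under controlled additive noise, not clinical image quality.

Intensities are float64 on the 0–255 scale throughout; clipping and
quantization happen only at I/O boundaries so metric computations are not
biased by mid-pipeline clipping.

## Benchmark protocol and problem sizes

`run_benchmark` sweeps image × σ × method × seed and reports one
PSNR/SSIM/EPI row per run, scoring after the automatic border crop.  The
shipped evaluation uses two 256² images, σ ∈ {5, 15, 25}, five noise seeds
and the four main methods (120 runs, well under a minute); the ordering
check uses two 128² phantoms under the same sweep.  At these sizes the
mean margins of the proposed method over the strongest baseline are stable
across seeds (see `scripts/acceptance.py` output).

## Clinical arithmetic

`effective_rate` computes 100·(disappeared + reduced)/total with half-up
rounding to two decimals; `compare_rates` compares two groups'
effective-vs-not 2×2 table with a continuity-corrected chi-square test,
switching to Fisher's exact test when any expected cell is below 5 — the
statistically appropriate replacement for running an ANOVA on two binary
proportions, whose headline output (significant vs. not at α = 0.05) it
reproduces.

## Known limitations

* Periodic boundary handling leaks wrap-around artifacts into a border of
  width roughly the coarsest filter support; metrics crop it by default,
  and outputs meant for display inherit it.
* The noise estimator assumes additive white Gaussian noise; under pure
  multiplicative speckle φ tracks the speckle contrast only approximately
  (a log-transform front end would be the principled extension).
* The KAD stage with default settings is deliberately gentle (10 explicit
  steps with Δt = 0.15); it polishes the low band but is not a competitive
  standalone denoiser at high noise, which the benchmark shows.
* Grayscale 2D only; no GPU path.
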