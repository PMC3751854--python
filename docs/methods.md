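# Methods

## Signal model and voxelwise T2 estimation

A multiple-spin-echo (Multi-SE / CPMG-type) acquisition samples the
transverse-magnetization decay of each voxel at echo times TE_k.  On
magnitude images the noise-free signal follows

    SI(TE) = β · exp(−TE / T2),

where β absorbs proton density, T1 weighting, coil sensitivity and
amplifier gain.  Because refocusing flip angles deviate from 180°,
echoes after the first mix primary and stimulated pathways; only the
first echo is a pure primary echo and does not lie on the same
exponential as the rest.  The pipeline therefore **always discards the
first echo** and fits the remaining points (7 of 8 on the default TE
grid 12.9, 25.8, …, 103.2 ms).

Echo selection further removes the trailing contiguous run of points
with SNR = SI/σ below 2, scanning backward from the last echo.  Interior
points below the threshold are kept: the noise floor argument applies to
the long-TE end of the curve, and deleting interior downward noise
excursions would bias the fit upward.  A voxel needs at least 3
surviving points (two parameters plus one degree of freedom for the
t-tests).

The nonlinear fit is initialized from a robust linear regression of
ln(SI) on TE — iteratively reweighted least squares with Tukey bisquare
weights (tuning constant 4.685), scale = median(|r|)/0.6745 (MAD about
zero; the median-centered MAD degenerates when a single outlier at the
TE-grid centroid shifts only the intercept), at most 50 iterations or a
weight change below 1e−8.  The slope s and intercept a map to
T2 = −1/s (requiring s < 0) and β = exp(a).  If both linear-stage
estimates are significant (two-tailed t-test of estimate/SE at p < 0.05,
n−2 degrees of freedom, SEs from the weighted normal equations), they
seed the nonlinear stage; otherwise the defaults β = 500, T2 = 50 ms do.

The nonlinear least-squares problem min Σ(SI_k − β e^{−TE_k/T2})² is
solved by Levenberg–Marquardt (via lmfit/MINPACK, tolerance 1e−8,
bounds β > 0, T2 ∈ (1, 2000] ms).  Standard errors come from the
Gauss–Newton covariance s²(JᵀJ)⁻¹ with s² the residual mean square;
p-values are two-tailed t-tests with n−2 degrees of freedom, and 95%
confidence intervals use the matching t quantile.  A voxel enters the T2
map only when **both** β and T2 reject the null at p < 0.05; rejected
voxels carry a reason code (insufficient points, non-significant,
non-converged, below noise).

The half-life helper T2·ln 2 documents the TE-grid design: a normal
carotid wall at T2 ≈ 50 ms has a half-life of ≈ 35 ms, so the last TE
(103.2 ms) samples about three half-lives.

## Noise model and its estimation

Magnitude MRI noise is Rician: the magnitude of the noise-free signal
plus complex Gaussian noise of per-channel SD σ.  In signal-free
background the magnitude is Rayleigh, so σ is estimated from a
background mask on the last echo as mean/√(π/2) (default) or
SD/√(2−π/2); the two agree within sampling error on Rayleigh data and
the config selects between them.  σ is a single scalar per acquisition.
Throughout the package, "SNR" means measured magnitude divided by this
σ — including the first echo, whose measured amplitude contains the
primary-echo scale factor.

## Digital vessel phantom

The phantom emulates a black-blood carotid cross-section: suppressed
lumen (β = 0, ideal double-inversion-recovery), an annular wall of
normal intima/media, circular component inclusions inside the wall, an
optional muscle disc, and background.  Geometry is rasterized by
pixel-center inclusion, 0-based row-major, pixel size 0.25 mm.  Each
signal-bearing pixel draws T2 and β from per-tissue Gaussians
(truncated below at 1 ms / 0):

| tissue        | T2 (ms)  | β        |
|---------------|----------|----------|
| intima/media  | 54 ± 13  | 500 ± 25 |
| fibrous       | 56 ± 9   | 500 ± 25 |
| LRNC          | 37 ± 5   | 500 ± 25 |
| recent IPH    | 107 ± 25 | 500 ± 25 |
| muscle        | 40 ± 5   | 500 ± 25 |
| calcification | —        | 0        |

β means are free parameters of the phantom (no tissue-wise amplitude
data exist); 500 matches the fit's default initializer scale.  The
default noise σ = 11.2 puts the measured first-echo SNR of normal wall
at ≈ 30, falling to the SNR < 2 floor at long TEs for short-T2 tissue.
The first echo is multiplied by `first_echo_scale` (default 0.85) to
emulate the primary/stimulated-echo mismatch; any value ≠ 1 suffices
because the first echo is always discarded, and a test asserts output
invariance to it.  A linear multiplicative coil-sensitivity field and a
residual-lumen-flow artefact on echo 1 are available but off by default.

What the phantom does **not** model: partial-volume mixing at component
borders, k-space/partial-Fourier effects, stimulated-echo pathway
physics (no Bloch/EPG simulation), multi-coil noise correlation, motion
and flow artefacts beyond the echo-1 option.  Passing phantom tests
therefore demonstrates correctness of the estimation and classification
chain under the stated noise model, not in-vivo robustness to those
effects.

## Bayes/MAP plaque classification

Accepted wall voxels are classified into LRNC, fibrous tissue (shared
with normal intima/media) and recent IPH via
P(C_i | T2) ∝ P(C_i) · N(T2; μ_i, σ_i) and the MAP rule.  Class
conditionals are trained from labelled voxels (sample mean, n−1 SD;
≥ 2 voxels and nonzero variance per class required); priors default to
1/3 each.  Ties are broken by class order (LRNC < fibrous < recent IPH),
a measure-zero event for continuous T2.  Decision boundaries are the
admissible roots of the pairwise quadratic log-density equations; for
the default parameters they fall near 16.9, 45.1 and 73.6 ms.

Calcification precedes the Bayes step: it has no decaying signal, hence
no valid T2, so wall voxels whose synthetic proton-density-weighted
image — the fitted curve evaluated at TE = 14 ms, or the measured
first-echo intensity where the fit was rejected — has SNR < 2 are masked
first and never receive posteriors.  Under Rician noise the first-echo
fallback detects a truly signal-free voxel with probability
1 − exp(−2) ≈ 0.865, which bounds the expected per-blob detection rate.
An optional minimum connected-component filter can suppress isolated
recent-IPH speckle caused by T2 overestimation; it is off by default.

## Agreement statistics

Reader agreement over the ordered AHA plaque types uses the square
cross-classification table: percent agreement = trace/N and unweighted
Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from the marginal products.
Linear and quadratic weighted κ are provided as options but unused by
default, since the unweighted form reproduces the published value on the
published table.  Report rounding: κ to 2 decimals, agreement to integer
percent.

## Validation problem sizes and numerical choices

- Noise-free recovery: 64×64 phantom, every accepted voxel within 1e−6
  relative of truth (in practice ≈ 1e−15).
- Monte-Carlo recovery: 500 voxels per class at T2 ∈ {37, 54, 56, 107} ms,
  measured first-echo SNR 30; the median relative T2 error stays below
  5%.  T2 = 107 ms sits closest to that limit (~4.7–5.0%): the TE window
  ends at 103.2 ms, under one half-life of the decay, which is the
  information-theoretic weak spot of the design.
- Oracle cross-checks: the LM solution is never worse (RSS) than a
  400×400 log-spaced grid search; MAP boundaries agree with a 0.001 ms
  scan; empirical classifier accuracy on model draws matches the
  closed-form Gaussian decision-region accuracy within 3 Monte-Carlo SEs.
- Pure-noise voxels pass the dual significance gate far below the 5%
  nominal level (the trailing SNR cut usually leaves too few points to
  fit at all).
- End-to-end validation phantom: 128×128, equal-size component blobs
  (radius 5 px) so every class mean is estimated from ≥ 50 voxels; the
  per-tissue mean estimated T2 agrees with the mean generated T2 within
  2 ms, and ≥ 90% of accepted voxels whose true T2 lies > 5 ms from
  every decision boundary (and inside their own class's region) receive
  the correct label.  Classified-voxel means are additionally reported:
  decision-region truncation biases the recent-IPH classified mean
  noticeably downward (upper-tail fibrous/wall voxels cross the ≈ 73.6 ms
  boundary), which is why recovery is assessed against ground-truth
  labels.

## Known limitations

- Mono-exponential model only; multi-compartment or stimulated-echo-
  corrected models are out of scope.
- The Gaussian class-conditional model assigns every long-T2 voxel to
  recent IPH; sparse false IPH under T2 overestimation is expected and
  only optionally filtered.
- Noise σ is global; spatially varying noise (parallel imaging) is not
  modelled.
- The significance gate tests β ≠ 0 and T2 ≠ 0, following the published
  procedure; for a decay time the latter is a weak null and acts mostly
  through its standard error.
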