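# Methods

`phasefmri` implements a complete single-machine fMRI analysis stack built
around phase-based image registration and non-parametric statistics. This
note describes the models and procedures, the parameters that matter, what
the synthetic phantoms do and do not emulate, and the numerical choices
made where the design was genuinely open.

## Quadrature filters and local phase

All registration in the package is driven by *local phase* rather than raw
intensity. A quadrature filter is a complex-valued 3D bandpass filter whose
real part is even-symmetric (a line detector) and whose imaginary part is
odd-symmetric (an edge detector). The argument of the filter response
encodes the type of local structure independently of the image's intensity
scale or offset; the magnitude acts as a certainty. Because the filters are
bandpass, slow intensity variations (bias fields, shadings) and
high-frequency noise are both suppressed, which is what makes the
registration robust to the intensity corruptions that defeat plain
intensity-difference methods.

Filters are designed in the frequency domain as a lognormal radial profile

    R(w) = exp( -4 / (ln 2 * B^2) * ln^2(w / w0) )

multiplied by a directional factor `(w_hat . n_hat)^2` on the half-space
`w_hat . n_hat > 0`, sampled on a 33^3 grid, inverse-transformed, cropped
to 7^3 taps and renormalized to unit response at the tuning frequency.
Defaults: center frequency `w0 = pi/3` rad/sample (wavelength 6 voxels,
matched to cortical-scale structure at typical voxel sizes), bandwidth
`B = 2` octaves, which are standard choices for this filter family.
Cropping to 7^3 reintroduces a small DC term and a small first moment in
the odd part; both are explicitly removed after cropping (the former would
leak the mean intensity, the latter would make the edge detector respond to
linear shadings — with the correction, a full-volume linear shading changes
the responses only at machine precision).

The linear algorithm uses three filters along x, y, z. The non-linear
algorithm uses six filters along the antipodal-unique icosahedron vertex
directions `(0, ±1, g), (±1, g, 0), (g, 0, ±1)` (g the golden ratio,
normalized), for which `sum_k n_k n_k^T = 2 I` — the identity that makes
the isotropic structure tensor come out as exactly `I`.

Convolution is performed in the spatial domain semantically (FFT-based
under the hood, which is numerically identical to well below the tested
1e-8 tolerance), with zero padding in `same` mode; responses in the
half-kernel border halo are treated as invalid wherever that matters.

## Linear (affine/rigid) registration

The optical-flow constraint `grad^T v = delta` is written with the phase
gradient and the per-filter phase difference `delta_phi = arg(q1 conj(q2))`
in place of the image gradient and difference, and the motion field is the
12-parameter affine model `v(x) = B(x) p` (3 translations + 9 matrix
entries relative to identity). Accumulating the weighted normal equations
over all voxels and filters gives one 12x12 system `A p = h` per iteration.

Numerical and design choices:

* **Coordinates are centered on the volume midpoint**, so rotations pivot
  about the center and the translation and rotation blocks of `A` are
  nearly decoupled.
* **Weighting is the squared phase-match certainty**
  `c = sqrt(|q1||q2|) cos^2(delta_phi / 2)`, squared — the same weight the
  per-voxel non-linear solve uses. On the phantom benchmark the squared
  weight roughly halves the recovered-rotation error relative to plain `c`
  (rotation information lives in voxels far from the center, where phase
  inconsistency is most damaging).
* **Iteration accumulates the parameter vector**: each iteration warps the
  *original* moving volume with the composed transform (one interpolation),
  estimates an increment from the phase differences, and composes. Phase
  differences from rotations are only partially explained by the first-order
  model, so rotations converge over several iterations; 10 iterations per
  scale is the default for volume registration, 3 for motion correction.
* **Multiscale**: Gaussian blur (FWHM 2 voxels) + factor-2 decimation per
  level; translations double when moving to a finer level. Levels whose
  smallest axis would drop below twice the filter size are skipped.
* **Rigid restriction** projects the linear part onto the closest rotation
  by SVD with all singular values forced to one and the determinant forced
  positive; rotation angles are extracted with four-quadrant arctangents.
  The Euler convention is fixed operationally: `compose_euler` is defined
  as the transpose of `Rz Ry Rx`, derived so extraction round-trips
  exactly; a 1,000-rotation round-trip property test pins it.
* An ill-posed scale (constant intensity, too few certain voxels,
  condition number above 1e12) keeps the incoming parameters and warns.

Motion correction registers every volume rigidly to the reference volume
and reports a T x 6 trace (translations in voxels, rotations in degrees).
The total recovery error metric is the square root of the sum of squared
parameter differences over all time points and all six parameters.

## Morphon non-linear registration

After an affine pre-alignment, the Morphon solves a 3x3 system per voxel:

    d = ( sum_k c_k^2 T^T T )^(-1) sum_k c_k^2 dphi_k T^T T n_k

where `T` is the local structure tensor
`T = sum_k |q_k| (5/4 n_k n_k^T - 1/4 I)` built from the six filter-response
magnitudes. The tensor reinforces displacements along the locally dominant
orientation (perpendicular to edges); where it is rank-deficient the motion
is simply unconstrained in the null directions, and voxels whose system has
condition number above 1e8 (or no certainty) get zero displacement rather
than a regularized inverse — the Gaussian field regularization then fills
these in from their neighbourhood. The increment field is smoothed
component-wise (default FWHM 4 voxels per scale, halved at the finest
scale) and composed onto the accumulated field by trilinear lookup, so the
moving volume is always warped once from the original. The border halo
(half the filter size) is zeroed before regularization because responses
there are corrupted by the zero padding.

On the 32^3 phantom, a known smooth sinusoidal deformation of 2-voxel
amplitude is recovered to about 0.3 voxels RMS inside the brain mask, and
normalized cross-correlation to the reference rises from ~0.72 to ~0.995.

## Preprocessing

* **Slice timing**: every slice's time series is resampled to the middle
  slice's acquisition time with Catmull-Rom cubic interpolation (the
  "cubic in time" choice pinned to a specific, exactly testable kernel),
  clamped at the series edges.
* **Gaussian smoothing** is Cartesian separable with
  `sigma = FWHM / (2 sqrt(2 ln 2))` per axis (FWHM in mm, converted through
  the voxel size), truncated at 4 sigma, zero-padded — so values shrink
  toward the volume borders, documented behaviour.
* **Normalized averaging** computes `(v.c * f) / (c * f)` with the same
  separable Gaussian and the binary brain mask as certainty: out-of-mask
  values can then never leak into in-mask smoothed values (no edge
  darkening at the brain boundary). Denominators below 1e-6 yield zero
  with a warning.
* **EPI segmentation**: smooth one volume with a 4 mm Gaussian and
  threshold at 90% of the smoothed volume's mean over all voxels. The rule
  is scale-invariant by construction. Edge-replicated borders are used for
  this one smoothing so a constant volume yields a full mask.
* **Skullstripping** is registration-based and two-pass: register the T1
  to a with-skull template, pull the template brain mask back into T1 space
  (nearest-neighbour + 0.5 threshold keeps it binary), multiply; then
  register the stripped T1 to a brain-only template and re-transform the
  mask with the improved parameters, again multiplying the original T1.

## GLM with AR(4) prewhitening

The voxel-wise model is `y = X beta + eps`. The design matrix is ordered
`[task | motion(6) | mean, linear, quadratic, cubic]`, the trends built on
normalized time in [-1, 1] (raw powers, not orthogonalized — inference uses
contrasts on task columns only), with at most 25 regressors. OLS uses the
shared pseudoinverse; `t = (c^T beta - u) / sqrt(var(eps) c^T (X^T X)^-1 c)`
with the *unbiased* residual variance `||eps||^2 / (T - R)` — the divisor is
pinned by the null-calibration property (the two-sided 5% rejection rate on
white noise matches the Student reference within 1% at 100k voxel draws).
The F statistic generalizes to a contrast matrix and divides by the number
of contrast rows; for a single row F = t^2 exactly.

First-level errors are modelled as AR(4). The Cochrane-Orcutt procedure
(three iterations by default) alternates: residuals from the newest beta
against the *original* y and X; per-voxel Yule-Walker AR(4) estimates
(biased autocovariances, normalized by T); spatial smoothing of each AR
coefficient map (7 mm normalized averaging within the mask); whitening
`y~_t = y_t - sum rho_i y_{t-i}` of the data and of every design column
(zero initial conditions, length preserved — chosen over dropping the first
`order` samples to keep the permutation bookkeeping trivial); and a
re-estimated beta from the voxel-specific whitened system. Final statistics
use the whitened residual variance and voxel-specific `(X~^T X~)^(-1)`.
On AR(4) synthetic data at T=500 the recovered effect is biased by well
under 5% and the AR coefficients are recovered to better than 0.05 RMS.

### AR estimation for the permutation pipeline

Yule-Walker on OLS residuals is systematically biased: the residual
projection `(I - H)` absorbs exactly the low-frequency power the detrend
columns span, so on white noise the naive estimates come out near -0.1 per
coefficient, and surrogates built from them carry less autocorrelation than
the data — an anticonservative test. The permutation pipeline therefore
uses two refinements, implemented in `glm.estimate_ar_spatial`:

1. **Residual-projection bias correction.** For residuals `r = (I-H) eps`,
   the expected lag-k sample autocovariance is a known linear mixture of
   the true error autocovariances, `E[c_k] = sum_l M_kl gamma_l`, with `M`
   computable from the design alone. Inverting `M` yields unbiased
   autocovariance estimates.
2. **Smooth the autocovariances, not the coefficients.** The AR maps are
   spatially smoothed as usual, but the smoothing is applied to the
   corrected autocovariance maps *before* the Yule-Walker solve. Solving on
   low-noise averaged autocovariances sidesteps the small-sample ratio bias
   (about `-(1+3 rho)/T`) that per-voxel solves then averaging would retain.

With both refinements the AR estimates are unbiased to ~0.01 at T=60 and
the first-level permutation test calibrates (see below). The
Cochrane-Orcutt fit itself keeps the classical estimate-then-smooth order;
its recovery targets do not require the correction at T=500.

## Permutation inference

All corrected p-values come from maximum-statistic permutation tests: in
each permutation only the image-wide maximum (voxel-level) or the largest
cluster extent/mass above a cluster-defining threshold is kept. The
corrected p is the proportion of null values greater than or equal to the
observed value — the printed convention without a +1 correction; the
identity permutation/relabeling is always forced into the set, so the
smallest achievable p is `1/n_permutations`. The alpha-level threshold is
the sorted null value at the ceiling rank `(100 - alpha)% * n`; with ties
this order statistic may equal lower entries, and thresholding with strict
`>` keeps the empirical FWE at or below alpha up to the 1/n granularity.

Cluster labeling is a hand-written union-find over the suprathreshold set
with 26-connectivity (corner-touching voxels join), deterministic labels by
smallest linear voxel index; an independent flood-fill implementation
serves as the test oracle.

**Second level** needs no whitening or smoothing: subjects are relabeled by
sign flips (one-sample designs) or design-row permutation, the group GLM is
refit and the maximum recorded. When the requested permutation count
reaches the number of distinct relabelings (2^S or S!), the test falls back
to full enumeration with a warning. Permutation streams come from a
counter-based Philox generator keyed by the seed; results are
bit-reproducible. Empirical FWE over 500 null simulations (10 subjects,
12^3 smooth Gaussian noise, 128 permutations) is ~4% at alpha = 5%.

**First level** whitens once and permutes in the whitened domain:
detrend, estimate the voxel-wise AR(4) model (with the refinements above),
whiten; in each permutation shuffle the whitened series in time (the same
permutation at every voxel, preserving spatial structure for cluster
inference), run the AR recursion forward to put the autocorrelation back,
re-smooth (smoothing alters the autocorrelation, so it must be redone every
permutation) and fit OLS. The observed statistic is the identity
permutation processed identically — which reconstructs the detrended data
exactly, since whitening and the forward recursion are exact inverses given
matching zero initial conditions. Empirical voxel-level FWE on no-signal
AR data is 5-8% at alpha = 5% across the tested noise settings.

## Bayesian GLM (Gibbs sampler)

Per voxel, `y = X beta + eps` with AR(1) errors, priors: `beta | sigma2`
Gaussian (mean 0, precision `Omega0 / sigma2`, default `Omega0 = 1e-4 I`),
`sigma2` inverse gamma `(a0, b0)`, `rho` Gaussian (mean 0, variance
`v0 = 1`) truncated to (-1, 1). Each sweep draws `sigma2 | rho` from an
inverse gamma with shape `a0 + T/2` and a scale built from the
beta-marginalized quadratic form, then `beta | sigma2, rho` from a
multivariate Gaussian, then `rho | beta, sigma2` from the residual lag
regression with rejection outside the stationarity interval (the previous
value is kept if 50 redraws all fall outside). All quadratic forms come
from rho-separated sufficient statistics `S_ij, m_ij, g_ij` with the
convention `rho_0 = -1` (lagged samples zero for t <= 0, consistent with
the whitening), so no sweep ever touches the raw series; residual lag sums
for the rho step use the same moments.

Random numbers: uniforms from a counter-based Philox stream, normals via
the Box-Muller transform, and inverse-gamma draws as
`g = 2B / sum_{i=1}^{2A} n_i^2` — which requires `2A` to be a positive
integer. The posterior shape is `a0 + T/2`, so validation requires `2 a0`
integral; the default is `a0 = 0.5`, `b0 = 0.01` (weakly informative, and
the smallest half-integral shape). The sampler is vectorized over voxels;
up to 8 regressors and AR order 1 are supported.

The posterior probability map (PPM) is the fraction of retained draws with
`c^T beta > 0`. Consistency checks: with rho = 0 and a diffuse prior the
chains reproduce the conjugate Normal-Inverse-Gamma moments and the PPM
tracks the analytic Student posterior probability within 0.02; under pure
noise the PPM averages 0.5; the inverse-gamma sampler matches the analytic
mean and variance at A=3, B=2 and passes a Kolmogorov-Smirnov test against
the exact CDF.

## Synthetic phantoms — what they do and do not show

The fixtures module generates every input the tests need:

* **Phantom volumes**: nested ellipsoids (sharp edges), eight random
  Gaussian blobs (internal lines/blobs), and a moderate smoothed noise
  texture. All three ingredients matter: phase-based *rotation* recovery
  needs oriented edge structure, and an isotropic fine-noise texture alone
  decorrelates the quadrature responses under rotation. The brain mask
  fills 20-50% of the volume.
* **Motion series**: rigid transforms with all six parameters drawn
  N(0, 0.5) (voxels / degrees) per time point, volume 0 untransformed,
  plus white noise scaled as a percentage of the maximum intensity
  (defaults 0.5-2%) and an optional linear shading increasing along z.
  The drawn parameters are recorded in the convention the motion-correction
  estimator reports, so the total-error metric applies directly.
* **Activation series**: block-design (boxcar, or boxcar convolved with a
  single-gamma HRF — fixtures-only conveniences; the analysis caller always
  supplies regressors) times a ground-truth effect confined to an
  ellipsoidal mask, plus AR(p) noise with specified coefficients and
  innovation variance, on a flat or phantom-structured baseline.

All generators are pure functions of (parameters, seed). They emulate
geometry, motion statistics and noise autocorrelation — not MR physics: no
B0 distortion, slice-profile effects, spin history, partial volume, or
physiological noise, and the motion is temporally independent rather than
drifting. Passing tests therefore demonstrate the correctness and
calibration of the algorithms under their stated models, not performance
on real scanner data.

## Problem sizes used in the validation suite

Registration and phantom tests run at 32^3; statistical calibration uses
100,000 voxel-draws for the parametric null, 500 simulated group studies
(10 subjects, 12^3) for the second-level FWE, and ~100 replicates at 150-200
permutations for the first-level FWE; Cochrane-Orcutt recovery uses T=500
over 200 voxels; Gibbs checks use 1,200-2,500 draws over 150-600 voxels;
the end-to-end pipeline runs 16^3 x 40 with 1,000 permutations. These sizes
give comfortable statistical resolution for every asserted tolerance while
keeping the whole suite fast on one CPU.

## Known limitations

* The quadrature filter coefficients are a reproducible lognormal design,
  not the product of a joint space/frequency optimization; any software
  using individually optimized coefficients will differ at coefficient
  level (though the invariants — symmetry, DC-free, bandpass — agree).
* Rigid/affine estimation assumes isotropically resampled inputs; no
  anisotropic-voxel handling beyond the NIfTI voxel size in mm-based
  smoothing.
* The Morphon offers no inverse-consistency or diffeomorphism guarantee;
  large deformations that fold are not prevented (regularization only
  discourages them).
* The Bayesian model is AR(1) with at most 8 regressors.
* Exchangeability of whitened residuals is approximate: the surrogate
  transient from zero initial conditions and any model mismatch beyond
  AR(4) are ignored; calibration was verified for AR noise up to
  `sum rho approx 0.5`.
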