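# Methods

## Model

A broad leaf is represented as N identical absorbing dielectric plates
(the structure index N is real-valued, N ≥ 1, a proxy for mesophyll
scattering complexity). Per wavelength λ (nm, 400–800 at 1 nm by default):

1. **Absorption.** Each pigment i ∈ {Chla, Chlb, Cars, Ants} has a specific
   absorption coefficient K_i(λ) (cm²/µg) built as a sum of pseudo-Voigt
   peaks: a Gaussian and a Lorentzian sharing position p, height h and
   FWHM w, mixed by the Gauss ratio v ∈ [0, 1]. The `4·ln2` and `4`
   scalings make w the full width at half maximum of *both* components, so
   the mixture attains exactly h at p and h/2 at p ± w/2. The in vivo
   position is the organic-solution position plus a spectral displacement
   Δλ (solvent-to-leaf polarity shift). The per-layer absorption is
   k(λ) = Σ_i K_i(λ)·C_i / N + K0(λ), with C_i in µg/cm² and K0 a
   nonnegative baseline for non-pigment photosensitive material (zero by
   default; configurable or fittable).
2. **One plate.** The incident beam enters the top interface within a
   40° solid-angle cone (the plate-model lineage convention; configurable)
   with the cone-averaged unpolarized Fresnel transmissivity tav(θm, n).
   Inside, the flux is assumed perfectly diffuse: a single traversal
   transmits τ(k) = (1−k)e^(−k) + k²E₁(k) (isotropic Beer–Lambert with
   slant paths), and internal interface crossings use the hemispherical
   averages t21 = tav(90°, n)/n². The infinite bounce series is summed in
   closed form.
3. **Stack.** N−1 further diffuse plates are attached with the Stokes
   layer-stacking solution generalized to real N through the
   a/b parameterization (a, b real because one plate always satisfies
   R+T ≤ 1; degenerate limits — no absorption, vanishing reflectance,
   vanishing transmittance — are handled by their analytic limits).

The model conserves energy: R(λ) + T(λ) ≤ 1 with equality exactly when
k(λ) = 0, and T decreases monotonically in each concentration wherever the
corresponding K_i(λ) > 0.

### Shipped parameters

The packaged default (`table6-default`) carries nine calibrated peaks:
Chla at in vivo positions 419/591/627/679 nm, Chlb at 468/612/661 nm, Cars
at 482 nm, Ants at 544 nm, with their Gauss ratios, heights, widths,
organic-solution positions and displacements, plus the reported
range-of-absorption-feature intervals as metadata. Two chlorophyll-*b*
peaks carry an explicit in vivo position that differs by a few nm from
solution position + displacement as separately published; the explicit
in vivo position is authoritative here and both numbers are stored (the
`invivo_position` override on `PeakParameter`). RAF intervals are stored
verbatim and never recomputed: their defining threshold is not a
half-maximum rule (the anthocyanin interval matches half maximum, the
carotenoid one does not), so any recomputation would be guesswork.

The leaf average refractive index spectrum m_la(λ) is not part of the peak
table. The shipped default is a smooth **synthetic stand-in** generated in
code (1.40 + 0.14·e^−(λ−400)/350, declining from ≈1.54 to ≈1.44),
reproducing the published envelope of leaf refractive indices; any measured
spectrum can be supplied as a CSV. No shipped result depends on its exact
values: the coefficient-anatomy measurements bypass the plate model, and
all round-trip tests use the same m_la on both legs.

## Retrieval protocol

Default two-stage protocol: first N is estimated on the 780–800 nm
minimal-absorption window by bounded least squares over (N, k_w), where k_w
is a single constant nuisance absorption that soaks up residual red-edge
pigment tails; N is clamped to [1, 4] and a boundary solution raises a
warning flag. Then the four concentrations are inverted with N fixed, by
trust-region-reflective least squares on the unweighted merit function with
bounds [0, 200] µg/cm² per pigment, from four deterministic start points
(one mid-range canonical start plus three drawn from a seeded generator) to
avoid local minima; the best final merit wins. A joint mode frees N ∈ [1,4]
alongside the pigments. Optimizer failures are reported through
`converged=False`, never raised. Identical inputs and seed give bitwise
identical results.

## Calibration

`calibrate_model` re-fits the peak parameters from a calibration dataset by
alternating (a) per-sample N estimation, (b) a joint bounded least-squares
fit of all peak parameters (v ∈ [0,1], h ∈ (0, 2] cm²/µg, w ∈ [10, 250] nm,
|Δλ| ≤ 45 nm) plus, optionally, K0 as nonnegative values on a coarse knot
grid (9 knots, linear interpolation), and (c) optionally a per-wavelength
bounded scalar search for m_la in [1.2, 1.6] followed by an 11-point
moving-average smooth against wavelength-to-wavelength jitter. Each step is
accepted only if it improves the pooled merit, so the outer merit history
is nonincreasing by construction; the loop stops when the improvement falls
below 1e−8 or after `max_outer` iterations (best-so-far returned with
`converged=False` in the latter case).

The Δλ bound of ±45 nm admits the largest calibrated displacement in the
shipped set (39 nm, carotenoids) with margin while still anchoring every
peak to its solvent position — the anchoring is what keeps the
overlapping-band fit from degenerating into an unconstrained spectral
decomposition. Displacements are always fitted relative to the solution
position; pinned in vivo positions in an init set are folded into the
starting displacement.

Free-parameter accounting: four parameters (v, h, w, Δλ) per peak, e.g. 12
for a three-peak carotenoid specification and 36 for the shipped nine-peak
set.

`split_dataset` builds calibration/validation splits by seeded shuffling
screened for representativeness: each subset's per-pigment mean must lie
within 10% (configurable) of the full-set mean and its range must bracket
that mean.

## Synthetic data

`simulate_dataset` emulates the statistical envelope of a multi-species
leaf campaign: concentrations drawn uniformly (log-uniform optional) within
per-pigment ranges — defaults Chla [0.04, 94.53], Chlb [0.05, 47.49], Cars
[0.24, 44.55], Ants [0.01, 47.22] µg/cm² — with the Chlb/Chla ratio
constrained to [0.4, 1.09] (the ratio is drawn first and Chla is then drawn
on the subinterval keeping Chlb in range, so both constraints hold without
clipping), structure index uniform in [1, 3], and independent additive
Gaussian noise (σ = 0.005 by default) on R and T, the reproducibility-grade
noise of a bench spectrophotometer. Noisy values are clipped to [0, 1] and
pairs are renormalized where R + T would exceed 1, so all generated spectra
satisfy the physical invariants; near the limits (T → 0 under strong
absorption, R + T → 1 in the near infrared) the effective noise is
therefore truncated and its per-wavelength RMSE falls below σ. A
heteroscedastic noise model can be plugged in by post-processing the clean
spectra, which `forward_model` returns directly.

What the generator does **not** emulate: species-level covariance between
pigments (independence within the ratio constraint is assumed), baseline
absorption (K0 = 0 unless configured), water/dry-matter absorption (absent
from the 400–800 nm parameterization), and instrument artifacts other than
additive noise. Passing round-trip tests on these fixtures therefore
demonstrates the correctness and conditioning of the estimator under the
model's own assumptions, not retrieval accuracy on real leaves.

## Evaluation metrics

For residuals d = predicted − measured: RMSE = √(mean d²), BIAS = mean d,
SEC = √(Σ(d−BIAS)²/(n−1)) and CV = 100·SEC/mean(measured) (flagged
undefined when the measured mean is zero). The n−1 denominator and the
predicted−measured sign convention are explicit package choices. They imply
RMSE² = BIAS² + SEC²·(n−1)/n, which is verified to 1e−10 in the tests.
`spectral_error_profile` applies the same metrics across samples at each
wavelength, separately for R and T.

## Numerical choices

- tav(θm, n) is evaluated by 64-point Gauss–Legendre quadrature of the
  Fresnel integrand in θ, where it is smooth; this is machine-precision
  accurate and vectorizes over the wavelength-dependent index. The test
  suite checks it against independent adaptive quadrature, and the whole
  single-plate solution against a Monte-Carlo photon tracer.
- τ(k) uses `scipy.special.exp1`; k = 0 is special-cased to 1 and the
  result clipped to [0, 1] against underflow at extreme k.
- Stokes stacking switches to limit expressions when r + t ≥ 1 − 1e−12
  (conserving layer), t < 1e−12 (opaque layer) or r < 1e−12 (pure
  absorber).
- Inversion and calibration use scipy's trust-region-reflective
  `least_squares` with ftol = xtol = gtol = 1e−12 and finite-difference
  Jacobians.
- Spectra CSVs on non-1 nm grids are resampled by linear interpolation with
  a logged note.

## Problem sizes

The shipped test suite runs the photon-tracing comparison at 20 random
interface/absorption configurations with 10⁶ photons each, the inversion
round trip on 100 noiseless synthetic leaves spanning the full
concentration envelope, the noise-bias check on 50 replicates at σ = 0.005,
and the calibration recovery on 40 noiseless leaves with all 36 peak
parameters free from a deliberately perturbed init (displacements zeroed,
heights shrunk 20%). These sizes were chosen so the full statistical suite
completes in minutes on one CPU while keeping the Monte-Carlo standard
errors and recovery tolerances meaningful.

## Known limitations

- No bidirectional effects: surfaces are rough Lambertian-coupled
  interfaces; surface roughness, specular/diffuse separation and viewing
  geometry are out of scope.
- The 400–800 nm window excludes water and dry-matter bands; do not run the
  model beyond the red edge without adding those absorbers to K0.
- Carotenoids are treated as one pool; individual xanthophylls are not
  retrievable.
- The default refractive index is a synthetic stand-in (see above);
  absolute forward-modelling accuracy on real leaves requires a measured or
  calibrated m_la(λ).
- The anthocyanin assay conversion interprets the published molar
  coefficient as a molar absorptivity (L·mol⁻¹·cm⁻¹) referenced to
  cyanidin-3-glucoside (449.2 g/mol); both are configurable because the
  literature is ambiguous about the unit.
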