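# Methods

This note documents the models, numerical choices and synthetic-data design
behind `cortimat`, and what the test suite does and does not demonstrate.

## Tissue model and its assumptions

The voxel signal model is the standard three-compartment construction:
Watson-dispersed sticks (intra-neurite), a tortuosity-coupled axially
symmetric Gaussian tensor (extra-neurite), and free water. Its assumptions,
inherited deliberately:

* **Fixed compartment diffusivities.** `d_par = 1.7e-3 mm²/s` and
  `d_iso = 3.0e-3 mm²/s` are the documented adult defaults. No neonatal
  reference values exist, and freeing the intrinsic diffusivity is known to
  destabilise the fit, so the values are fixed but configurable
  (`ModelConstants`; `model.d_par` / `model.d_iso` in pipeline YAML), and
  the CLI records them next to its outputs so results declare their
  constants.
* **Watson dispersion.** Single-modal, antipodally symmetric orientation
  distribution; no Bingham anisotropic dispersion, no dot compartment, no
  per-compartment T2 weighting.
* **Tortuosity.** `d_perp = d_par · (1 − v_in)`, with the extra-neurite
  tensor orientation-averaged under the Watson distribution: the mean
  squared cosine τ₁ = M(3/2,5/2,κ)/(3·M(1/2,3/2,κ)) sets the axial
  eigenvalue `d_perp + (d_par − d_perp)·τ₁`, and the perpendicular
  eigenvalues share the remaining trace equally.

## Numerics of the Watson integrals

Every orientation average reduces to the surface integral of `exp(nᵀBn)`
over the unit sphere for a symmetric 3×3 `B` (for the stick kernel,
`B = κ μμᵀ − b·d_par · ggᵀ`, rank ≤ 2, eigenvalues in closed form). In the
eigenbasis this is a 1-D integral with a modified-Bessel azimuthal factor,
evaluated by fixed 128-node Gauss–Legendre quadrature after shifting all
eigenvalues by their maximum, so every exponent is non-positive and nothing
overflows at any κ or b. Accuracy is ~1e-14 for eigenvalue spreads up to
~10³ (κ up to 128, the fitting bound, is comfortably inside). Beyond a
spread of 1.2×10³ the integrand is too peaked for the fixed rule and the
evaluation switches to the Laplace approximation around the dominant
eigenvector (relative error O(1/spread); at κ = 10⁴ about 5e-5) — this
branch only serves extreme-κ queries outside the fitting range, e.g. the
single-stick limit. Kummer-transformed hypergeometric ratios
(`M(a,b,κ) = e^κ M(b−a,b,−κ)`) keep the Watson normalisation and τ₁ stable
to at least κ = 1e4.

The closed form for the fully dispersed stick,
`√(π/4x)·erf(√x)` with `x = b·d_par`, and a 2-D product-quadrature sphere
integral serve as independent oracles in the tests.

## Fitting pipeline

* **Shell normalisation.** Each shell is divided by the mean of its own b0
  volumes (the two shells have different TE/TR, so their baselines are not
  comparable). Means rather than medians: at most 4 b0s per shell, the mean
  minimises variance. The result is exactly invariant to global rescaling
  of the raw signal up to floating-point rounding of the division.
* **Initialisation.** Exhaustive grid search over v_in (13 points on
  [0, 0.3] — the restricted start range for premyelinated tissue), f_iso
  (11 on [0, 1]), κ (8 log1p-spaced on [0, 64]) and 30
  repulsion-distributed orientations. The restriction applies to starting
  points only; optimisation bounds stay at [0, 1]. RSS ties break toward
  the lexicographically smallest (v_in, f_iso, κ). The grid's model
  signals are precomputed once per (scheme, constants, grid) and cached.
* **Refinement.** Bounded trust-region least squares over
  (v_in, log(1+κ), f_iso, θ, φ); the log1p parameterisation avoids the
  κ = 0 boundary pathology; κ is capped at 128 (ODI ≈ 0.005). Convergence
  requires the optimiser's success flag, a final RSS at most twice the
  initialisation RSS, and no parameter pinned at a bound with a
  non-vanishing outward gradient. f_iso ≥ 0.99 raises a degeneracy flag
  (v_in and κ are unidentifiable in free water).
* **Orientation restart.** In weakly anisotropic voxels the grid's coarse
  orientation can drop the refinement into a κ = 0 local minimum. Since the
  noiseless model signal is axially symmetric about μ, the lower-shell
  tensor's principal eigenvector identifies the axis; whenever κ ends at
  (numerically) zero or the fit fails to converge, the pipeline restarts
  once from that orientation and keeps the better optimum. This removed the
  ~6% of voxels that otherwise stall.
* **Dictionary fallback.** Voxels still not converged are re-initialised by
  non-negative least squares (small L2 ridge, 1e-3) onto 144 tissue atoms
  spanning 12 v_in × 12 κ values at the DTI orientation plus one isotropic
  atom; weight-averaged atom parameters (dispersion averaged on the ODI
  scale, where atoms are evenly spaced) seed a second refinement.

Noiseless identifiability on the study acquisition (32 directions at b=750
+ 1 b0, 64 at b=2500 + 4 b0s): 95th-percentile recovery errors are at
machine precision (~1e-15) over 500 random draws. At SNR 20 the
magnitude-noise (Rician) floor inflates the attenuated high-shell signal
and biases v_in upward by ~+0.08 at a typical cortical parameter set; a
least-squares fit cannot remove this (that would need a Rician-likelihood
estimator, out of scope). Trajectory analyses are therefore comparisons of
identically biased estimates across age.

## DTI

Signal²-weighted linear least squares on the log-signal, lower shell only
(the Gaussian model fails at b = 2500 in tissue), with the shell's b0s
averaged into a single baseline observation. Non-positive signals are
clamped to 1e-3 × the voxel's smallest positive signal and flagged.
Negative eigenvalues are kept for MD (unbiasedness) but clamped at zero
inside FA's normalisation so FA stays in [0, 1]; such voxels are flagged.

## Regional aggregation

A voxel enters region r iff it is grey matter, labelled r, and its fitted
f_iso is strictly below 0.5 (a voxel exactly at threshold is excluded).
Medians (even count: mean of the central pair) give robustness to residual
partial-volume outliers; a pooled whole-cortex row is the median over the
union of regional voxel sets. Inputs must be voxel-aligned; mismatched
grids are refused rather than resampled (registration is upstream of this
package). Labels above 82 are rejected with a warning — the analysis is
defined on an 82-region cortical scheme, sub-cortical and cerebellar
structures excluded.

## Developmental statistics

* **Residualisation.** Covariates (sex, small-for-gestational-age,
  respiratory-support days, head coil, gestational age at birth) are
  regressed out before rank correlation. With repeated scans a linear mixed
  model with a per-subject random intercept is used and *conditional*
  residuals (observed − fixed effects − predicted intercept) returned;
  windows containing no repeated subject reduce to OLS with a logged
  notice. Covariate columns are standardised internally (a pure
  reparameterisation) to keep the mixed-model optimiser conditioned;
  rank-deficient designs are refused with the collinear columns named.
  The alternative rank-first ordering is not offered: residualise-then-rank
  is the single documented behaviour.
* **Partial Spearman.** Spearman correlation of the two residual vectors;
  two-sided t-approximation for n > 10, seeded 10,000-draw permutation
  test for n ≤ 10. With no covariates and no repeats this is exactly plain
  Spearman.
* **Windows.** Pre/post split at 38 weeks PMA; a scan at exactly 38.0 weeks
  is post. Second scans count as independent observations within a window.
* **Biphasic regression.** Continuous two-segment least squares; the
  breakpoint is grid-searched (0.1-week steps, ties toward the smaller
  candidate) between the 1st and 3rd PMA quartiles by default, with at
  least 3 observations required strictly on each side. Model choice:
  AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) with k = 5 for the broken line
  (intercept, two slopes, breakpoint, error variance) and k = 3 for the
  single line; "biphasic" only on strictly lower AICc. RSS is floored at
  1e-12 × total sum of squares so noiseless data stay finite without
  affecting the breakpoint (pure RSS argmin) or scale invariance. A
  discontinuous two-line variant is available behind a flag. Under a true
  line the broken line is selected in ~25% of simulated nulls (AICc is not
  a calibrated test; this documents its over-selection).
* **FDR.** Native Benjamini–Hochberg step-up (sorted p·m/rank, running
  minimum from the largest rank, capped at 1), applied separately within
  each contrast (metric × window × correlation family) across regions; the
  whole-cortex row is its own single-test family. The implementation is
  cross-checked against statsmodels' `multipletests` in the tests.

## Synthetic data: what it emulates, and what it does not

The phantom generator draws signals from the forward model with per-shell
b0 baselines (default 1.0 / 0.85 — a single multiplicative factor per shell
as the minimal structure exercising the per-shell normalisation; real
echo-time differences also act per compartment, which is not modelled) and
Rician noise (default sigma 0.05 = SNR 20 at b0). No head motion, eddy
currents or susceptibility artefacts are simulated — those are corrected
upstream by published tools in the real pipeline, which this package only
meets through a supplied exclusion list.

The cohort generator emulates the study design: 99 subjects, 8 scanned
twice (an early scan plus a term-equivalent scan), gestational age at birth
uniform on 24–37 weeks, 60% male, 30% small-for-gestational-age,
log-normal respiratory-support days, per-subject head-coil flag.
Scan age is sampled from 25 + 22·Beta(2.8, 1.8) weeks, reproducing the
cohort's reported quartiles (~35 / ~39 / ~42); a uniform distribution would
misplace the quartile-bounded breakpoint search. Covariates are sampled
independently (their empirical covariance is not reported) and effect sizes
are expressed per metric noise SD so one set spans metrics of different
scales. Metric trajectories are continuous piecewise-linear in PMA with the
break at 38 weeks — continuity mirrors the analysis model — plus covariate
effects, a per-subject random intercept and Gaussian noise. Noise SDs are
calibrated so the generated whole-cortex covariate-adjusted correlations
match the strengths reported for this cohort (ODI ≈ +0.77 and FA ≈ −0.66
pre-38; FA ≈ +0.43 and NDI ≈ +0.47 post-38; MD ≈ −0.63 and volume ≈ +0.82
overall). Under these conditions breakpoint recovery has median error
≈ 0.65 weeks with the biphasic model preferred essentially always; at
weaker effect sizes (≈2 noise-SD per decade slope change) the breakpoint is
not localisable to under a week at n = 99 — recovery claims are therefore
statements about effect sizes of the magnitude actually observed, not about
arbitrary small effects.

Passing tests on this synthetic data demonstrate correctness of the
estimators and statistics under the model's own assumptions. They do not
validate the tissue model against histology, nor the robustness of the
pipeline to artefacts the generator does not produce (motion, distortion,
compartment-specific T2, spatially correlated noise).

## Problem sizes and determinism

The test suite runs in ~3–4 minutes on one CPU: 500 noiseless recovery
draws, 200 noisy Monte-Carlo fits, 500-cohort breakpoint and 500-null
calibration simulations, phantoms up to 4×4 voxels, and cohort analyses
restricted to the whole-cortex column plus 5 regions (the analysis itself
scales linearly in regions; the full 82-region layout is the generator's
default). The acceptance script re-runs the recovery at 150 draws and the
breakpoint study at 150 cohorts, reporting each problem size in its JSON
output. All randomness flows through seeded `numpy` generators; phantom
and cohort generation are bit-reproducible for a fixed seed.

## Known limitations

* Fixed diffusivities bias parameter estimates if the true neonatal values
  differ; only the constants are configurable, not a free-diffusivity fit.
* The Rician noise floor biases v_in and f_iso upward at realistic SNR
  (least-squares estimator by design).
* The mixed model estimates a single variance component from only 8
  repeated subjects; its variance estimate is weak and may hit zero, in
  which case residualisation coincides with OLS.
* AICc-based model preference over-selects the broken line under the null
  (~10% in the suite's simulation); it is a descriptive choice criterion,
  not a test.
* `fit_volume` processes voxels serially; volumes beyond a few thousand
  masked voxels call for chunking or parallelism that is not provided.
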