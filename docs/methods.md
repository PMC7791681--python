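# Methods

This note documents the models and procedures `boldsv` implements, the
defaults and why, the numerical choices that matter, what the synthetic
generator does and does not emulate, and the package's known limitations.

## Signal model and the variability statistic

Each run is a 4D grid (X, Y, Z, T) with a voxel→world affine (world
coordinates are MNI millimetres for real data) and a repetition time TR.
The per-subject statistic is the temporal sample standard deviation (ddof 1)
of each voxel's preprocessed series — a direct time-domain index of
fluctuation amplitude, as opposed to spectral-amplitude measures — computed
after band-pass filtering and z-standardised across a gray-matter mask:

    z(v) = (SD(v) − mean_{mask} SD) / SD_{mask} SD .

Sample SD (ddof 1) is used both for the temporal SD and the across-mask
standardisation; the z map is invariant to that common choice and to any
positive affine rescaling of the raw map.  The gray-matter mask is a
required input: no tissue segmentation is performed, and whether a
subject-specific or group mask is supplied is the caller's decision.

## Preprocessing tail

Inputs are assumed already slice-time/motion corrected and spatially
aligned; motion parameters are *consumed* (for nuisance regression and
framewise displacement), never estimated.  Defaults, in order:

| step | default | notes |
|---|---|---|
| discard initial volumes | k = 5 | scanner equilibration |
| grand-mean scaling | target 10000 | multiplicative; cancels in z maps |
| nuisance regression | CSF, WM, 6 motion params + intercept, linear, quadratic trends | OLS residual per voxel; residuals orthogonal to the design |
| smoothing | 6-mm FWHM Gaussian | per-axis σ in voxels from the affine, so anisotropic voxels are correct |
| band-pass | 0.01–0.198 Hz; slow-5/4/3 sub-bands | ideal FFT filter |
| framewise displacement | 50-mm head radius | Power backward-difference convention, rotations in radians |

Numerical choices:

- **Band membership is half-open (low, high]** and DC is always removed.
  This makes slow-5/4/3 disjoint with union exactly equal to the overall
  band, so the variance partition (Parseval) holds to machine precision —
  a property the test suite checks at T = 235.  The filter is zero-phase
  and idempotent by construction.  The trade-off of a brick-wall filter is
  ringing near band edges for strongly non-stationary signals; no named
  filter family is canonical for this analysis, and the exact tiling
  property is worth more here than roll-off smoothness.
- **Smoothing boundary is symmetric ('reflect') extension**, which
  preserves constant images and conserves the spatial mean exactly;
  constant ('nearest') extension would preserve constants but not the mean.
- The nuisance fit uses a QR projection; rank-deficient designs are
  rejected with the indices of the dependent columns (found by pivoted QR).
- Order of operations is nuisance/detrend → smooth → band-pass.  The order
  is configurable; this default keeps the band-limited output exactly
  band-limited.

## Group inference

Voxel-wise OLS of z on [intercept, group, age, sex, mean FD]; the t
statistic is on the group column (with no covariates this reduces exactly
to the pooled two-sample t).  Sex coding (0/1 vs 1/0) does not affect the
group contrast.  Voxels with zero residual variance up to round-off
(perfect fits, label-invariant data) are assigned t = 0 rather than a
floating-point-noise ratio.

Two permutation procedures control family-wise error, both using the
add-the-observed convention p = (1 + #{null ≥ obs}) / (n_perm + 1), so
p ≥ 1/(n_perm+1) always:

- **Cluster extent**: voxels with |t| above the two-tailed critical value
  at p < 0.001 are grouped into 26-connected clusters; the null is the
  permutation distribution of the *maximum* cluster extent.
- **TFCE**: TFCE(v) = Σ_h e(h,v)^E · h^H · dh with E = 0.5, H = 2 and
  dh = max|stat|/n_steps (n_steps = 100 by default), positive and negative
  tails enhanced separately; the null is the distribution of the mask-wide
  maximum |TFCE|.  Voxel-wise FWE p values follow from the max-null.

Covariates are handled by **Freedman–Lane**: the reduced model (intercept +
covariates) is fitted once, its residual rows are permuted, the fitted part
is added back, and the full model is refitted.  For tiny designs without
covariates, when the number of distinct group-label arrangements C(n, n₁)
does not exceed the requested permutation count, the label space is
enumerated exhaustively instead (permuted-regressor form, equivalent in
distribution when no covariates are present); the mode used is recorded in
the result.  A permutation-based null was chosen over parametric
Gaussian-random-field correction for self-containment and small-sample
validity; equivalence with any particular software's parametric null is not
claimed.

**Calibration and conservativeness.** The suite verifies empirical FWE on
200 fully null synthetic cohorts (8 vs 8 subjects, 8×8×8 grid, T = 60,
n_perm = 500, TFCE with 10 enhancement steps — problem sizes chosen so the
whole calibration runs in a few minutes on one CPU; FWE validity of a
max-statistic test does not depend on the TFCE step count).  TFCE lands
near the nominal 0.05.  Cluster extent is conservative at this scale
(observed ≈ 0.01): with a p < 0.001 height threshold on a ~500-voxel mask
most null cohorts have no supra-threshold voxel at all, and the max-extent
null is heavily tied at small integers, so the attainable level sits below
the nominal one.  This is the standard discreteness effect of max-statistic
permutation tests — error control holds (the procedure is never
anticonservative); it simply has reduced power at very small mask ×
threshold combinations.

Sphere ROI masks (e.g. a brainstem mask built from two 5-mm spheres, or
3-mm peak-extraction spheres) use voxel-center Euclidean distance in world
mm with inclusive boundary.  On a 2-mm isotropic grid a 5-mm sphere
centered on a voxel center contains exactly 81 voxels and a 3-mm sphere 19
(1 + 6 face + 12 edge neighbours, since an edge neighbour lies 2√2 ≈ 2.83 mm
away); both counts are verified against independent enumeration.

## Dynamic connectivity: ARMA(1,1) + GARCH(1,1) + DCC(1,1)

Per ROI, the band-limited (0.01–0.198 Hz) sphere-mean series is modelled in
two stages, then pairs of standardised residuals enter a correlation
recursion:

1. **Mean equation** xₜ = c + φxₜ₋₁ + εₜ + θεₜ₋₁, estimated by Gaussian
   conditional MLE (innovation recursion with ε₀ = 0, conditioning on x₀;
   equivalent to minimising the innovation sum of squares), |φ|, |θ| ≤ 0.99.
   An intercept is always included.
2. **Variance equation** σ²ₜ = ω + αε²ₜ₋₁ + βσ²ₜ₋₁ with ω > 0, α, β ≥ 0,
   α + β < 1, estimated by quasi-MLE maximising Σ −½(log σ²ₜ + ε²ₜ/σ²ₜ).
   The recursion is initialised at the sample variance of the innovations —
   stated explicitly because small-T results are sensitive to it.
   Standardised residuals are εₜ/σₜ.
3. **Correlation recursion** Qₜ = (1−a−b)Q̄ + a εₜ₋₁ε′ₜ₋₁ + b Qₜ₋₁ with
   Q₀ = Q̄, Rₜ = Qₜ,₁₂/√(Qₜ,₁₁Qₜ,₂₂); Q̄ is the sample correlation matrix of
   the standardised residuals (correlation targeting).  (a, b) are
   estimated by the second-stage correlation quasi-likelihood.  An
   exponentially-weighted moving-average mode (fixed decay λ, default 0.94)
   is provided as the a+b → 1, vanishing-Q̄-weight limit of the same
   recursion, for users who want the smoother-style estimate rather than a
   fitted model; the fitted DCC(1,1) is the default because it nests the
   EWMA and returns interpretable persistence parameters.

dFC **strength** and **variability** are the time mean and sample SD of Rₜ;
groups are compared by pooled-variance unpaired t tests per ROI pair and
measure.

Optimisation details (all stages): bounded quasi-Newton / Nelder–Mead on
transformed parameters — log for ω, logistic for α, β and a, b with the
stationarity sum constraint enforced by reparameterisation (sum < 0.999) —
with three starting points; the best likelihood wins.  Unconstrained
parameters are clipped to ±35 before exponentiation so optimizer
excursions cannot overflow.  Non-convergence of the GARCH stage is flagged,
not raised: the fallback standardises by the constant sample SD and marks
the fit, so downstream group tests can exclude flagged subjects.  A
residual pair whose sample correlation is 1 up to round-off (e.g. identical
inputs) is detected before optimisation — the correlation likelihood is
singular there — and returns the pinned constant path Rₜ = ±1 with a
boundary flag.  The Rₜ path is clipped to [−1, 1] (the recursion keeps it
there up to round-off).

Verified behaviour (test suite): hand-computed σ² paths match exactly;
i.i.d. input yields α ≈ 0 and unit-variance standardised residuals; on 50
pairs simulated from the exact generative recursions at T = 2000 with
(a, b) = (0.05, 0.90), ρ̄ = 0.4, the median |â+b̂ − 0.95| ≤ 0.05, the mean
fitted path is within 0.05 of ρ̄, and the fitted path correlates positively
with the true path in ≥ 90% of runs; at T = 235 (study scale) fits complete
without failure on ≥ 95% of draws.

## Cross-correlation

Normalised cross-correlation at lags −K..K with full-series means and SDs
in the denominator, so lag 0 equals the Pearson correlation; the
approximate 95% white-noise bound is ±1.96/√T.

## Clinical module

- **P.A.I.N.S.**: 220 craniofacial cells with integer intensities 0–3;
  cumulative score 0–660; percentage = 100·score/660.  The 3D head-grid
  geometry is not reproduced — cells are an ordered vector.  Scoring is
  strictly monotone in every cell.
- **Spearman**: Pearson correlation of mid-ranks (average ranks on ties);
  two-tailed p by the t approximation t = ρ√((n−2)/(1−ρ²)), adequate at
  the n ≈ 14–20 of typical clinical subsamples.  An exact permutation p
  (full n! enumeration) is available for small n (default cap n ≤ 8, where
  enumeration is instant; the cap is an argument).
- **BH-FDR**: step-up procedure with adjusted values
  q₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j capped at 1; the rejection set from the
  threshold form equals {q ≤ q_level} (property-tested).  The family of
  correlations corrected together is declared by the caller, not inferred.
- **Demographics**: pooled two-sample t (Welch optional) for continuous
  variables; Pearson chi-square without continuity correction (optional)
  for categorical ones; empty contingency cells are reported as errors.

## Synthetic data: what it emulates and what it does not

The generator's defaults emulate the motivating study's acquisition: 26 +
20 subjects, 240 volumes at TR = 2 s, 2-mm isotropic voxels (on a reduced
grid; the full MNI field of view is unnecessary for verification).  Voxel
series are white Gaussian noise FFT-limited to a configurable band
(default 0.01–0.25 Hz — broadband up to Nyquist minus drift, so the
preprocessing band-pass has something to remove) and rescaled to sample SD
exactly 1, making planted effects exact: group B's series inside an effect
blob are multiplied by the configured SD multiplier, so the SD map is the
exact carrier of the group difference.  Because z-standardisation is
relative to the whole mask, a planted positive blob slightly depresses z
elsewhere in group B — a real property of the statistic, visible in
synthetic runs as weak opposite-signed secondary clusters.

Motion traces are Gaussian random walks with increment SD
motion_scale/√T; rotation increments are additionally scaled by 1/50 so
their arc-length contribution to framewise displacement matches the
translations (motion_scale = 0.18 gives mean FD ≈ 0.05 mm at T = 240,
matching the motion levels typical of compliant adult cohorts).  Nuisance
tables carry two band-limited noise series (CSF, WM).  Clinical tables tie
the pain-score percentage to a covariate through a Gaussian copula with
latent Pearson r = 2 sin(πρ/6), so the population Spearman correlation
equals the requested target and monotone mapping to the 0–100% reporting
scale preserves it.

One global integer seed; per-subject streams are derived from
(seed, subject index), so cohorts are bit-reproducible and individual
subjects are stable under resizing the other group.

Deliberately **not** emulated: hemodynamic response shape, spatial
autocorrelation of real BOLD noise, physiological (cardiac/respiratory)
waveforms, scanner drift/artifacts, and any empirical SD distribution of
the motivating study (which is not publicly characterised — synthetic noise
levels are conventional).  Consequently, passing tests demonstrate that the
estimators recover what the generative model plants and that error rates
are controlled under exchangeability; they do not certify performance on
real data with structured noise.

## Known limitations

- The whole-brain cluster correction of the motivating analysis used
  unnamed software with a parametric null; this package's permutation null
  is procedurally faithful but not numerically equivalent, and the original
  cohort is not deposited, so published t values and clinical correlations
  are not reproducible here.  Verification is therefore property-based.
- DCC estimation at T ≈ 235 is noisy; persistence estimates individually
  scatter widely around the truth even though the recovered paths track the
  true dynamics.  Group comparisons of strength/variability inherit that
  noise.
- The cluster-extent procedure is conservative on very small masks with
  strict height thresholds (see calibration note above).
- The ideal FFT band-pass assumes the series is well represented by its
  DFT; for runs with large unremoved drifts the detrending step must come
  first (the default order does this).
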