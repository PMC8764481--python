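# Methods

## The pipeline and its assumptions

The package treats disease severity as a pseudo-temporal axis over
cross-sectional subjects. Its central assumptions, inherited from the CaSCN
family of methods, are:

1. the clinical severity score orders patients approximately along the true
   progression axis;
2. regional gray-matter loss is (locally) monotone in progression, so a
   region whose loss lags the seed's in severity rank can be read as
   "downstream" of the seed;
3. the voxel-wise statistic fields are smooth enough for Gaussian
   random-field (GRF) cluster inference.

None of these is guaranteed in real data; the synthetic generator makes all
three true by construction so that the machinery can be validated, and the
limitations section below states what that does and does not establish.

## Group morphometry (VBM)

Per voxel: OLS of GM density on `[1, group, sex, age, TIV]`. The default
contrast is one-tailed atrophy (HC > PD), matching the conventional
one-tailed height threshold z > 3.09 = Φ⁻¹(.999) for voxel p < .001; the
reverse tail is a flag. t maps are Gaussianized with a tail-stable
t→z probability transform. Stage-specific contrasts compare each patient
subgroup with all controls, using the shipped staging schemes:

- Hoehn–Yahr: Stage I = 1–2, Stage II = 2.5–3 (the modified scale's 2.5 is
  counted as Stage II), Stage III = 4–5;
- UPDRS-III tertiles: 1–23 / 24–40 / 41–74;
- MoCA dementia screen: score < 21.

Cohort QC follows the pairwise-homogeneity convention: a subject's score is
the mean Pearson correlation of their map with every other map, and
subjects below mean − 2 SD are flagged. Demographic tables use the Pearson
chi-square without continuity correction for sex (the uncorrected statistic
is the convention this package reproduces exactly) and two-sided
Mann–Whitney tests for continuous scores (exact enumeration up to n = 20
per group, tie-corrected normal approximation beyond), with row-wise
available-case handling of missing cognitive scores.

## Smoothness and GRF cluster correction

Smoothness is estimated from residual images: along each axis the pooled
ratio of first-difference power to field power estimates 2(1 − ρ) for the
lag-one autocorrelation ρ. For ρ ≥ 0.5 the Gaussian autocorrelation model
is inverted exactly (σ² = Δ²/(−4 ln ρ), FWHM = √(8 ln 2)·σ). The cruder
derivative-variance form FWHM = √(4 ln 2/λ) is kept as the fallback for
rough data (it floors at ~1.18 voxels on white noise, where an ACF fit is
meaningless). The inversion matters: the raw form overestimates a 4 mm
kernel on a 1.5 mm grid by ~5%, and the cluster test's family-wise error is
steeply sensitive to the assumed FWHM (about −0.008 FWE per +0.1 mm around
these conditions, by our Monte-Carlo).

Cluster p-values use the standard stationary-field formulas: expected
cluster count E[m] = Σ_d R_d ρ_d(u) with Euler-characteristic densities
ρ_d and resel counts R_d of an equivalent cuboid (bounding-box aspect,
exact resel volume); expected cluster size E[n] = R₃·Φ(−u)/E[m]; extent
tail P(n ≥ k) = exp(−β k^{2/3}) with β = (Γ(5/2)/E[n])^{2/3};
p_FWE = 1 − exp(−E[m]·P(n ≥ k)). Connectivity defaults to 18 neighbours
(configurable 6/18/26). Nonstationarity correction is out of scope.

Monte-Carlo calibration (3000 stationary null fields, 32³ voxels at 1.5 mm,
4 mm FWHM, z > 3.09, cluster α = .05; `cascnet.experiments.grf_fwe_rate`)
gives an empirical family-wise rate of ≈ 0.03 — mildly conservative, as
expected for extent-based RFT at ~2.7-voxel smoothness on a lattice.
We run 3000 rather than a few hundred fields because the experiment is
cheap and the binomial noise would otherwise dominate the comparison.

For CaSCN maps, which have no voxel-wise model residuals, smoothness is
estimated from covariate-residualized *control* maps. Patient residuals
are unsuitable: they contain the severity-driven atrophy pattern, which is
structured at region scale and inflates the estimated FWHM (we measured
7.4 mm against a true 4 mm null smoothness), distorting cluster inference.

## Severity sequencing and signed-path-coefficient GC

Patients are sorted ascending by H&Y or UPDRS-III with a deterministic
tie-break chain (the other scale, then disease duration, then subject id),
so the ordering is invariant to input row order. Controls never enter the
sequencing. For seed series x and target series y (both residualized
against `[1, sex, age, TIV]` before the lag regression, keeping the GC
design identical at every voxel — exogenous-covariate variants can be built
from `regress_covariates` directly),

    y_t = c + Σ_{i≤p} a_i y_{t−i} + Σ_{i≤p} b_i x_{t−i} + e_t,

and the signed path coefficient is b₁ at the default order p = 1 (Σ b_i for
p > 1). The order-1 default reflects the ~84-point series length: each
additional lag costs 2 parameters and the identifiable signal lives in the
lag-1 neighbourhood once subjects are severity-sorted.

The voxel-wise map z-scores the coefficients across the analysis mask
(mean 0, SD 1 to 1e−6, excluding voxels flagged for rank-deficient lag
designs) and then reuses the VBM's GRF machinery; only the seed→voxel
direction is computed by default. The conjunction of the two orderings'
surviving masks is a voxel-wise logical AND.

At the ROI level, each ordered pair's coefficient is converted to a z
deviate through the probability transform of its regression t statistic
(the same Gaussianization the voxel pipeline uses for t maps) and tested
two-sided at α = .05, uncorrected. We deliberately do *not* standardize raw
coefficients across the pair population for inference (that convention
remains available via `roiwise_cascn(method="zscore")`): with few ROIs the
empirical z is bounded by the pair count, and under permutation the
atrophied-region series are near-collinear, making the pair population a
heavy-tailed correlated mixture whose empirical standardization is
miscalibrated (measured null edge rates of 0.013–0.088 against the nominal
0.05; the per-pair transform measures 0.048 pooled over ten cohorts).

## The synthetic cohort

The phantom is geometric: an ellipsoidal "brain" (semi-axes 28×34×28 mm) of
GM density 0.5 containing six 6 mm-radius ellipsoidal regions of density
0.75 — a seed at (−17, −3, 20) mm, three downstream targets, two decoys.
Defaults encode the study conditions the pipeline is sized for: 84
patients, 70 controls, 40×48×40 grid of 1.5 mm voxels, propagation lags
{3, 5, 8} severity ranks at gain 0.3 (fractional density loss per unit
severity), white noise SD 0.02 followed by 4 mm FWHM Gaussian smoothing (so
random-field smoothness assumptions hold downstream).

Latent severity is a sorted sample of Uniform(0, 1) order statistics; the
patient ranked r loses `gain · s_(r)` of seed density and
`gain · s_(r−lag)` of each target's density (zero before the lag elapses).
The irregular spacings of the order statistics matter: they give the
severity-sequenced seed series genuine innovations that reappear `lag`
positions later in the target series. A perfectly affine severity ramp
would make the seed and target lag regressors collinear and the coefficient
unidentifiable — lagged-prediction analysis on sequenced cross-sections
requires between-patient severity irregularity.

Both clinical scales are monotone noisy transforms of the latent severity
with configurable latent correlation (default 0.9), discretized to their
conventional ranges: H&Y onto the modified 7-point scale with a marginal
matching stage sizes 32/41/11 of 84, UPDRS-III through a Gaussian quantile
map (mean 33, SD 17, clipped to 1–74). The 0.9 default is an
identifiability requirement, not a free dial: sequencing can only resolve
propagation lags of 3–8 ranks if scale noise displaces ranks by less than
the lag, which at n = 84 needs latent consistency ≈ 0.9 or better (observed
inter-scale Pearson r ≈ 0.86 after discretization). Age (≈N(53, 10.5) PD /
N(52.6, 10.9) HC), sex (male fraction 48/84 and 38/70), and TIV
(≈N(1450, 130) ml) scale GM multiplicatively (defaults −0.3%/year of age,
−1% male, +0.01%/ml TIV), so covariate regression has real work to do;
MMSE/MoCA decline with severity and carry available-case missingness.

What the generator does **not** emulate: cortical geometry and anatomy,
scanner artifacts and site effects, registration/segmentation error,
nonstationary smoothness, region-specific biological variability beyond the
covariate effects, and any within-subject longitudinal change. Passing
tests therefore demonstrate that the machinery recovers a known
severity-lagged propagation structure under its own assumptions — not that
those assumptions hold in patient data.

## Numerical choices and degenerate inputs

- Sphere ROIs use closed-ball voxel-center membership; world coordinates
  follow the affine with no implicit flips; negative densities are clamped
  to zero on load (logged) or rejected per flag.
- Rank-deficient designs (GLM, covariate regression, GC lag embedding) are
  rejected with errors; voxel-wise GC flags degenerate voxels via the
  eigenvalue spectrum of the normalized normal matrix and excludes them
  from the map z-scoring; a near-constant coefficient map (relative spread
  ≤ 1e−6) is marked degenerate rather than z-scored.
- Voxels a GLM fits exactly (zero residual variance) get t = 0 rather than
  0/0.
- An empty supra-threshold set yields an empty cluster table, not an error;
  an empty conjunction skips ROI extraction with a warning.
- All randomness flows from one integer seed per generated cohort or
  experiment; `demo()` twice with the same seed is byte-identical.

## Problem sizes of the standing experiments

The validation studies (`cascnet.experiments`) use: 1000 random series of
length 84 for the estimator/oracle agreement; 3000 null 32³ fields for the
FWE calibration; 20 cohorts for end-to-end recovery (success = at least 2
of 3 true regions hit and no decoy); and 10 cohorts × 50 shuffles (30
ordered pairs each) for the permutation negative control, pooled because
the pair statistics within one cohort are correlated and a single cohort's
density estimate is noisier than its binomial width suggests. These sizes
are chosen so each estimate's sampling noise is small relative to the
property being checked while a full run stays within a few minutes on one
CPU.

## Known limitations

- Pseudo-time is not time: even perfect recovery on sequenced
  cross-sections cannot distinguish propagation from region-specific onset
  thresholds on a shared progression axis.
- Bivariate GC cannot distinguish direct from induced lag relations: if the
  seed drives A at lag 3 and B at lag 8, then B lags A by 5 and a
  sufficiently powered analysis will (correctly, at the sequence level)
  also flag A→B.
- Per-edge ROI-level power is modest at n = 84 under realistic covariate
  effects and scale noise (~0.4–0.55 per true edge in our fixtures); the
  voxel-level conjunction is the robust readout, the ROI network the
  descriptive one.
- GRF cluster inference is mildly conservative at ~2.7-voxel smoothness and
  assumes stationarity.
- The map-level z-scoring of GC coefficients is a normalization, not an
  analytic null; inference rests on the GRF correction of the standardized
  map, which is the method family's convention.
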