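# Methods

## The generative model

Each of the six sex × race strata is modeled independently. The modeled
vector is the 146-dimensional concatenation of the 145 ROI volumes (mm³)
and age (years), in the package's dictionary order (ROIs first, age
last). Within a stratum the vector is z-scored feature-wise with the
stratum's sample mean and standard deviation (ddof = 1); both are
retained so synthetic draws can be mapped back to native units. The
standardized density is a product-Gaussian KDE with one scalar bandwidth
*h*; log-densities are evaluated exactly by log-sum-exp over squared
Euclidean distances (blocked over query rows to bound memory).

**Sampling.** A draw is a uniformly chosen training row plus independent
N(0, h²) noise in every dimension, back-transformed to native units.
Draws with any non-positive ROI volume are rejected and redrawn (the
count is logged); age is never truncated. Rejection keeps the support
biologically valid while leaving the closed-form mixture moments
essentially exact, because the rejection rate at default scales is far
below 1%.

**Analytic identities used as oracles.** In standardized space the
sampler's population covariance is S + h²I (S = training covariance,
ddof = 0), so any pairwise correlation ρ attenuates by 1/(1 + h²) —
a factor of ≈ 0.671 at h = 0.7. The test suite verifies both at 10⁵
draws, and verifies the log-density against an independent double-loop
summation and against an external KDE implementation.

**Bandwidth selection.** Grid search over [0.5, 1.0] in steps of 0.05.
The criterion is the mean held-out log-likelihood under 5-fold
cross-validation with a seeded fold assignment; exact ties resolve to
the larger bandwidth (smoother, less overfit). In-sample likelihood is
not a usable criterion — self-point kernels make it strictly decreasing
in *h* on this interval, which would always select the grid's lower
edge; the suite asserts that monotonicity as a guard. The grid is
confined to [0.5, 1] because the standardized features are approximately
N(0, 1): well below 0.5 the mixture collapses onto training points,
while near 1 the kernel noise (variance h² added to unit-variance
features) washes out the age–ROI correlation structure.

## The cohort simulator

Real normative tables of this kind are access-restricted, so the package
ships a parametric simulator whose parameters are known exactly; it is
the ground truth against which every pipeline stage is validated. Per
subject in stratum s:

* age ~ Uniform(22, 90) — maximal coverage for age-trend checks;
* ROI_j = intercept_{j,s} + slope_j·age + quad_j·age² + Σ_k λ_{jk} f_k + ε_j,
  with f_k ~ N(0,1) shared across ROIs (latent factors inducing cross-ROI
  correlation) and ε_j ~ N(0, noise_sd_j).

Default scales (drawn once from a fixed stream, identical across
sessions): intercepts span ~400–20,000 mm³ by tissue class; gray/white
regions lose 0.1–0.4% (gray) and 0.05–0.2% (white) of baseline per year
while ventricles expand 0.8–1.5%/year; male offsets are +5–12% of
baseline and race offsets ~±2%; five latent factors load ~4% of baseline
each; residual noise is 6% of baseline for parenchyma and 35% for
ventricles. The ventricular noise level matters: ventricles are by far
the most inter-individually variable structures in real cohorts, and if
they are simulated with parenchymal noise levels a single ventricle
becomes a near-noiseless age readout — brain-age MAE drops to ~2 years
and the predictor ignores the rest of the brain, which makes every
atrophy-driven downstream experiment degenerate. With the default
scales, brain-age MAE on held-out controls is ~5–6 years, in the range
typical of volumetric brain-age models.

**Disease groups.** MCI/AD subjects carry a half-normal severity
variable (scale 1 for MCI, 2 for AD, so AD severities are stochastically
larger). Atrophy is modeled as accelerated aging: every gray- and
white-matter ROI loses 5 × |slope_j| mm³ per severity unit, i.e. one
severity unit costs five years' worth of normal volume loss across the
parenchyma. Cognition = clamp(30 − 4·severity + N(0, 1.5), 0, 30),
mimicking MMSE bounds. Disease ages default to the same uniform range
as controls so case/control contrasts are age-matched by construction;
an override exists for older disease cohorts. Positivity is preserved
by clipping at an infinitesimal floor after atrophy (relevant only in
pathological configurations).

**What the simulator does not emulate:** site/scanner effects (assumed
harmonized upstream), longitudinal trajectories, non-Gaussian residuals,
heavy-tailed or skewed volume distributions, age-dependent variance, and
any calibration of the covariance structure to a specific consortium.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and internally consistent under a realistic Gaussian-factor
cohort law — not that real data of any particular study would yield the
same metric levels.

## Fidelity battery

* **Univariate:** per ROI, OLS of volume on {intercept, group indicator,
  age}; two-sided t-test (n − 3 df) on the group coefficient; the count
  of significant ROIs uses the Bonferroni threshold 0.05/145 ≈ 3.45e-4.
  All ROIs share one design matrix, so the battery is a single
  vectorized normal-equations solve; tests verify it against an
  independent OLS implementation to 1e-8 and check family-wise error
  calibration over 200 null replicates.
* **Discriminator:** linear-kernel SVM (C = 1), features standardized
  within training folds, stratified 5-fold CV, AUC from continuous
  decision scores. Age is excluded from the features by default (the
  groups are age-matched by construction; a flag includes it). Rows are
  canonically reordered before fold assignment so the result is
  invariant to input row order. A linear discriminator cannot exploit
  the variance inflation (factor 1 + h²) that KDE smoothing adds,
  because the class means coincide — this is why the null calibration
  lands near 0.5 even for real-vs-synthetic contrasts.
* **Covariate prediction:** gradient-boosted trees with fixed settings
  (300 trees, depth 4, learning rate 0.1, single thread, seeded). Race
  is 3-class with macro one-vs-rest AUC. The IND/OOD wrapper evaluates
  both sources on identical held-out real folds (5-fold).

## Downstream experiments

* **Augmentation:** per repeat, the real CN pool is split into a
  training pool (sized to the largest scheme) and a real-only test set;
  cases split 50/50. Each scheme trains the same linear SVM as the
  discriminator (internal consistency) on R real + S synthetic controls
  plus the training cases. Synthetic rows never enter test sets.
* **Brain age:** boosted-tree age regressor on controls. The Cole
  correction coefficients (α, β) are estimated by OLS of predicted on
  chronological age *within the training controls using out-of-fold
  predictions* (5-fold). In-sample predictions of a boosted tree are
  overfit (slope → 1), which would leave a residual age trend in
  held-out corrected gaps; out-of-fold fitting is the standard robust
  variant and the package's definition. Corrected gap =
  (pred − β)/α − age. MCI and AD are pooled for the gap–cognition
  correlation (separate groups available by filtering the input).

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen so
each statistical check retains its power: 250 subjects per stratum for
the IND/OOD and augmentation worlds, 2,000 training + 2,000 held-out
controls for the bias-correction check, 10⁵ draws for moment
identities, 200 replicates (20 ROIs, 300 rows per arm) for family-wise
error calibration, and 10 sampling seeds for the discriminator null.
Degenerate inputs raise informative errors: single-row strata, constant
features (named in the message), empty bandwidth grids, α = 0 bias
corrections, zero-variance correlation inputs. Serialization stores the
standardized training matrix, bandwidth, μ, σ and feature names in a
versioned JSON container; a reloaded model reproduces log-densities to
1e-12.

## Known limitations

KDE sampling memorizes training rows plus noise: with very small
training strata, synthetic rows cluster near real subjects, which is a
privacy consideration the package does not quantify. The single scalar
bandwidth trades off per-feature adaptivity for the robustness of a
one-parameter search; heavily skewed features would benefit from a
transform before fitting. The correlation attenuation by 1/(1 + h²) is
intrinsic to the method — downstream models trained on synthetic data
inherit slightly weakened feature–covariate couplings (visible as the
OOD-vs-IND gap in the covariate-prediction metrics).
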