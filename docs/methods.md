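# Methods

This note records the modeling choices behind `neonorm`, the parameters
that matter, what the synthetic cohorts do and do not emulate, and the
numerical conventions.

## Segmentation taxonomy and denominators

The unit of input is a per-subject table of 21 segment volumes in cm³:
six lobar grey-matter and six lobar white-matter segments (frontal,
temporal, parietal, occipital, insula, cingulate), cerebellum, brainstem,
caudate, lentiform and thalamic nuclei, hippocampus, amygdala, plus the two
CSF compartments (extra-cerebral CSF, which includes the third and fourth
ventricles in the source segmentation; and the lateral ventricles, which
include the cavum septum pellucidum when present).  An optional
`unlabeled_intracranial` segment (default 0) represents intracranial tissue
the segmentation left unassigned.

Aggregates are pure sums and therefore exact: TTV is the 19 tissue segments
plus the unlabeled share; TBV adds the lateral ventricles; ICV adds eCSF.
Composites follow the membership lists of the source taxonomy, including
two conventions that are easy to get wrong: total deep GM is caudate +
lentiform + thalamus + unlabeled (hippocampus and amygdala are counted in
TTV but belong to no composite), and the basal ganglia are caudate +
lentiform only.  Relative volumes divide tissue measures by TTV, lateral
ventricles by TBV and eCSF by ICV.  Hemispheres are not distinguished;
volumes are stored as floats and reported to 3 decimals (cm³) in the
absolute CSV outputs.

## Normative model

Per measure, a GP regression over three covariates: sex (female = 0,
male = 1), PMA at scan and age from birth, all standardized on the training
controls.  The kernel is

    σ_f² · RBF(per-dimension length scales) + σ_l² · linear + σ_n² · I

— a smooth local component for nonlinearity in the growth curve, a linear
component for the monotone trend, and independent Gaussian noise.  The
linear algebra and hyperparameter optimization are delegated to
scikit-learn's `GaussianProcessRegressor` (L-BFGS on the marginal
likelihood, 5 restarts by default from seeded draws over the log-bounds;
ties broken by best likelihood).  A 1e-8 jitter is added to the kernel
diagonal for Cholesky stability.  Fits require at least 30 controls and a
non-degenerate (non-constant) target; both guards are arguments so small
closed-form examples remain constructible.

Two deliberate conventions:

- **The predictive SD includes the noise variance.**  Deviation z-scores
  divide by the full predictive SD, so held-out controls have unit-SD
  z-scores.  Excluding the noise term would shrink the denominator and
  inflate every z.
- **Out-of-range prediction warns rather than fails.**  Atypical cohorts
  routinely extend a week or two beyond the control covariate range; a
  warning is logged when a subject sits more than 2 weeks outside it and
  the prediction is returned.

The target is centred and scaled internally, which makes the model
equivariant under positive rescaling of the measure: scaling all training
targets by a > 0 scales predictive means and SDs by a and leaves z-scores
unchanged (exactly so for binary-power factors, to optimizer tolerance
otherwise, since rescaling can perturb the floating-point standardization
in the last bit).  Fits are bit-reproducible for identical inputs and seed.
Model state (kernel hyperparameters, standardization constants, training
data digest) serializes to JSON and restores without refitting.

Extreme deviations use the inclusive rule |z| ≥ 2.6, the outer ~0.5% per
tail of a standard normal (Φ(−2.6) ≈ 0.0047).

## Statistical battery

- **Mann–Whitney U / Kruskal–Wallis** wrap scipy with the package's
  switching rule: exact enumeration when n·m ≤ 64 and the pooled sample is
  tie-free, otherwise the midrank normal approximation with tie-corrected
  variance and continuity correction.  A constant pooled sample returns
  p = 1 with a warning rather than an error.
- **Cliff's delta** is computed by a sort/searchsorted dominance count
  (O((n+m) log(n+m)), no n×m matrix).  Magnitude bands use half-open
  intervals with cut-points 0.148, 0.34 and 0.475, so values falling in the
  gaps of the conventional printed bands (e.g. 0.335) resolve downward and
  every |d| maps to exactly one category.  Bands act on |d|; the sign is
  reported separately.
- **BH-FDR** wraps statsmodels' step-up implementation; families are per
  report table (all measures of the absolute comparison form one family,
  the relative comparison another, each regression family its own).
- **Spearman ρ** bands use midpoint cut-points 0.195/0.395/0.595/0.795 on
  |ρ| so the banding is total.
- **LMS z-scores** use z = ((x/M)^L − 1)/(L·S), falling back to
  ln(x/M)/S for |L| < 1e-7; L, M, S interpolate linearly in age within the
  reference grid and extrapolation is refused.

## Regression toolkit

Quantile regression is solved as an exact linear program (split-variable
formulation, HiGHS), not by IRLS; the achieved check loss is therefore
never above that of any straight line, which the tests verify against a
grid-search oracle.  The AIC for median regression uses the
asymmetric-Laplace working likelihood, AIC = 2k + 2n·ln(mean check loss)
with k = 2; only differences between models on the same data are
meaningful, and a zero-loss fit returns −inf as a sentinel.

The extra sum-of-squares F-test is hierarchical: separate lines (4
parameters) vs shared slope (3) for the slope test; conditional on a shared
slope, shared slope vs single pooled line (2) for the intercept
("elevation") test.  Degenerate fits (residual SS ≈ 0 relative to the data
scale) raise.  Age regressions optionally exclude |z| > 5 outliers under a
config toggle (default off), with the exclusion logged.

WBV covariation pairs each measure with the whole-brain measure that also
serves as its relative-volume denominator: tissue segments and composites
with TTV, lateral ventricles with TBV, eCSF with ICV.  The WBV-adjusted
group median z is the median-regression intercept at WBV z = 0; the
two-group difference is tested by a seeded subject bootstrap (resample
within group, refit, two-sided percentile p), 2000 resamples by default at
the function level and 500 in the pipeline config where ~30 measures are
processed.

## Synthetic cohorts

The generator emulates the study conditions the pipeline assumes: a control
cohort with 17.5% preterm births (GA ~ N(33.5, 2.5²) truncated to
[24, 36.9]; terms ~ N(39.8, 1.2²) on [37, 42]), 49.3% female, and PMA at
scan on [31, 46] weeks — preterm neonates are scanned either soon after
birth or at term-equivalent age (an even mixture), term neonates near
41 weeks.  Each segment grows logistically in PMA,
A/(1 + exp(−r·(PMA − t₀))), with a multiplicative sex offset (males ~6%
larger by default) and heteroscedastic Gaussian noise, SD = CV·mean
(CV 8% for tissue, larger for CSF spaces), producing the fan-shaped
normative bands real data show.  Asymptotes were chosen once to give
term-age magnitudes of realistic order (TTV ≈ 500 cm³ at term; cerebellum
≈ 6% of TTV); they are configuration, not claims about any dataset.
Aggregates are computed from the generated segments by the volumes module,
so sum constraints hold by construction.  Each subject draws from
`default_rng([seed, i])`, so enlarging a cohort never reshuffles existing
subjects.

Atypical cohorts are drawn as controls and then deviated: each targeted
segment is shifted by (mean_shift + age_slope_shift·(PMA − 40))·σ(x), where
σ(x) is the fitted control model's predictive SD at that subject's
covariates.  The age-interaction term emulates a gradual deviation from the
control mean with advancing PMA, as reported for neonates with congenital
heart defects.  Shifted volumes are floored at 2% of the unshifted value —
volumes are physical quantities — which slightly truncates large negative
injections on very small early-age segments.  A truth table of injected
shifts (SD units) per subject and measure is emitted for recovery checks.
Deviations target raw segments only; aggregates move through their members.

What the generator does *not* emulate: left/right asymmetry, twin
correlation, comorbidity co-occurrence, segmentation errors, recruitment or
mortality processes, and any covariance between segments beyond what the
shared growth curves induce.  Passing tests therefore demonstrate that the
pipeline's machinery is correct and calibrated under its stated
assumptions, not that those assumptions hold for any real cohort.

## Problem sizes and tolerances

The test suite and the acceptance script scale the expensive stages to
sizes where the checked properties are already decisive: normative fits on
120–350 training controls with 1–3 optimizer restarts, calibration on 400
held-out controls, deviation recovery at the study-typical n = 25, type-I
simulations at 1000–2000 replicates, and a ~30-measure null pipeline on 200
training controls.  Statistical assertions use bands derived from the
sampling distribution at those sizes (e.g. a median of 25 unit-SD draws has
SE ≈ 0.25, hence the ±0.5 recovery band); exact oracles (enumeration,
grid search, closed forms) are asserted at 1e-9–1e-12.

## Known limitations

- No warped or heteroscedastic-likelihood GPs: the noise variance is
  homoscedastic per model even though the generator's noise scales with the
  mean.  Calibration on held-out controls remains within the tested bands
  because the fan-out over the modeled range is moderate; strongly
  heteroscedastic measures would need a transformed target.
- No centile curves beyond mean ± k·SD bands, no longitudinal modeling
  (one scan per subject), no multi-output coupling across measures.
- The intercept (elevation) test is only meaningful conditional on a
  shared slope; the pipeline reports it unconditionally and leaves the
  hierarchy to the `chosen_model` column.
- Plot rendering is deliberately out of scope; reports are CSV/JSON.
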