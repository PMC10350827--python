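# neonorm

Normative modeling of regional neonatal brain volumes, with individualized
deviation z-scores and the downstream statistical battery used in volumetric
phenotyping studies of atypical neonatal cohorts (e.g. Down syndrome, with or
without congenital heart defects).

## The problem

Regional brain volumes change rapidly between 31 and 46 weeks postmenstrual
age (PMA), and they differ by sex and by how long a neonate has been out of
the womb.  A raw volume is therefore meaningless without a reference: the
question is not "is this cerebellum small?" but "is it small *for this sex
and age*?".  `neonorm` answers that by fitting, per measure, a Gaussian
process regression (GPR) on a control cohort over three covariates — sex,
PMA at scan (weeks) and age from birth (weeks).  The GP posterior provides a
predictive mean μ(x) and predictive SD σ(x) at any covariate point, and each
individual is expressed as a deviation z-score

    z = (y − μ(x)) / σ(x)

in SD units, with |z| ≥ 2.6 flagged as an extreme deviation (the outer
~0.5% per tail of a standard normal).  σ(x) includes the observation-noise
term, so held-out controls score as approximately N(0, 1).

Models are fitted for **absolute** volumes (cm³) and **relative** volumes:
each tissue measure as a proportion of total tissue volume (TTV), the
lateral ventricles as a proportion of total brain volume (TBV = TTV +
lateral ventricles), and extra-cerebral CSF (eCSF) as a proportion of
intracranial volume (ICV = TBV + eCSF).

Downstream, the package implements the field's standard nonparametric
battery over the z-scores:

- **Group comparison** — Mann–Whitney U / Kruskal–Wallis, Cliff's delta d
  with magnitude bands (negligible < 0.148 ≤ small < 0.34 ≤ medium < 0.475
  ≤ large), Benjamini–Hochberg FDR per report table, extreme-deviation
  counts.
- **Age regression** — OLS plus quantile (τ = 0.25/0.5/0.75) regression of
  z on PMA at scan; extra sum-of-squares F-tests for slope and intercept
  (elevation) differences between groups; banded Spearman ρ; AIC for median
  regression under the asymmetric-Laplace working likelihood.
- **Whole-brain covariation** — segment z regressed on the matched
  whole-brain z (tissue↔TTV, ventricles↔TBV, eCSF↔ICV); the
  median-regression intercept at WBV z = 0 is the *WBV-adjusted* group
  median z, separating segment-specific from brain-size-mediated deviation.
- **Growth charts** — LMS (skewness/median/CV) z-scores for weight and head
  circumference against a user-supplied or synthetic reference grid.

A seeded synthetic-cohort generator (`neonorm.synthetic`) emulates the
statistical structure of a preterm-to-term control cohort and lets you
inject known per-segment deviations — including age-interaction deviations —
so every stage of the pipeline is testable without access to any real data.

## Worked example

```python
from neonorm import fit_normative, zscore, calibration_report
from neonorm import synthetic as syn

train_demo, train_segs = syn.generate_controls(syn.CohortSpec(n=400, seed=10))
model = fit_normative(train_demo, train_segs["cerebellum"], "cerebellum",
                      seed=0, n_restarts=3)

held_demo, held_segs = syn.generate_controls(syn.CohortSpec(n=200, seed=11))
rep = calibration_report(model, held_demo, held_segs["cerebellum"])

dev = syn.DeviationSpec(mean_shift={"cerebellum": -1.8})
atyp_demo, atyp_segs, truth = syn.generate_atypical(
    syn.CohortSpec(n=25, seed=12, group="atypical"), dev,
    {"cerebellum": model})
scores = zscore(model, atyp_demo, atyp_segs["cerebellum"])
```

Running this (`python examples/02_normative_zscores.py`) prints:

```
held-out controls: mean z = +0.055, SD of z = 0.978, extreme fraction = 0.020
atypical cohort (injected -1.8 SD): median z = -1.60, extreme deviations = 5/25
```

The held-out controls centre on z = 0 with unit SD — the model is
calibrated — and the cohort with a −1.8 SD cerebellar deficit injected is
recovered at a median z of −1.60 (sampling error of a median of 25 unit-SD
draws is ~0.25), with 5 of 25 subjects beyond the −2.6 extreme threshold.

The `examples/` directory has one short script per capability: cohort
simulation, normative scoring, group comparison, age regression with the
slope F-test, WBV covariation, and LMS growth-chart scoring.  A thin CLI
wraps the same pipeline for shell use:

```bash
neonorm simulate --n-controls 500 --n-atypical 25 --outdir cohort
neonorm all --demographics cohort/demographics.csv \
            --segments cohort/segments.csv --outdir reports
```

## Input schemas

- **demographics CSV** — `subject_id, sex (female/male), ga_birth, pma_scan,
  age_from_birth, group (control/atypical), chd` plus optional
  `weight_birth, weight_scan, hc_birth, hc_scan`.
- **segment CSV** — `subject_id` plus one column per segment: the six lobar
  GM and six lobar WM segments (`frontal_gm`, `frontal_wm`, …, using lobes
  frontal/temporal/parietal/occipital/insula/cingulate), `cerebellum`,
  `brainstem`, `caudate`, `lentiform`, `thalamus`, `hippocampus`,
  `amygdala`, `ecsf`, `lateral_ventricles`, and optionally
  `unlabeled_intracranial` (defaults to 0).

Aggregates (TTV/TBV/ICV, total cortical GM, total WM, total deep GM, lobar
totals, posterior fossa, basal ganglia) are always derived from the segment
columns, never supplied.  Two conventions worth noting: TTV counts the
hippocampus and amygdala (they are tissue segments) while *total deep GM*
does not — deep GM comprises the caudate, lentiform and thalamic nuclei plus
any unlabeled intracranial tissue; and the WBV-adjusted median z is defined
as the group median regression evaluated at WBV z = 0, i.e. the segment
deviation expected for a typically sized brain.

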