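"""Synthetic preterm-to-term neonatal cohorts with known ground truth.

The generator emulates the statistical structure the normative pipeline
assumes: a control cohort of ~500 neonates (about 17.5% preterm, ~49% female,
postmenstrual age at scan 31-46 weeks) whose regional brain volumes follow
monotone logistic growth in PMA with a multiplicative sex offset and
heteroscedastic noise proportional to the mean, and an atypical cohort in
which selected segments are shifted by a configurable number of predictive
SDs — optionally with an age-interaction term that makes the deviation grow
with PMA, emulating the decline observed with congenital heart defects.

Aggregate volumes are always recomputed from the generated segments by the
volumes module, so sum constraints hold by construction.  Each subject draws
from its own seeded substream: enlarging a cohort never reshuffles the
subjects already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import volumes as vol

__all__ = [
    "GrowthParams",
    "CohortSpec",
    "DeviationSpec",
    "DEFAULT_GROWTH",
    "generate_controls",
    "generate_atypical",
    "synthetic_lms_reference",
]


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth curve for one segment.

    mean(pma, sex) = asymptote / (1 + exp(-rate * (pma - inflection)))
                     * (1 + sex_offset/2 if male else 1 - sex_offset/2)

    with observation SD = cv * mean (heteroscedastic, fan-shaped bands).
    """

    asymptote: float      # cm^3, plateau volume
    rate: float           # per week
    inflection: float     # weeks PMA
    sex_offset: float = 0.06   # fractional male-female difference
    cv: float = 0.08           # noise coefficient of variation

    def mean(self, pma, male):
        base = self.asymptote / (1.0 + np.exp(-self.rate * (np.asarray(pma) - self.inflection)))
        return base * (1.0 + (np.asarray(male) - 0.5) * self.sex_offset)


def _lobar(gm: float, wm: float) -> dict[str, GrowthParams]:
    return {"gm": GrowthParams(gm, 0.28, 38.5), "wm": GrowthParams(wm, 0.20, 35.5)}


def _default_growth() -> dict[str, GrowthParams]:
    lobes = {
        "frontal": (110.0, 95.0),
        "temporal": (65.0, 52.0),
        "parietal": (75.0, 65.0),
        "occipital": (45.0, 34.0),
        "insula": (11.0, 12.0),
        "cingulate": (15.0, 16.0),
    }
    g: dict[str, GrowthParams] = {}
    for lobe, (gm, wm) in lobes.items():
        for tissue, params in _lobar(gm, wm).items():
            g[f"{lobe}_{tissue}"] = params
    g.update(
        cerebellum=GrowthParams(48.0, 0.35, 40.0),
        brainstem=GrowthParams(8.5, 0.15, 33.0),
        caudate=GrowthParams(7.5, 0.18, 34.0),
        lentiform=GrowthParams(10.5, 0.18, 34.0),
        thalamus=GrowthParams(13.5, 0.18, 34.0),
        hippocampus=GrowthParams(4.0, 0.20, 35.0),
        amygdala=GrowthParams(2.4, 0.20, 35.0),
        ecsf=GrowthParams(120.0, 0.12, 36.0, sex_offset=0.05, cv=0.18),
        lateral_ventricles=GrowthParams(9.0, 0.10, 34.0, sex_offset=0.05, cv=0.25),
    )
    return g


DEFAULT_GROWTH: dict[str, GrowthParams] = _default_growth()


@dataclass(frozen=True)
class CohortSpec:
    """Population-level parameters of a simulated cohort."""

    n: int = 500
    seed: int = 0
    preterm_fraction: float = 0.175
    pma_range: tuple[float, float] = (31.0, 46.0)
    sex_ratio_female: float = 0.493
    chd_fraction: float = 0.0
    group: str = "control"
    growth: dict[str, GrowthParams] = field(default_factory=_default_growth)

    def __post_init__(self):
        for name, p in [("preterm_fraction", self.preterm_fraction),
                        ("sex_ratio_female", self.sex_ratio_female),
                        ("chd_fraction", self.chd_fraction)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not self.pma_range[0] < self.pma_range[1]:
            raise ValueError("pma_range must be increasing")
        for seg, g in self.growth.items():
            if g.asymptote <= 0 or g.cv <= 0:
                raise ValueError(f"growth parameters for {seg!r} must be positive")


@dataclass(frozen=True)
class DeviationSpec:
    """Ground-truth deviations to inject into an atypical cohort.

    ``mean_shift`` is in predictive-SD units; ``age_slope_shift`` is in SD per
    week of PMA, applied relative to 40 weeks so the deviation grows with age.
    """

    mean_shift: dict[str, float] = field(default_factory=dict)
    age_slope_shift: dict[str, float] = field(default_factory=dict)

    def measures(self) -> set[str]:
        return set(self.mean_shift) | set(self.age_slope_shift)


# term medians ~3.4 kg and ~35 cm head circumference at 40 weeks
_ANTHRO_CURVES = {
    "weight": GrowthParams(5.2, 0.20, 37.0, sex_offset=0.07, cv=0.11),
    "hc": GrowthParams(39.0, 0.12, 22.0, sex_offset=0.03, cv=0.03),
}


def _truncnorm(rng, loc, scale, lo, hi):
    """One truncated normal draw by rejection (bounded; falls back to clip)."""
    for _ in range(200):
        x = rng.normal(loc, scale)
        if lo <= x <= hi:
            return x
    return float(np.clip(rng.normal(loc, scale), lo, hi))


def _draw_subject(spec: CohortSpec, i: int):
    rng = np.random.default_rng([spec.seed, i])
    female = rng.random() < spec.sex_ratio_female
    preterm = rng.random() < spec.preterm_fraction
    if preterm:
        ga = _truncnorm(rng, 33.5, 2.5, 24.0, 36.9)
    else:
        ga = _truncnorm(rng, 39.8, 1.2, 37.0, 42.0)
    lo, hi = spec.pma_range
    # preterm neonates are scanned either soon after birth or at
    # term-equivalent age; term neonates shortly after birth
    if preterm and rng.random() < 0.5:
        pma = _truncnorm(rng, ga + 2.0, 1.5, max(lo, ga + 0.3), hi)
    else:
        pma = _truncnorm(rng, 40.8, 2.2, max(lo, ga + 0.3), hi)
    chd = rng.random() < spec.chd_fraction
    # anthropometrics: crude logistic growth, used only for LMS demonstrations
    wt_curve = _ANTHRO_CURVES["weight"]
    hc_curve = _ANTHRO_CURVES["hc"]
    male = 0.0 if female else 1.0
    record = {
        "sex": "female" if female else "male",
        "ga_birth": round(ga, 2),
        "pma_scan": round(pma, 2),
        "group": spec.group,
        "chd": bool(chd),
        "weight_birth": wt_curve.mean(ga, male) * (1 + wt_curve.cv * rng.normal()),
        "weight_scan": wt_curve.mean(pma, male) * (1 + wt_curve.cv * rng.normal()),
        "hc_birth": hc_curve.mean(ga, male) * (1 + hc_curve.cv * rng.normal()),
        "hc_scan": hc_curve.mean(pma, male) * (1 + hc_curve.cv * rng.normal()),
    }
    record["age_from_birth"] = record["pma_scan"] - record["ga_birth"]
    segs = {}
    for seg in vol.REQUIRED_SEGMENTS:
        g = spec.growth[seg]
        mu = float(g.mean(record["pma_scan"], male))
        segs[seg] = mu * (1.0 + g.cv * rng.normal())
    segs["unlabeled_intracranial"] = 0.0
    return record, segs


def generate_controls(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (demographics, segment volumes).

    Both frames are indexed by ``subject_id`` (``"{group}-{i:04d}"``).
    Reproducible: the same spec (including seed) yields bit-identical output.
    """
    records, seg_rows, ids = [], [], []
    for i in range(spec.n):
        rec, segs = _draw_subject(spec, i)
        ids.append(f"{spec.group}-s{spec.seed}-{i:04d}")
        records.append(rec)
        seg_rows.append(segs)
    cols = ["sex", "ga_birth", "pma_scan", "age_from_birth", "group", "chd",
            "weight_birth", "weight_scan", "hc_birth", "hc_scan"]
    demo = pd.DataFrame(records, index=pd.Index(ids, name="subject_id"))
    demo = demo[cols] if len(demo) else pd.DataFrame(columns=cols,
                                                     index=pd.Index(ids, name="subject_id"))
    seg_cols = list(vol.REQUIRED_SEGMENTS) + ["unlabeled_intracranial"]
    segs = pd.DataFrame(seg_rows, index=demo.index, columns=seg_cols, dtype=float)
    return demo, segs


def generate_atypical(
    spec: CohortSpec,
    dev: DeviationSpec,
    control_models: dict[str, "object"],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate an atypical cohort with injected per-segment deviations.

    Subjects are drawn exactly like controls, then each deviated segment is
    shifted by ``(mean_shift + age_slope_shift * (PMA - 40)) * predicted_sd``
    where ``predicted_sd`` comes from the fitted control model for that
    segment's absolute volume at the subject's covariates.  Aggregates are
    never shifted directly; they move only through their member segments.

    Returns (demographics, segment volumes, truth table).  The truth table
    lists the injected total shift (SD units) per subject and measure.
    """
    missing = [m for m in dev.measures() if m not in control_models]
    if missing:
        raise KeyError(f"deviation measures without fitted control models: {missing}")
    bad = [m for m in dev.measures() if m not in vol.REQUIRED_SEGMENTS]
    if bad:
        raise KeyError(f"deviations can target raw segments only, got: {bad}")
    if spec.group == "control":
        spec = replace(spec, group="atypical")
    demo, segs = generate_controls(spec)
    truth_rows = []
    for measure in sorted(dev.measures()):
        model = control_models[measure]
        _, sd = model.predict(demo)
        shift_sd = (dev.mean_shift.get(measure, 0.0)
                    + dev.age_slope_shift.get(measure, 0.0) * (demo["pma_scan"] - 40.0))
        shifted = segs[measure] + shift_sd.to_numpy() * sd
        # volumes are physical: floor at a sliver of the unshifted value
        segs[measure] = np.maximum(shifted, 0.02 * segs[measure])
        for sid, s in zip(demo.index, shift_sd):
            truth_rows.append({"subject_id": sid, "measure": measure,
                               "injected_shift": float(s)})
    truth = pd.DataFrame(truth_rows, columns=["subject_id", "measure", "injected_shift"])
    return demo, segs, truth


def synthetic_lms_reference(measure: str = "weight",
                            ages=np.arange(24.0, 47.0)) -> pd.DataFrame:
    """Synthetic LMS (skewness/median/CV) reference grid for weight or head
    circumference, built from the generator's own anthropometric curves.

    This is a stand-in table with the structure of a growth-chart reference
    (columns sex, age_weeks, L, M, S); it is synthetic and carries no claim
    about any published chart.
    """
    curves = _ANTHRO_CURVES
    if measure not in curves:
        raise KeyError(f"unknown LMS measure {measure!r}; use 'weight' or 'hc'")
    g = curves[measure]
    rows = []
    for sex, male in (("female", 0.0), ("male", 1.0)):
        for age in ages:
            rows.append({"sex": sex, "age_weeks": float(age), "L": 1.0,
                         "M": float(g.mean(age, male)), "S": g.cv})
    return pd.DataFrame(rows)
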