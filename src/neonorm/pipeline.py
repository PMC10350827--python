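"""End-to-end analysis pipeline.

From a demographics CSV and a segment-volume CSV the pipeline (1) derives
aggregate and relative volumes, (2) fits per-measure GP normative models on
the control group, (3) scores every subject as a deviation z-score, and (4)
runs the downstream battery: groupwise comparisons (Mann-Whitney U, Cliff's
delta, BH-FDR, extreme-deviation counts), age-at-scan regressions with
extra sum-of-squares slope/intercept comparisons and Spearman correlations,
and the whole-brain covariation analysis with WBV-adjusted group median
z-scores.

FDR families: each report table (absolute comparison, relative comparison,
each regression family) is adjusted as one family.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import volumes as vol
from . import normative as nm
from . import stats as st
from . import regression as reg

__all__ = [
    "MAIN_MEASURES",
    "AnalysisConfig",
    "measurement_tables",
    "fit_models",
    "score_cohort",
    "run_group_comparison",
    "run_age_analysis",
    "run_covariation_analysis",
    "run_all",
]

log = logging.getLogger("neonorm")

#: whole-brain volumes and main tissue classes used by the default config
MAIN_MEASURES: tuple[str, ...] = (
    "icv", "tbv", "ttv", "total_cortical_gm", "total_deep_gm", "total_wm",
    "cerebellum", "brainstem", "ecsf", "lateral_ventricles",
)

#: WBV partner of each measure in the covariation analysis (mirrors the
#: relative-volume denominators; whole-brain measures have no partner)
WBV_PARTNER: dict[str, str] = dict(vol.RELATIVE_DENOMINATOR)


@dataclass
class AnalysisConfig:
    """Tunable parameters of a pipeline run."""

    measures_absolute: tuple[str, ...] = MAIN_MEASURES
    measures_relative: tuple[str, ...] = tuple(
        m for m in MAIN_MEASURES if m in vol.RELATIVE_DENOMINATOR)
    extreme_threshold: float = 2.6
    alpha: float = 0.05
    taus: tuple[float, ...] = (0.25, 0.5, 0.75)
    seed: int = 0
    n_restarts: int = 5
    subgroup: str = "chd"
    exclude_outliers: bool = False   # drop |z| > 5 from age regressions
    outlier_z: float = 5.0
    n_boot: int = 500

    def __post_init__(self):
        if self.extreme_threshold <= 0:
            raise ValueError("extreme_threshold must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if any(not 0 < t < 1 for t in self.taus):
            raise ValueError("taus must lie in (0, 1)")

    @classmethod
    def from_toml(cls, path) -> "AnalysisConfig":
        import tomllib
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        for key in ("measures_absolute", "measures_relative", "taus"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_toml_text(self) -> str:
        lines = []
        for key, value in asdict(self).items():
            if isinstance(value, tuple):
                items = ", ".join(json.dumps(v) for v in value)
                lines.append(f"{key} = [{items}]")
            elif isinstance(value, bool):
                lines.append(f"{key} = {'true' if value else 'false'}")
            elif isinstance(value, str):
                lines.append(f"{key} = {json.dumps(value)}")
            else:
                lines.append(f"{key} = {value}")
        return "\n".join(lines) + "\n"


def measurement_tables(segs: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Absolute (segments + aggregates) and relative measurement tables."""
    segs = vol.validate_segment_table(segs)
    absolute = pd.concat([segs, vol.compute_aggregates(segs)], axis=1)
    return {"absolute": absolute, "relative": vol.compute_relative(segs)}


def fit_models(demo: pd.DataFrame, segs: pd.DataFrame,
               config: AnalysisConfig) -> dict[tuple[str, str], nm.NormativeModel]:
    """Fit one GP normative model per (kind, measure) on control subjects."""
    controls = demo[demo["group"] == "control"]
    if controls.empty:
        raise ValueError("no control subjects to fit on")
    tables = measurement_tables(segs.loc[controls.index])
    models = {}
    for kind, measures in (("absolute", config.measures_absolute),
                           ("relative", config.measures_relative)):
        for measure in measures:
            if measure not in tables[kind].columns:
                raise KeyError(f"unknown {kind} measure {measure!r}")
            models[(kind, measure)] = nm.fit_normative(
                controls, tables[kind][measure], measure,
                seed=config.seed, n_restarts=config.n_restarts)
            log.info("fit %s/%s on n=%d controls", kind, measure, len(controls))
    return models


def score_cohort(models: dict, demo: pd.DataFrame, segs: pd.DataFrame,
                 config: AnalysisConfig) -> pd.DataFrame:
    """Deviation z-scores for every subject and configured measure.

    Returns a long DataFrame with columns ``subject_id, kind, measure,
    observed, mean, sd, z, extreme`` plus the subject's ``group``, ``sex``,
    ``pma_scan`` and subgroup flag.
    """
    tables = measurement_tables(segs.loc[demo.index])
    rows = []
    for (kind, measure), model in models.items():
        scores = nm.zscore(model, demo, tables[kind][measure],
                           threshold=config.extreme_threshold)
        scores = scores.assign(kind=kind, group=demo["group"],
                               sex=demo["sex"], pma_scan=demo["pma_scan"])
        if config.subgroup in demo.columns:
            scores[config.subgroup] = demo[config.subgroup]
        rows.append(scores.reset_index(names="subject_id"))
    return pd.concat(rows, ignore_index=True)


def _iqr_text(v: np.ndarray) -> str:
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    return f"{q2:.2f} ({q1:.2f}, {q3:.2f})"


def run_group_comparison(scores: pd.DataFrame, config: AnalysisConfig,
                         group_a: str = "atypical",
                         group_b: str = "control") -> pd.DataFrame:
    """Per-measure comparison of z-scores between two groups.

    One FDR family per ``kind`` (absolute / relative table).
    """
    frames = []
    for kind, sub in scores.groupby("kind"):
        rows = []
        for measure, ms in sub.groupby("measure", sort=False):
            za = ms.loc[ms["group"] == group_a, "z"].to_numpy()
            zb = ms.loc[ms["group"] == group_b, "z"].to_numpy()
            if za.size == 0 or zb.size == 0:
                raise ValueError(f"empty group for measure {measure!r}")
            u, p = st.mann_whitney(za, zb)
            d, cat = st.cliffs_delta(za, zb)
            rows.append({
                "kind": kind, "measure": measure,
                f"median_iqr_{group_a}": _iqr_text(za),
                f"median_iqr_{group_b}": _iqr_text(zb),
                f"median_z_{group_a}": float(np.median(za)),
                f"median_z_{group_b}": float(np.median(zb)),
                "U": u, "p_raw": p, "cliffs_delta": d, "effect_category": cat,
                f"n_extreme_{group_a}": int(ms.loc[ms["group"] == group_a, "extreme"].sum()),
                f"n_extreme_{group_b}": int(ms.loc[ms["group"] == group_b, "extreme"].sum()),
            })
        table = pd.DataFrame(rows)
        table["p_fdr"] = st.bh_fdr(table["p_raw"])
        table["significant"] = table["p_fdr"] < config.alpha
        table["stars"] = table["p_fdr"].map(st.significance_stars)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def _fit_block(x, y, taus, prefix=""):
    res = reg.ols_fit(x, y)
    row = {f"{prefix}slope": res.slope, f"{prefix}intercept": res.intercept,
           f"{prefix}r2": res.r2, f"{prefix}adj_r2": res.adj_r2,
           f"{prefix}F": res.f_statistic, f"{prefix}p": res.p_value,
           f"{prefix}n": res.n}
    for tau in taus:
        b, a = reg.quantile_fit(x, y, tau)
        row[f"{prefix}q{tau}_slope"] = b
        row[f"{prefix}q{tau}_intercept"] = a
        if tau == 0.5:
            row[f"{prefix}aic_median"] = reg.median_aic(x, y, b, a)
    return row


def _maybe_drop_outliers(ms: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    if not config.exclude_outliers:
        return ms
    mask = ms["z"].abs() > config.outlier_z
    if mask.any():
        log.info("age analysis: excluding %d outlier(s) with |z| > %g",
                 int(mask.sum()), config.outlier_z)
    return ms[~mask]


def run_age_analysis(scores: pd.DataFrame, config: AnalysisConfig,
                     pairs=(("atypical", "control"),),
                     kind: str = "absolute") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regressions of z-scores on PMA at scan per measure and group, plus
    extra sum-of-squares comparisons for each requested pair of groups.

    ``pairs`` may name cohort groups or subgroup values of the configured
    subgroup column within the atypical cohort (e.g. CHD+ vs CHD-); a pair
    entry ``("chd+", "chd-")`` selects on the subgroup flag.
    """
    sub = scores[scores["kind"] == kind]
    reg_rows, cmp_rows = [], []
    for measure, ms in sub.groupby("measure", sort=False):
        ms = _maybe_drop_outliers(ms, config)
        series = {}
        for grp, gs in ms.groupby("group"):
            series[grp] = (gs["pma_scan"].to_numpy(), gs["z"].to_numpy())
        if config.subgroup in ms.columns:
            atyp = ms[ms["group"] == "atypical"]
            flag = atyp[config.subgroup].astype(bool)
            series[f"{config.subgroup}+"] = (
                atyp.loc[flag, "pma_scan"].to_numpy(), atyp.loc[flag, "z"].to_numpy())
            series[f"{config.subgroup}-"] = (
                atyp.loc[~flag, "pma_scan"].to_numpy(), atyp.loc[~flag, "z"].to_numpy())
        for grp, (x, z) in series.items():
            if x.size < 5 or np.ptp(x) == 0:
                log.warning("age analysis: skipping %s/%s (n=%d)", measure, grp, x.size)
                continue
            row = {"measure": measure, "group": grp}
            row.update(_fit_block(x, z, config.taus))
            rho, p_rho, band = st.spearman(x, z)
            row.update({"spearman_rho": rho, "spearman_p": p_rho,
                        "spearman_band": band})
            reg_rows.append(row)
        for ga, gb in pairs:
            if ga not in series or gb not in series:
                continue
            (xa, za), (xb, zb) = series[ga], series[gb]
            if min(xa.size, xb.size) < 3:
                log.warning("slope comparison: skipping %s %s vs %s", measure, ga, gb)
                continue
            res = reg.extra_ss_ftest((xa, za), (xb, zb), measure_name=measure,
                                     alpha=config.alpha)
            cmp_rows.append({"measure": measure, "pair": f"{ga} vs {gb}",
                             "F_slope": res.f_slope, "p_slope": res.p_slope,
                             "F_intercept": res.f_intercept,
                             "p_intercept": res.p_intercept,
                             "chosen_model": res.chosen_model})
    reg_table = pd.DataFrame(reg_rows)
    if not reg_table.empty:
        reg_table["spearman_p_fdr"] = st.bh_fdr(reg_table["spearman_p"])
    cmp_table = pd.DataFrame(cmp_rows)
    if not cmp_table.empty:
        for col in ("p_slope", "p_intercept"):
            cmp_table[f"{col}_fdr"] = st.bh_fdr(cmp_table[col])
    return reg_table, cmp_table


def run_covariation_analysis(scores: pd.DataFrame, config: AnalysisConfig,
                             groups=("atypical", "control")) -> pd.DataFrame:
    """Segment z-scores regressed on their paired whole-brain z-scores.

    Each tissue segment pairs with TTV, the lateral ventricles with TBV and
    eCSF with ICV.  Reports per-group OLS and quantile fits plus the
    WBV-adjusted median z (median-regression intercept at WBV z = 0) with a
    seeded bootstrap p-value for the group difference, FDR-adjusted across
    measures.
    """
    sub = scores[scores["kind"] == "absolute"]
    wide = sub.pivot_table(index="subject_id", columns="measure", values="z")
    meta = sub.drop_duplicates("subject_id").set_index("subject_id")
    rows = []
    for measure in sub["measure"].unique():
        partner = WBV_PARTNER.get(measure)
        if partner is None:
            continue  # whole-brain measures have no covariation partner
        if partner not in wide.columns:
            raise KeyError(f"covariation needs WBV measure {partner!r} "
                           f"for {measure!r}; add it to measures_absolute")
        mask = meta["group"].isin(groups)
        zseg = wide.loc[mask.index[mask], measure].to_numpy()
        zwbv = wide.loc[mask.index[mask], partner].to_numpy()
        glabels = meta.loc[mask.index[mask], "group"].to_numpy()
        row = {"measure": measure, "wbv_measure": partner}
        for grp in groups:
            gmask = glabels == grp
            row.update(_fit_block(zwbv[gmask], zseg[gmask], config.taus,
                                  prefix=f"{grp}_"))
        adj = reg.wbv_adjusted_median(zseg, zwbv, glabels, seed=config.seed,
                                      n_boot=config.n_boot)
        for grp in groups:
            row[f"adjusted_median_{grp}"] = adj["adjusted"][grp]
        row["adjusted_difference"] = adj["difference"]
        row["p_boot"] = adj["p_boot"]
        rows.append(row)
    table = pd.DataFrame(rows)
    if not table.empty and table["p_boot"].notna().all():
        table["p_boot_fdr"] = st.bh_fdr(table["p_boot"])
    return table


def run_all(demo: pd.DataFrame, segs: pd.DataFrame, config: AnalysisConfig,
            outdir=None) -> dict:
    """Full pipeline; optionally writes every report to ``outdir`` as CSV."""
    models = fit_models(demo, segs, config)
    scores = score_cohort(models, demo, segs, config)
    comparison = run_group_comparison(scores, config)
    age_reg, age_cmp = run_age_analysis(scores, config)
    covariation = run_covariation_analysis(scores, config)
    results = {"models": models, "scores": scores, "comparison": comparison,
               "age_regression": age_reg, "age_slope_comparison": age_cmp,
               "covariation": covariation}
    if outdir is not None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tables = measurement_tables(segs)
        vol.write_volume_csv(tables["absolute"], out / "aggregates.csv", "%.3f")
        vol.write_volume_csv(tables["relative"], out / "relative_volumes.csv", "%.6f")
        scores.to_csv(out / "zscores.csv", index=False)
        comparison.to_csv(out / "comparison.csv", index=False)
        age_reg.to_csv(out / "age_regression.csv", index=False)
        age_cmp.to_csv(out / "age_slope_comparison.csv", index=False)
        covariation.to_csv(out / "covariation.csv", index=False)
        with open(out / "models.json", "w") as fh:
            json.dump({f"{kind}/{measure}": json.loads(m.to_json())
                       for (kind, measure), m in models.items()}, fh)
        manifest = {
            "config": asdict(config),
            "config_sha256": hashlib.sha256(
                config.to_toml_text().encode()).hexdigest(),
            "n_subjects": int(len(demo)),
            "python": sys.version.split()[0],
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return results
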