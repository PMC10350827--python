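"""Neonatal brain segmentation taxonomy: aggregates and relative volumes.

The segmentation distinguishes 19 specific tissue segments (lobar grey and
white matter, cerebellum, brainstem, deep grey nuclei, hippocampus, amygdala)
plus two CSF-filled compartments (extra-cerebral CSF and the lateral
ventricles) and an optional unlabeled intracranial background.  Three nested
whole-brain denominators are derived from them:

* TTV (total tissue volume)   = sum of the 19 tissue segments + unlabeled
* TBV (total brain volume)    = TTV + lateral ventricles
* ICV (intracranial volume)   = TBV + eCSF

Relative volumes divide each tissue measure by TTV, the lateral ventricles by
TBV and eCSF by ICV.  All volumes are in cm**3.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TISSUE_SEGMENTS",
    "CSF_SEGMENTS",
    "OPTIONAL_SEGMENTS",
    "REQUIRED_SEGMENTS",
    "AGGREGATES",
    "COMPOSITE_MEMBERS",
    "RELATIVE_DENOMINATOR",
    "ValidationError",
    "validate_segment_table",
    "compute_aggregates",
    "compute_relative",
    "read_segment_csv",
    "write_volume_csv",
]

LOBES = ("frontal", "temporal", "parietal", "occipital", "insula", "cingulate")

GM_SEGMENTS = tuple(f"{lobe}_gm" for lobe in LOBES)
WM_SEGMENTS = tuple(f"{lobe}_wm" for lobe in LOBES)
DEEP_GM_SEGMENTS = ("caudate", "lentiform", "thalamus")
OTHER_SEGMENTS = ("cerebellum", "brainstem", "hippocampus", "amygdala")

#: the 19 specific tissue segments counted inside TTV
TISSUE_SEGMENTS: tuple[str, ...] = (
    GM_SEGMENTS + WM_SEGMENTS + ("cerebellum", "brainstem") + DEEP_GM_SEGMENTS
    + ("hippocampus", "amygdala")
)

CSF_SEGMENTS: tuple[str, ...] = ("ecsf", "lateral_ventricles")
OPTIONAL_SEGMENTS: tuple[str, ...] = ("unlabeled_intracranial",)
REQUIRED_SEGMENTS: tuple[str, ...] = TISSUE_SEGMENTS + CSF_SEGMENTS

# Composite regions. Hippocampus and amygdala sit inside TTV but belong to no
# composite; total deep GM includes the unlabeled intracranial background.
COMPOSITE_MEMBERS: dict[str, tuple[str, ...]] = {
    "total_cortical_gm": GM_SEGMENTS,
    "total_wm": WM_SEGMENTS,
    "total_deep_gm": DEEP_GM_SEGMENTS + ("unlabeled_intracranial",),
    "posterior_fossa": ("cerebellum", "brainstem"),
    "basal_ganglia": ("caudate", "lentiform"),
    **{(f"total_{lobe}_lobe" if lobe not in ("insula", "cingulate")
        else f"total_{lobe}"): (f"{lobe}_gm", f"{lobe}_wm") for lobe in LOBES},
}

WHOLE_BRAIN = ("ttv", "tbv", "icv")
AGGREGATES: tuple[str, ...] = WHOLE_BRAIN + tuple(COMPOSITE_MEMBERS)

#: denominator used when converting each measure to a relative volume
RELATIVE_DENOMINATOR: dict[str, str] = {
    **{seg: "ttv" for seg in TISSUE_SEGMENTS},
    **{comp: "ttv" for comp in COMPOSITE_MEMBERS},
    "lateral_ventricles": "tbv",
    "ecsf": "icv",
}


class ValidationError(ValueError):
    """Raised when a segment-volume table violates the taxonomy contract."""


def _as_frame(table: Mapping[str, float] | pd.DataFrame | pd.Series) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    if isinstance(table, pd.Series):
        return table.to_frame().T
    return pd.DataFrame([table])


def validate_segment_table(table) -> pd.DataFrame:
    """Check segment keys and non-negativity; return a normalized DataFrame.

    The optional ``unlabeled_intracranial`` column is added (as 0) when absent.
    Raises :class:`ValidationError` naming the first offending key.
    """
    df = _as_frame(table).copy()
    for key in REQUIRED_SEGMENTS:
        if key not in df.columns:
            raise ValidationError(f"missing segment column: {key!r}")
    if "unlabeled_intracranial" not in df.columns:
        df["unlabeled_intracranial"] = 0.0
    cols = list(REQUIRED_SEGMENTS) + ["unlabeled_intracranial"]
    values = df[cols].astype(float)
    if values.isna().any().any():
        bad = values.columns[values.isna().any()][0]
        raise ValidationError(f"non-numeric or missing volume in column {bad!r}")
    neg = values.lt(0).any()
    if neg.any():
        raise ValidationError(f"negative volume in column {neg.idxmax()!r}")
    df[cols] = values
    return df


def compute_aggregates(table) -> pd.DataFrame:
    """Whole-brain and composite volumes per subject (cm**3).

    Returns a DataFrame (same index as the input) with columns
    ``icv, tbv, ttv`` plus every composite in :data:`COMPOSITE_MEMBERS`.
    """
    df = validate_segment_table(table)
    out = pd.DataFrame(index=df.index)
    ttv = df[list(TISSUE_SEGMENTS)].sum(axis=1) + df["unlabeled_intracranial"]
    out["ttv"] = ttv
    out["tbv"] = ttv + df["lateral_ventricles"]
    out["icv"] = out["tbv"] + df["ecsf"]
    for name, members in COMPOSITE_MEMBERS.items():
        out[name] = df[list(members)].sum(axis=1)
    return out


def compute_relative(table) -> pd.DataFrame:
    """Relative volumes: tissue measures / TTV, ventricles / TBV, eCSF / ICV."""
    df = validate_segment_table(table)
    agg = compute_aggregates(df)
    for denom in WHOLE_BRAIN:
        if (agg[denom] <= 0).any():
            raise ValidationError(f"non-positive denominator {denom!r}; "
                                  "relative volumes undefined")
    out = pd.DataFrame(index=df.index)
    combined = pd.concat([df, agg], axis=1)
    for measure, denom in RELATIVE_DENOMINATOR.items():
        out[measure] = combined[measure] / agg[denom]
    return out


def read_segment_csv(path) -> pd.DataFrame:
    """Read a per-subject segment-volume CSV (``subject_id`` + one column per
    segment) and validate it."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValidationError("segment CSV must have a 'subject_id' column")
    df = df.set_index("subject_id")
    return validate_segment_table(df)


def write_volume_csv(df: pd.DataFrame, path, float_format: str = "%.6f") -> None:
    """Write a volume table with the package's CSV conventions."""
    df.to_csv(path, float_format=float_format, index_label="subject_id")
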