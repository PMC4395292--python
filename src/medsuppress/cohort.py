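"""Cohort data model: derived metabolic indices, log transforms, risk flags.

The phenotype table is an ordinary :class:`pandas.DataFrame` with one row per
participant.  Columns follow a fixed dictionary (see :data:`CONTINUOUS_COLUMNS`
and :data:`BOOLEAN_COLUMNS`); sex is coded 0 = male, 1 = female throughout the
pipeline.

Two insulin-homeostasis indices are derived per row:

* HOMA-IR = fasting insulin (uU/mL) x fasting glucose (mmol/L) / 22.5, with
  glucose converted from mg/dL using 18.0 mg/dL per mmol/L;
* QUICKI = 1 / (log10 I0 + log10 G0) with insulin in uU/mL and glucose in
  mg/dL.

Right-skewed biomarkers (adiponectin, HDL, LDL, total cholesterol,
triglycerides) get base-10 log columns so downstream regressions can assume
approximate normality.  Base-10 (rather than natural) logs are used because
QUICKI is defined with decimal logs and because genotype contrasts on the
log10 scale are the convention this pipeline follows; see docs/methods.md.

Binary risk factors use standard clinical cutoffs (hypertension 140/90 or
medication, diabetes fasting glucose >= 7.0 mmol/L or medication, obesity
BMI >= 25 under the Asian criterion) and the ATP-III metabolic-syndrome score
with Asian waist cutoffs.  Insulin resistance is a cohort-level flag: HOMA-IR
at or above the cohort's 75th percentile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, MissingDataError

#: mg/dL of glucose per mmol/L (clinical convention)
MGDL_PER_MMOLL = 18.0

#: Continuous phenotype columns that must be strictly positive when present.
CONTINUOUS_COLUMNS = (
    "age",
    "sbp",
    "dbp",
    "total_chol",
    "hdl",
    "ldl",
    "triglycerides",
    "bmi",
    "waist",
    "glucose_fasting",
    "insulin_fasting",
    "adiponectin",
)

BOOLEAN_COLUMNS = ("current_smoker", "on_htn_med", "on_dm_med", "on_lipid_med")

#: medication flags default False when the column is absent from the input.
MEDICATION_COLUMNS = ("on_htn_med", "on_dm_med", "on_lipid_med")

DEFAULT_SEX_MAP = {"M": 0, "F": 1, "m": 0, "f": 1, "1": 0, "2": 1, 1: 0, 2: 1, 0: 0}

#: columns consumed by the ATP-III metabolic-syndrome score
MET_S_INPUTS = ("sbp", "dbp", "triglycerides", "hdl", "glucose_fasting", "waist", "sex")


@dataclass
class Cohort:
    """A phenotype table plus provenance (source path and filter log)."""

    data: pd.DataFrame
    source: str | None = None
    filter_log: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "id" in self.data.columns and self.data["id"].duplicated().any():
            dups = self.data.loc[self.data["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate participant ids: {dups[:5]}")

    @property
    def n(self) -> int:
        return len(self.data)


def _check_positive(value: Any, name: str) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(~np.isnan(arr) & (arr <= 0)):
        raise DomainError(f"{name} must be strictly positive")


def compute_homa_ir(insulin: Any, glucose: Any) -> Any:
    """HOMA insulin-resistance index from fasting insulin (uU/mL) and glucose (mg/dL).

    Glucose is converted to mmol/L internally (18.0 mg/dL per mmol/L).
    """
    _check_positive(insulin, "insulin_fasting")
    _check_positive(glucose, "glucose_fasting")
    insulin = np.asarray(insulin, dtype=float)
    glucose = np.asarray(glucose, dtype=float)
    out = insulin * (glucose / MGDL_PER_MMOLL) / 22.5
    return float(out) if out.ndim == 0 else out


def compute_quicki(insulin: Any, glucose: Any) -> Any:
    """QUICKI insulin-sensitivity index, 1/(log10 I0 + log10 G0).

    Insulin I0 in uU/mL, glucose G0 in mg/dL; decimal logarithms.
    """
    _check_positive(insulin, "insulin_fasting")
    _check_positive(glucose, "glucose_fasting")
    insulin = np.asarray(insulin, dtype=float)
    glucose = np.asarray(glucose, dtype=float)
    denom = np.log10(insulin) + np.log10(glucose)
    if np.any(~np.isnan(denom) & (denom == 0)):
        raise DomainError("log10(insulin_fasting) + log10(glucose_fasting) is zero")
    out = 1.0 / denom
    return float(out) if out.ndim == 0 else out


_LOG_COLUMNS = {
    "log_adiponectin": "adiponectin",
    "log_hdl": "hdl",
    "log_tg": "triglycerides",
    "log_tc": "total_chol",
    "log_ldl": "ldl",
}


def derive_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with HOMA-IR, QUICKI and log10 biomarker columns appended."""
    out = df.copy()
    out["homa_ir"] = compute_homa_ir(df["insulin_fasting"], df["glucose_fasting"])
    out["quicki"] = compute_quicki(df["insulin_fasting"], df["glucose_fasting"])
    for log_col, raw_col in _LOG_COLUMNS.items():
        if raw_col in df.columns:
            _check_positive(df[raw_col], raw_col)
            out[log_col] = np.log10(df[raw_col].astype(float))
    return out


def _mets_components(df: pd.DataFrame, med_flags_count: bool) -> pd.Series:
    for col in MET_S_INPUTS:
        if col not in df.columns:
            raise MissingDataError(f"metabolic-syndrome scoring needs column {col!r}")
        if df[col].isna().any():
            bad = df.index[df[col].isna()][0]
            raise MissingDataError(f"missing {col!r} for participant index {bad!r}")
    male = df["sex"].astype(int) == 0

    bp = (df["sbp"] >= 130) | (df["dbp"] >= 85)
    glucose = df["glucose_fasting"] >= 100
    if med_flags_count:
        if "on_htn_med" in df.columns:
            bp = bp | df["on_htn_med"].fillna(False).astype(bool)
        if "on_dm_med" in df.columns:
            glucose = glucose | df["on_dm_med"].fillna(False).astype(bool)
    tg = df["triglycerides"] >= 150
    hdl = np.where(male, df["hdl"] < 40, df["hdl"] < 50)
    waist = np.where(male, df["waist"] > 90, df["waist"] > 80)

    count = (
        bp.astype(int)
        + tg.astype(int)
        + glucose.astype(int)
        + pd.Series(hdl, index=df.index).astype(int)
        + pd.Series(waist, index=df.index).astype(int)
    )
    return count


def classify_mets(
    record: pd.Series | pd.DataFrame, *, med_flags_count: bool = True
) -> tuple[int, bool] | pd.DataFrame:
    """ATP-III metabolic-syndrome score (Asian waist cutoffs).

    The five attributes, with the boundary strictness each cutoff carries:
    BP at least 130/85 mm Hg (or antihypertensive medication), triglycerides
    at least 150 mg/dL, HDL below 40 (men) / 50 (women) mg/dL, fasting glucose
    at least 100 mg/dL (or antidiabetic medication), waist above 90 (men) /
    80 (women) cm.  Three or more attributes define the syndrome.

    Parameters
    ----------
    record
        A single participant row (Series) or a whole table (DataFrame).
    med_flags_count
        Whether medication flags satisfy the BP/glucose attributes on their
        own.  Default True.

    Returns
    -------
    ``(component_count, mets)`` for a Series; a DataFrame with columns
    ``mets_component_count`` and ``mets`` for a DataFrame.
    """
    if isinstance(record, pd.Series):
        frame = record.to_frame().T
        # preserve dtypes lost by the transpose
        count = int(_mets_components(frame.infer_objects(), med_flags_count).iloc[0])
        return count, count >= 3
    count = _mets_components(record, med_flags_count)
    return pd.DataFrame({"mets_component_count": count, "mets": count >= 3})


def classify_binary_risks(df: pd.DataFrame) -> pd.DataFrame:
    """Row-level hypertension/diabetes/obesity flags plus cohort-level insulin resistance.

    Requires ``homa_ir`` (from :func:`derive_phenotypes`).  Insulin resistance
    is HOMA-IR at or above the cohort upper quartile (linear-interpolation
    percentile, boundary inclusive), so it depends on the whole table and is
    undefined for cohorts of fewer than four rows.
    """
    if "homa_ir" not in df.columns:
        raise MissingDataError("classify_binary_risks needs derived column 'homa_ir'")
    if len(df) < 4:
        raise DomainError("upper quartile undefined for cohorts with fewer than 4 rows")
    htn = (df["sbp"] >= 140) | (df["dbp"] >= 90)
    dm = df["glucose_fasting"] >= 7.0 * MGDL_PER_MMOLL
    if "on_htn_med" in df.columns:
        htn = htn | df["on_htn_med"].fillna(False).astype(bool)
    if "on_dm_med" in df.columns:
        dm = dm | df["on_dm_med"].fillna(False).astype(bool)
    q75 = float(np.percentile(df["homa_ir"].dropna().to_numpy(), 75))
    return pd.DataFrame(
        {
            "hypertension": htn,
            "diabetes": dm,
            "obesity": df["bmi"] >= 25.0,
            "insulin_resistant": df["homa_ir"] >= q75,
        },
        index=df.index,
    )


def apply_exclusions(
    df: pd.DataFrame, *, min_age: float = 18.0, drop_medicated: bool = True
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop under-age rows and regular medication users; log counts per criterion.

    Idempotent: re-applying to an already filtered table removes nothing.
    """
    under_age = df["age"] < min_age
    medicated = pd.Series(False, index=df.index)
    if drop_medicated:
        for col in MEDICATION_COLUMNS:
            if col in df.columns:
                medicated = medicated | df[col].fillna(False).astype(bool)
    keep = ~(under_age | medicated)
    log = {
        "n_input": int(len(df)),
        "excluded_age": int(under_age.sum()),
        "excluded_medication": int((medicated & ~under_age).sum()),
        "n_retained": int(keep.sum()),
    }
    return df.loc[keep].copy(), log


def annotate_cohort(cohort: Cohort, *, med_flags_count: bool = True) -> Cohort:
    """Derived indices + risk flags + ATP-III score, returned as a new Cohort."""
    df = derive_phenotypes(cohort.data)
    df = pd.concat([df, classify_mets(df, med_flags_count=med_flags_count)], axis=1)
    df = pd.concat([df, classify_binary_risks(df)], axis=1)
    return Cohort(df, source=cohort.source, filter_log=dict(cohort.filter_log))


def load_phenotypes(
    path: str | Path,
    *,
    sex_map: Mapping[Any, int] | None = None,
    sep: str | None = None,
) -> Cohort:
    """Read a phenotype TSV/CSV into a Cohort.

    ``sex`` may be coded M/F or 1/2 (configurable via ``sex_map``); it is
    recoded to 0 = male, 1 = female.  Empty cells and "NA" are missing.
    Medication flag columns default to False when absent.  Continuous columns
    are validated to be strictly positive where present.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""], dtype={"id": str})
    sex_map = dict(DEFAULT_SEX_MAP if sex_map is None else sex_map)
    if "sex" in df.columns:
        mapped = df["sex"].map(lambda v: sex_map.get(v, sex_map.get(str(v), v)))
        bad = ~mapped.isin([0, 1]) & mapped.notna()
        if bad.any():
            raise ValueError(f"unrecognized sex codes: {sorted(set(df.loc[bad, 'sex']))}")
        df["sex"] = mapped.astype("Int64").astype(float)
    for col in MEDICATION_COLUMNS + ("current_smoker",):
        if col not in df.columns:
            if col in MEDICATION_COLUMNS:
                df[col] = False
        else:
            df[col] = df[col].fillna(False).astype(bool)
    for col in CONTINUOUS_COLUMNS:
        if col in df.columns:
            _check_positive(df[col], col)
    return Cohort(df, source=str(path))


def write_cohort(cohort: Cohort, table_path: str | Path, log_path: str | Path | None = None) -> None:
    """Write the augmented phenotype table as TSV plus the filter log as JSON."""
    cohort.data.to_csv(table_path, sep="\t", index=False)
    if log_path is not None:
        Path(log_path).write_text(json.dumps(cohort.filter_log, indent=2) + "\n")
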