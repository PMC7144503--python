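"""CSV readers/writers and configuration loading.

Cohorts travel as UTF-8 CSV, missing = empty cell. The wide layout has
one row per patient with per-session score columns ``pds_s0 ... pds_s12``
(and likewise ``ptci_``, ``mem_``, ``dep_``, ``anx_``), the baseline
covariates and follow-up columns ``pds_fu``, ``dep_fu``, ``anx_fu``. The
long layout is tidy: ``patient_id, measure, session, value``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import PatientRecord
from .scales import FOLLOWUP_MEASURES, MEASURE_ATTR, SCALES

COVARIATE_COLS = ("age", "gender", "months_since_trauma", "trauma_type",
                  "comorbid_depression")
_FU_ATTR = {"pds": "followup_symptom", "dep": "followup_depression",
            "anx": "followup_anxiety"}


def cohort_to_wide(cohort: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for rec in cohort:
        row = {"patient_id": rec.patient_id, "age": rec.age,
               "gender": rec.gender,
               "months_since_trauma": rec.months_since_trauma,
               "trauma_type": rec.trauma_type,
               "comorbid_depression": rec.comorbid_depression}
        for measure, attr in MEASURE_ATTR.items():
            for s, v in enumerate(getattr(rec, attr)):
                row[f"{measure}_s{s}"] = v
        for measure in FOLLOWUP_MEASURES:
            row[f"{measure}_fu"] = getattr(rec, _FU_ATTR[measure])
        row["true_gain_session"] = (np.nan if rec.true_gain_session is None
                                    else rec.true_gain_session)
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_to_long(cohort: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for rec in cohort:
        for measure, attr in MEASURE_ATTR.items():
            for s, v in enumerate(getattr(rec, attr)):
                rows.append({"patient_id": rec.patient_id,
                             "measure": measure, "session": s, "value": v})
    return pd.DataFrame(rows)


def wide_to_cohort(df: pd.DataFrame) -> list[PatientRecord]:
    missing = [c for c in ("patient_id",) + COVARIATE_COLS
               if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    session_cols: dict[str, list[str]] = {}
    for measure in MEASURE_ATTR:
        cols = sorted((c for c in df.columns
                       if c.startswith(f"{measure}_s")
                       and c[len(measure) + 2:].isdigit()),
                      key=lambda c, m=measure: int(c[len(m) + 2:]))
        if not cols:
            raise ValueError(f"no session columns found for '{measure}'")
        session_cols[measure] = cols
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicated patient_id rows: {dupes}")
    cohort = []
    for _, row in df.iterrows():
        series = {}
        for measure, cols in session_cols.items():
            vals = pd.to_numeric(row[cols], errors="coerce").to_numpy(float)
            lo, hi = SCALES[measure].lower, SCALES[measure].upper
            bad = np.flatnonzero(np.isfinite(vals)
                                 & ((vals < lo) | (vals > hi)))
            if bad.size:
                raise ValueError(
                    f"patient {row['patient_id']}, column "
                    f"{cols[bad[0]]}: score {vals[bad[0]]} outside "
                    f"[{lo}, {hi}]")
            series[measure] = vals
        tg = row.get("true_gain_session", np.nan)
        rec = PatientRecord(
            patient_id=str(row["patient_id"]),
            age=float(row["age"]),
            gender=str(row["gender"]),
            months_since_trauma=float(row["months_since_trauma"]),
            trauma_type=str(row["trauma_type"]),
            comorbid_depression=bool(row["comorbid_depression"]),
            symptom_series=series["pds"],
            process_appraisal_series=series["ptci"],
            process_memory_series=series["mem"],
            depression_series=series["dep"],
            anxiety_series=series["anx"],
            followup_symptom=float(row.get("pds_fu", np.nan)),
            followup_depression=float(row.get("dep_fu", np.nan)),
            followup_anxiety=float(row.get("anx_fu", np.nan)),
            true_gain_session=None if pd.isna(tg) else int(tg),
        )
        rec.validate()
        cohort.append(rec)
    return cohort


def read_cohort(path, layout: str = "wide",
                column_map: dict[str, str] | None = None,
                ) -> list[PatientRecord]:
    """Read and validate a cohort CSV in wide or long layout.

    ``column_map`` renames input columns to the package's names before
    validation. Long input must carry ``patient_id, measure, session,
    value`` plus one covariate row set; duplicated (patient, measure,
    session) cells are an error.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    if layout == "wide":
        return wide_to_cohort(df)
    if layout != "long":
        raise ValueError("layout must be 'wide' or 'long'")
    required = {"patient_id", "measure", "session", "value"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"missing required columns: {sorted(required - set(df.columns))}")
    dupes = df.duplicated(subset=["patient_id", "measure", "session"])
    if dupes.any():
        listing = df.loc[dupes, ["patient_id", "measure", "session"]]
        raise ValueError("duplicated (patient, measure, session) cells:\n"
                         + listing.to_string(index=False))
    if not np.issubdtype(df["session"].dtype, np.integer):
        sess = pd.to_numeric(df["session"], errors="raise")
        if (sess < 0).any() or (sess != sess.round()).any():
            raise ValueError("sessions must be nonnegative integers")
        df["session"] = sess.astype(int)
    wide = df.pivot(index="patient_id", columns=["measure", "session"],
                    values="value")
    wide.columns = [f"{m}_s{s}" for m, s in wide.columns]
    wide = wide.reset_index()
    cov_cols = [c for c in COVARIATE_COLS if c in df.columns]
    if len(cov_cols) == len(COVARIATE_COLS):
        cov = df.drop_duplicates("patient_id").set_index("patient_id")
        for c in COVARIATE_COLS:
            wide[c] = wide["patient_id"].map(cov[c])
    else:
        raise ValueError(
            "long layout requires covariate columns "
            f"{sorted(set(COVARIATE_COLS) - set(df.columns))}")
    return wide_to_cohort(wide)


def write_cohort(cohort: list[PatientRecord], path,
                 layout: str = "wide") -> None:
    df = cohort_to_wide(cohort) if layout == "wide" else cohort_to_long(cohort)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def load_config_file(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


__all__ = [
    "cohort_to_wide", "cohort_to_long", "wide_to_cohort", "read_cohort",
    "write_cohort", "load_config_file", "COVARIATE_COLS",
]
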