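"""Cohort CSV schema: one row per subject, lossless round-trip.

The file starts with a schema-version comment line, then a header row.
Yes/no columns accept both {0,1} and {no,yes}; the writer emits 0/1.
Optional blocks (IFi items, grip readings, outcomes) may be absent as
whole columns or left blank per row.
"""

from __future__ import annotations

import io
from typing import List, Optional

import numpy as np
import pandas as pd

from .domain import (
    AGILE_ITEMS,
    N_IFI_GENERIC_ITEMS,
    AgileResponse,
    OutcomeRecord,
    SubjectRecord,
)
from .scoring import IFI_ITEM_COLUMNS

SCHEMA_VERSION = "agile-frailty-cohort-v1"

GRIP_COLUMNS = ("grip_1", "grip_2", "grip_3")
OUTCOME_COLUMNS = (
    "completed_followup",
    "died",
    "badl_lost_followup",
    "hospitalized",
    "incident_disability",
)
YESNO_COLUMNS = AGILE_ITEMS + OUTCOME_COLUMNS[:2] + OUTCOME_COLUMNS[3:]

COHORT_COLUMNS = (
    ("subject_id", "age", "sex")
    + AGILE_ITEMS
    + ("badl_lost_baseline",)
    + IFI_ITEM_COLUMNS
    + ("sss_score", "mna_score")
    + GRIP_COLUMNS
    + OUTCOME_COLUMNS
)

_YESNO_MAP = {"yes": 1, "no": 0, "1": 1, "0": 0, "true": 1, "false": 0}


def _coerce_yesno(series: pd.Series) -> pd.Series:
    def conv(v):
        if pd.isna(v):
            return np.nan
        if isinstance(v, str):
            key = v.strip().lower()
            if key not in _YESNO_MAP:
                raise ValueError(f"unparseable yes/no value: {v!r}")
            return _YESNO_MAP[key]
        return int(v)

    return series.map(conv)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV (comment lines ignored) into a canonical frame."""
    df = pd.read_csv(path, comment="#")
    for col in YESNO_COLUMNS:
        if col in df.columns:
            df[col] = _coerce_yesno(df[col])
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort frame with the schema-version header comment."""
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    buf = io.StringIO()
    buf.write(f"# schema: {SCHEMA_VERSION}\n")
    df[cols].to_csv(buf, index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def records_to_frame(records: List[SubjectRecord]) -> pd.DataFrame:
    """Flatten SubjectRecords into the cohort-CSV column layout."""
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "age": r.age, "sex": r.sex}
        for item, ans in r.agile_items.answers().items():
            row[item] = np.nan if ans is None else int(ans)
        row["badl_lost_baseline"] = r.badl_lost_baseline
        if r.ifi_items is not None:
            for col, v in zip(IFI_ITEM_COLUMNS, r.ifi_items):
                row[col] = v
        row["sss_score"] = r.sss_score if r.sss_score is not None else np.nan
        row["mna_score"] = r.mna_score if r.mna_score is not None else np.nan
        if r.grip_measurements is not None:
            for col, v in zip(GRIP_COLUMNS, r.grip_measurements):
                row[col] = v
        if r.outcome is not None:
            o = r.outcome
            row.update(
                completed_followup=int(o.completed_followup),
                died=int(o.died),
                badl_lost_followup=o.badl_lost_followup,
                hospitalized=int(o.hospitalized),
                incident_disability=int(o.incident_disability),
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    return df[cols]


def frame_to_records(df: pd.DataFrame) -> List[SubjectRecord]:
    """Inverse of :func:`records_to_frame` (NaN blocks become None)."""

    def opt(v):
        return None if pd.isna(v) else v

    records = []
    has_ifi = all(c in df.columns for c in IFI_ITEM_COLUMNS)
    has_grip = all(c in df.columns for c in GRIP_COLUMNS)
    has_outcome = all(c in df.columns for c in OUTCOME_COLUMNS)
    for _, row in df.iterrows():
        answers = {
            item: None if pd.isna(row[item]) else bool(int(row[item]))
            for item in AGILE_ITEMS
        }
        ifi = None
        if has_ifi and not any(pd.isna(row[c]) for c in IFI_ITEM_COLUMNS):
            ifi = tuple(float(row[c]) for c in IFI_ITEM_COLUMNS)
        grip = None
        if has_grip and not any(pd.isna(row[c]) for c in GRIP_COLUMNS):
            grip = tuple(float(row[c]) for c in GRIP_COLUMNS)
        outcome = None
        if has_outcome and not pd.isna(row["completed_followup"]):
            outcome = OutcomeRecord(
                completed_followup=bool(int(row["completed_followup"])),
                died=bool(int(row["died"])),
                badl_lost_followup=int(row["badl_lost_followup"]),
                hospitalized=bool(int(row["hospitalized"])),
                incident_disability=bool(int(row["incident_disability"])),
            )
        sss = opt(row.get("sss_score"))
        mna = opt(row.get("mna_score"))
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                agile_items=AgileResponse(**answers),
                badl_lost_baseline=int(row["badl_lost_baseline"]),
                ifi_items=ifi,
                sss_score=None if sss is None else int(sss),
                mna_score=None if mna is None else float(mna),
                grip_measurements=grip,
                outcome=outcome,
            )
        )
    return records
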