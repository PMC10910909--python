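"""Long-format CSV persistence for synthetic populations.

Three files: an events table (patient_id, date, code_system, code, value),
a patients table (id, sex, birth_date, reg_start, reg_end) and a separate
ground-truth table. Dates are ISO-8601, anchored at the generator's window
start; internally everything stays integer days.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .synthetic_ehr import Event, PatientRecord, TrueState

__all__ = [
    "day_to_date",
    "date_to_day",
    "write_population",
    "read_population",
    "write_truth",
    "read_truth",
]


def _anchor(window_start: str) -> _dt.date:
    return _dt.date.fromisoformat(window_start)


def day_to_date(day: int, window_start: str) -> str:
    return (_anchor(window_start) + _dt.timedelta(days=int(day))).isoformat()


def date_to_day(date: str, window_start: str) -> int:
    return (_dt.date.fromisoformat(date) - _anchor(window_start)).days


def write_population(
    records: Sequence[PatientRecord],
    out_dir: str | Path,
    window_start: str = "2007-01-01",
) -> Tuple[Path, Path]:
    """Write events.csv + patients.csv; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ev_rows = []
    pat_rows = []
    for rec in records:
        pat_rows.append(
            {
                "patient_id": rec.patient_id,
                "sex": "F" if rec.female else "M",
                "birth_date": day_to_date(rec.birth_day, window_start),
                "reg_start": day_to_date(rec.registration_start, window_start),
                "reg_end": day_to_date(rec.registration_end, window_start),
            }
        )
        for e in rec.events:
            ev_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "date": day_to_date(e.day, window_start),
                    "code_system": e.system,
                    "code": e.code,
                    "value": "" if e.value is None else e.value,
                }
            )
    events_path = out_dir / "events.csv"
    patients_path = out_dir / "patients.csv"
    pd.DataFrame(ev_rows).to_csv(events_path, index=False)
    pd.DataFrame(pat_rows).to_csv(patients_path, index=False)
    return events_path, patients_path


def read_population(
    in_dir: str | Path, window_start: str = "2007-01-01"
) -> List[PatientRecord]:
    """Read the events.csv / patients.csv pair back into patient records."""
    in_dir = Path(in_dir)
    patients = pd.read_csv(in_dir / "patients.csv")
    events = pd.read_csv(in_dir / "events.csv")
    by_patient = {pid: g for pid, g in events.groupby("patient_id")}
    records: List[PatientRecord] = []
    for row in patients.itertuples(index=False):
        evs: List[Event] = []
        g = by_patient.get(row.patient_id)
        if g is not None:
            for e in g.itertuples(index=False):
                value = None if pd.isna(e.value) or e.value == "" else float(e.value)
                evs.append(
                    Event(date_to_day(e.date, window_start), e.code_system, e.code, value)
                )
        rec = PatientRecord(
            patient_id=int(row.patient_id),
            female=int(row.sex == "F"),
            birth_day=date_to_day(row.birth_date, window_start),
            registration_start=date_to_day(row.reg_start, window_start),
            registration_end=date_to_day(row.reg_end, window_start),
            events=evs,
        )
        rec.sort_events()
        records.append(rec)
    return records


def write_truth(
    truths: Sequence[TrueState], out_dir: str | Path
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "ground_truth.csv"
    pd.DataFrame(
        {
            "patient_id": [t.patient_id for t in truths],
            "lp_covariates": [t.lp_covariates for t in truths],
            "frailty": [t.frailty for t in truths],
            "lp_true": [t.lp_true for t in truths],
            "true_event_day": [
                "" if t.true_event_day is None else t.true_event_day for t in truths
            ],
            "true_smoking": [t.true_smoking for t in truths],
            "true_sbp": [t.true_sbp for t in truths],
            "true_chol": [t.true_chol for t in truths],
        }
    ).to_csv(path, index=False)
    return path


def read_truth(in_dir: str | Path) -> List[TrueState]:
    df = pd.read_csv(Path(in_dir) / "ground_truth.csv")
    out: List[TrueState] = []
    for row in df.itertuples(index=False):
        day = None if pd.isna(row.true_event_day) else int(row.true_event_day)
        out.append(
            TrueState(
                patient_id=int(row.patient_id),
                lp_covariates=float(row.lp_covariates),
                frailty=float(row.frailty),
                lp_true=float(row.lp_true),
                true_event_day=day,
                true_smoking=int(row.true_smoking),
                true_sbp=float(row.true_sbp),
                true_chol=float(row.true_chol),
            )
        )
    return out
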