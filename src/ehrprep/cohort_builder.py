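"""Turn raw coded-event streams into an analysis cohort.

Time zero (t0) is placed at the end of a run-in period of ``k`` whole years
after database entry. Baseline predictors are aggregated from run-in data
only; eligibility (age 40-65 at t0, no prior cardiovascular code, still
registered at t0) is applied at t0; follow-up runs to the window end,
deregistration or death, whichever comes first. Event times under a specific
outcome definition are attached later by :mod:`ehrprep.outcome_engine`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .synthetic_ehr import (
    ASPIRIN_CODE,
    CHOL_CODE,
    DAYS_PER_YEAR,
    DEATH_CODE,
    DIAG,
    ICPC_EVENT_CODES,
    MEAS,
    MED,
    SBP_CODE,
    SMOKING_CODE,
    SPECIFIC_MED_CODES,
    PatientRecord,
)

__all__ = [
    "ALL_OUTCOME_CODES",
    "CohortConfig",
    "CohortRow",
    "build_cohort",
    "compute_followup",
    "cohort_to_frame",
    "summarize_cohort",
]

# Most conservative history exclusion: any code that any outcome definition
# could ever count, including aspirin.
ALL_OUTCOME_CODES: FrozenSet[str] = frozenset(
    ICPC_EVENT_CODES + SPECIFIC_MED_CODES + (ASPIRIN_CODE,)
)


@dataclass(frozen=True)
class CohortConfig:
    run_in_years: int = 1
    age_min: int = 40
    age_max: int = 65
    data_window_start: int = 0
    data_window_end: int = 15 * DAYS_PER_YEAR
    prior_cvd_codes: FrozenSet[str] = ALL_OUTCOME_CODES

    def __post_init__(self) -> None:
        if self.run_in_years < 1:
            raise ValueError("run_in_years must be >= 1")
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be < age_max")
        if self.data_window_end <= self.data_window_start:
            raise ValueError("data window end must be after start")
        if self.data_window_start + self.run_in_years * DAYS_PER_YEAR >= self.data_window_end:
            raise ValueError("run-in period does not fit inside the data window")


@dataclass
class CohortRow:
    """One eligible patient at t0, with a handle on the raw event stream."""

    patient_id: int
    t0: int
    age_at_t0: int
    female: int
    smoking: int
    mean_sbp: Optional[float]  # None when never measured during run-in
    mean_chol: Optional[float]
    followup_days: int  # censoring-only follow-up; outcome engine may shorten
    censoring_reason: str  # window_end | deregistration | death
    record: PatientRecord = field(repr=False)


def compute_followup(
    record: PatientRecord, t0: int, data_window_end: int
) -> Tuple[int, str]:
    """Follow-up from t0 to the earliest censoring time, with its reason.

    Stopping times considered here: end of the data window, deregistration
    (registration ends early without a death code) and death (``A96``).
    A qualifying outcome event can shorten this further, but which codes
    qualify depends on the outcome definition, so that step lives in
    :mod:`ehrprep.outcome_engine`.
    """
    death_day = next(
        (e.day for e in record.events if e.system == DIAG and e.code == DEATH_CODE),
        None,
    )
    stop = min(data_window_end, record.registration_end)
    reason = "window_end" if record.registration_end >= data_window_end else "deregistration"
    if death_day is not None and death_day <= stop:
        stop = death_day
        reason = "death"
    if stop < t0:
        raise AssertionError(
            f"patient {record.patient_id}: stopping time {stop} precedes t0 {t0}; "
            "should have been excluded"
        )
    return stop - t0, reason


def _run_in_means(
    record: PatientRecord, entry: int, t0: int
) -> Tuple[Optional[float], Optional[float]]:
    # run-in interval is half-open (entry, t0]: a measurement exactly at t0 counts
    sbp = [e.value for e in record.events
           if e.system == MEAS and e.code == SBP_CODE and entry < e.day <= t0]
    chol = [e.value for e in record.events
            if e.system == MEAS and e.code == CHOL_CODE and entry < e.day <= t0]
    return (
        float(np.mean(sbp)) if sbp else None,
        float(np.mean(chol)) if chol else None,
    )


def build_cohort(
    records: Iterable[PatientRecord], config: CohortConfig
) -> List[CohortRow]:
    """Apply run-in, eligibility and baseline aggregation to raw records."""
    rows: List[CohortRow] = []
    records = list(records)
    if not records:
        warnings.warn("empty input population; returning empty cohort")
        return rows
    for rec in records:
        entry = max(rec.registration_start, config.data_window_start)
        t0 = entry + config.run_in_years * DAYS_PER_YEAR
        if rec.registration_end <= t0 or t0 >= config.data_window_end:
            continue
        age_at_t0 = (t0 - rec.birth_day) // DAYS_PER_YEAR
        if not (config.age_min <= age_at_t0 <= config.age_max):
            continue
        # history exclusion: any prior-CVD code at or before t0
        if any(
            e.code in config.prior_cvd_codes and e.day <= t0
            for e in rec.events
            if e.system in (DIAG, MED)
        ):
            continue
        mean_sbp, mean_chol = _run_in_means(rec, entry, t0)
        smoking = int(
            any(e.system == DIAG and e.code == SMOKING_CODE and e.day <= t0
                for e in rec.events)
        )
        followup, reason = compute_followup(rec, t0, config.data_window_end)
        if followup <= 0:
            continue
        rows.append(
            CohortRow(
                patient_id=rec.patient_id,
                t0=t0,
                age_at_t0=int(age_at_t0),
                female=rec.female,
                smoking=smoking,
                mean_sbp=mean_sbp,
                mean_chol=mean_chol,
                followup_days=int(followup),
                censoring_reason=reason,
                record=rec,
            )
        )
    return rows


def cohort_to_frame(rows: Iterable[CohortRow]) -> pd.DataFrame:
    """Tabular view of the cohort (without the raw event streams)."""
    rows = list(rows)
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in rows],
            "t0": [r.t0 for r in rows],
            "age_at_t0": [r.age_at_t0 for r in rows],
            "female": [r.female for r in rows],
            "smoking": [r.smoking for r in rows],
            "mean_sbp": [np.nan if r.mean_sbp is None else r.mean_sbp for r in rows],
            "mean_chol": [np.nan if r.mean_chol is None else r.mean_chol for r in rows],
            "followup_days": [r.followup_days for r in rows],
            "censoring_reason": [r.censoring_reason for r in rows],
        }
    )


def summarize_cohort(frame: pd.DataFrame, event_col: str = "event") -> pd.DataFrame:
    """Baseline characteristics split into cases and controls.

    ``frame`` must carry an event indicator column (attach one with the
    outcome engine first). Returns one column per group with mean (SD) age,
    percentage women / smokers and measurement availability.
    """
    if frame.empty:
        raise ValueError("cannot summarize an empty cohort")
    if event_col not in frame.columns:
        raise KeyError(f"column {event_col!r} not found; run the outcome engine first")
    groups = {"cases": frame[frame[event_col] == 1], "controls": frame[frame[event_col] == 0]}
    if groups["cases"].empty:
        warnings.warn("no events in cohort; summary has a single informative column")
    out = {}
    for name, g in groups.items():
        out[name] = {
            "n": len(g),
            "age_mean": g["age_at_t0"].mean(),
            "age_sd": g["age_at_t0"].std(),
            "women_pct": 100.0 * g["female"].mean() if len(g) else np.nan,
            "smoking_pct": 100.0 * g["smoking"].mean() if len(g) else np.nan,
            "sbp_available_pct": 100.0 * g["mean_sbp"].notna().mean() if len(g) else np.nan,
            "chol_available_pct": 100.0 * g["mean_chol"].notna().mean() if len(g) else np.nan,
        }
    return pd.DataFrame(out)
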