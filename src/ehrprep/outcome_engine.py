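"""Coded operationalizations of "first-ever main adverse cardiovascular event".

Five definitions combine the diagnosis channel (ICPC codes K90/K89/K75) and
the medication channel (specific antiplatelet ATC codes, with or without
aspirin). Applying a definition to a cohort row yields an event indicator and
an event time; follow-up of non-cases is NOT truncated at codes the
definition does not recognize.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Tuple

import pandas as pd

from .cohort_builder import CohortRow, cohort_to_frame
from .synthetic_ehr import (
    ASPIRIN_CODE,
    DIAG,
    ICPC_EVENT_CODES,
    MED,
    SPECIFIC_MED_CODES,
)

__all__ = [
    "OutcomeDefinition",
    "DEFINITIONS",
    "get_definition",
    "apply_outcome",
    "attach_outcome",
    "venn_counts",
]

_DIAG_SET: FrozenSet[str] = frozenset(ICPC_EVENT_CODES)
_SPECIFIC_MED: FrozenSet[str] = frozenset(SPECIFIC_MED_CODES)
_ALL_MED: FrozenSet[str] = _SPECIFIC_MED | {ASPIRIN_CODE}


@dataclass(frozen=True)
class OutcomeDefinition:
    name: str
    diagnosis_codes: FrozenSet[str]
    medication_codes: FrozenSet[str]

    @property
    def includes_aspirin(self) -> bool:
        return ASPIRIN_CODE in self.medication_codes


#: The reference composite and the four derivation variants.
DEFINITIONS: Dict[str, OutcomeDefinition] = {
    "REF": OutcomeDefinition("REF", _DIAG_SET, _ALL_MED),
    "ATCexclASA_or_ICPC": OutcomeDefinition("ATCexclASA_or_ICPC", _DIAG_SET, _SPECIFIC_MED),
    "ATC_only": OutcomeDefinition("ATC_only", frozenset(), _ALL_MED),
    "ATCexclASA_only": OutcomeDefinition("ATCexclASA_only", frozenset(), _SPECIFIC_MED),
    "ICPC_only": OutcomeDefinition("ICPC_only", _DIAG_SET, frozenset()),
}


def get_definition(name: str) -> OutcomeDefinition:
    try:
        return DEFINITIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown outcome definition {name!r}; known: {sorted(DEFINITIONS)}"
        ) from None


def apply_outcome(row: CohortRow, definition: OutcomeDefinition) -> Tuple[int, int]:
    """(event indicator, time in days from t0) for one cohort row.

    A row is a case iff a qualifying code is dated strictly after t0 and
    within the censoring follow-up; its event time is the first such date.
    Non-cases keep the censoring follow-up unchanged.
    """
    end = row.t0 + row.followup_days
    first = None
    for e in row.record.events:
        if e.day <= row.t0:
            continue
        if e.day > end:
            break
        qualifies = (e.system == DIAG and e.code in definition.diagnosis_codes) or (
            e.system == MED and e.code in definition.medication_codes
        )
        if qualifies:
            first = e.day
            break
    if first is None:
        return 0, row.followup_days
    return 1, first - row.t0


def attach_outcome(
    rows: Iterable[CohortRow], definition: OutcomeDefinition
) -> pd.DataFrame:
    """Cohort frame with ``event`` / ``time`` columns under one definition.

    Covariate columns are identical across definitions by construction; only
    the outcome pair differs.
    """
    rows = list(rows)
    frame = cohort_to_frame(rows)
    events, times = [], []
    for r in rows:
        ev, t = apply_outcome(r, definition)
        events.append(ev)
        times.append(t)
    frame["event"] = events
    frame["time"] = times
    frame["outcome_definition"] = definition.name
    return frame


def venn_counts(
    rows: Iterable[CohortRow], definitions: List[OutcomeDefinition]
) -> Dict[FrozenSet[str], int]:
    """Partition of cases by which definitions flag them.

    Keys are frozensets of definition names (non-empty combinations only);
    values sum to the number of patients flagged by at least one definition.
    """
    if len(definitions) < 1:
        raise ValueError("need at least one definition")
    counts: Dict[FrozenSet[str], int] = {}
    for r in rows:
        flagged = frozenset(
            d.name for d in definitions if apply_outcome(r, d)[0] == 1
        )
        if flagged:
            counts[flagged] = counts.get(flagged, 0) + 1
    return counts
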