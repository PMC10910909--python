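import numpy as np
import pytest

from ehrprep import default_config, generate_population
from ehrprep.cohort_builder import CohortConfig, build_cohort
from ehrprep.synthetic_ehr import DAYS_PER_YEAR, Event, PatientRecord


@pytest.fixture(scope="session")
def small_population():
    """A modest deterministic population shared by read-only tests."""
    cfg = default_config(n_patients=4000, seed=1234)
    records, truths = generate_population(cfg)
    return cfg, records, truths


@pytest.fixture(scope="session")
def small_cohort(small_population):
    cfg, records, _ = small_population
    rows = build_cohort(records, CohortConfig(data_window_end=cfg.window_days))
    return rows


def make_record(
    patient_id=0,
    female=0,
    age_years=50,
    start=0,
    end=12 * DAYS_PER_YEAR,
    events=(),
):
    """Hand-built patient for targeted cohort/outcome tests."""
    rec = PatientRecord(
        patient_id=patient_id,
        female=female,
        birth_day=start - age_years * DAYS_PER_YEAR,
        registration_start=start,
        registration_end=end,
        events=list(events),
    )
    rec.sort_events()
    return rec


@pytest.fixture
def rng():
    return np.random.default_rng(99)
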