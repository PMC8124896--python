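import numpy as np
import pytest
from hypothesis import settings

from pnetrecur import SyntheticConfig, generate_cohort
from pnetrecur.records import PatientRecord

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_record(pid="p1", **kwargs):
    """Minimal eligible record; override any field."""
    defaults = dict(
        grade="G1",
        margin="R0",
        genetic_syndrome=False,
        synchronous_metastases=False,
        recurrence=False,
        rfs_months=60.0,
        os_months=60.0,
        os_event=False,
    )
    defaults.update(kwargs)
    return PatientRecord(patient_id=pid, **defaults)


def make_recurrence(pid="r1", rfs=12.0, prs=10.0, prs_event=True, **kwargs):
    kwargs.setdefault("recurrence_sites", frozenset({"liver"}))
    return make_record(
        pid,
        recurrence=True,
        rfs_months=rfs,
        prs_months=prs,
        prs_event=prs_event,
        os_months=rfs + prs,
        os_event=prs_event,
        **kwargs,
    )


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig()


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across tests (seed fixed)."""
    records, truth = generate_cohort(SyntheticConfig(seed=12345))
    return records, truth


@pytest.fixture(scope="session")
def recurred(cohort):
    records, _ = cohort
    return [r for r in records if r.recurrence]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
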