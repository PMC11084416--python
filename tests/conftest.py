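import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from aldress.causality import default_table
from aldress.records import (
    Dechallenge,
    DrugExposure,
    EosinophiliaGrade,
    Group,
    ImmunologyResult,
    ImmunoTestResult,
    MicrobiologyResult,
    Notoriety,
    Pathogen,
    PatientRecord,
    Rechallenge,
    RegiscarInputs,
    Sex,
    TernaryFlag,
    TestMethod,
    TestResult,
)

INDEX = dt.date(2020, 3, 1)


def make_regiscar(**kw) -> RegiscarInputs:
    """Gate-passing inputs (total +4 under the default table) unless overridden."""
    base = dict(
        fever_ge_38_5=TernaryFlag.yes,
        lymphadenopathy=TernaryFlag.yes,
        eosinophilia_grade=EosinophiliaGrade.marked,
        atypical_lymphocytes=TernaryFlag.no,
        skin_extent_gt50=TernaryFlag.no,
        rash_suggestive=TernaryFlag.yes,
        organs_involved=0,
        resolution_ge_15_days=TernaryFlag.yes,
        alternative_causes_excluded=TernaryFlag.no,
    )
    base.update(kw)
    return RegiscarInputs(**base)


def make_exposure(latency: int = 23, **kw) -> DrugExposure:
    base = dict(
        drug_name="lamotrigine",
        start_date=INDEX - dt.timedelta(days=latency),
        stop_date=INDEX + dt.timedelta(days=2),
        notoriety=Notoriety.well_known,
        dechallenge=Dechallenge.improved_after_withdrawal,
        rechallenge=Rechallenge.not_done,
        is_culprit_truth=True,
    )
    base.update(kw)
    return DrugExposure(**base)


def make_patient(exposures=None, **kw) -> PatientRecord:
    base = dict(
        patient_id="T001",
        age=41.0,
        sex=Sex.female,
        index_date=INDEX,
        resolution_date=INDEX + dt.timedelta(days=20),
        regiscar=make_regiscar(),
        microbiology=[
            MicrobiologyResult(
                pathogen=Pathogen.cmv, method=TestMethod.pcr, result=TestResult.negative
            )
        ],
        immunology=ImmunologyResult(),
        group=Group.case,
    )
    base["exposures"] = exposures if exposures is not None else [make_exposure()]
    base.update(kw)
    return PatientRecord(**base)


@pytest.fixture(scope="session")
def aldress_table():
    return default_table("aldress")


@pytest.fixture(scope="session")
def sefv_table():
    return default_table("sefv")


@pytest.fixture(scope="session")
def regiscar_table():
    return default_table("regiscar")


@pytest.fixture
def textbook_case():
    """Single-drug case: compatible chronology, improvement on withdrawal,
    well-known drug, negative infection screen, LTT not done."""
    return make_patient()
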