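"""Score-table engine, chronology windows, and the two causality algorithms."""

import datetime as dt

import pytest
from hypothesis import given
from hypothesis import strategies as st

from aldress.causality import (
    Compatibility,
    ConfigurationError,
    GateNotMetError,
    assess_chronology_aldress,
    assess_chronology_sefv,
    assess_cohort,
    classify,
    default_table,
    load_score_table,
    score_drug,
    score_levels,
    score_patient_drug,
)
from aldress.records import (
    Dechallenge,
    Group,
    ImmunologyResult,
    ImmunoTestResult,
    MicrobiologyResult,
    Notoriety,
    Pathogen,
    TernaryFlag,
)
from aldress.records import TestResult as LabResult

from conftest import INDEX, make_exposure, make_patient, make_regiscar


# ---------------------------------------------------------------------------
# Chronology windows
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "latency,expected",
    [
        (1, Compatibility.compatible),
        (4, Compatibility.compatible),
        (7, Compatibility.compatible),
        (8, Compatibility.partially_compatible),
        (14, Compatibility.partially_compatible),
        (21, Compatibility.partially_compatible),
        (22, Compatibility.incompatible),
        (60, Compatibility.incompatible),
        (0, Compatibility.excluding),
        (-1, Compatibility.excluding),
    ],
)
def test_sefv_chronology_windows(latency, expected):
    finding = assess_chronology_sefv(make_exposure(latency=latency, stop_date=None), INDEX)
    assert finding.compatibility is expected
    assert finding.latency_days == latency


@pytest.mark.parametrize(
    "latency,expected",
    [
        (15, Compatibility.compatible),
        (23, Compatibility.compatible),
        (56, Compatibility.compatible),
        (8, Compatibility.partially_compatible),
        (14, Compatibility.partially_compatible),
        (57, Compatibility.partially_compatible),
        (90, Compatibility.partially_compatible),
        (1, Compatibility.incompatible),
        (7, Compatibility.incompatible),
        (120, Compatibility.incompatible),
        (-1, Compatibility.excluding),
    ],
)
def test_aldress_chronology_windows(latency, expected):
    finding = assess_chronology_aldress(make_exposure(latency=latency, stop_date=None), INDEX)
    assert finding.compatibility is expected


# ---------------------------------------------------------------------------
# ALDRESS scoring
# ---------------------------------------------------------------------------


def test_textbook_single_drug_case_scores_eight_and_is_related(
    textbook_case, aldress_table
):
    a = score_drug(textbook_case, textbook_case.exposures[0], aldress_table)
    assert a.per_item_points == {
        "chronology": 3,
        "dechallenge": 2,
        "rechallenge": 0,
        "notoriety": 2,
        "alternative_infection": 1,
        "immunology": 0,
        "concomitant_suspect": 0,
    }
    assert a.net_score == 8
    assert a.related is True
    assert a.category == "probable"


def test_negative_ltt_and_active_cmv_strictly_lower_the_score(
    textbook_case, aldress_table
):
    baseline = score_drug(textbook_case, textbook_case.exposures[0], aldress_table)
    worse = make_patient(
        microbiology=[
            MicrobiologyResult(pathogen=Pathogen.cmv, result=LabResult.positive)
        ],
        immunology=ImmunologyResult(ltt=ImmunoTestResult.negative),
    )
    a = score_drug(worse, worse.exposures[0], aldress_table)
    assert a.net_score < baseline.net_score
    assert a.net_score == 4  # 3 + 2 + 2 - 2 - 1


def test_regiscar_gate_blocks_aldress_but_not_sefv(aldress_table, sefv_table):
    excluded = make_patient(
        regiscar=make_regiscar(
            lymphadenopathy=TernaryFlag.no,
            rash_suggestive=TernaryFlag.unknown,
        )
    )  # RegiSCAR total +2: not > +2
    with pytest.raises(GateNotMetError, match=r"\+2"):
        score_drug(excluded, excluded.exposures[0], aldress_table)
    sefv = score_drug(excluded, excluded.exposures[0], sefv_table)
    assert sefv.algorithm == "sefv"


def test_assess_cohort_yields_one_assessment_per_exposure(aldress_table):
    cases = [
        make_patient(patient_id=f"C{i}") for i in range(7)
    ]
    control = make_patient(
        patient_id="K1",
        group=Group.control,
        exposures=[
            make_exposure(),
            make_exposure(drug_name="paracetamol", latency=3, notoriety=Notoriety.unknown),
            make_exposure(drug_name="omeprazole", latency=5, notoriety=Notoriety.unknown),
        ],
    )
    out = assess_cohort(cases + [control], aldress_table)
    assert len(out) == 7 + 3
    assert [a.patient_id for a in out[-3:]] == ["K1"] * 3
    for a in out:
        assert a.net_score == sum(a.per_item_points.values())


def test_repeated_episodes_score_the_most_compatible_one(aldress_table):
    episodes = [
        make_exposure(latency=200),  # incompatible
        make_exposure(latency=23),  # compatible
    ]
    patient = make_patient(exposures=episodes, group=Group.control)
    a = score_patient_drug(patient, "lamotrigine", aldress_table)
    assert a.per_item_points["chronology"] == 3


# ---------------------------------------------------------------------------
# Classification and binary rules
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "algorithm,score,related",
    [
        ("aldress", 7, False),
        ("aldress", 8, True),
        ("sefv", 6, False),
        ("sefv", 7, True),
    ],
)
def test_positivity_thresholds_are_strict(algorithm, score, related):
    band, call = classify(score, default_table(algorithm))
    assert call is related


def test_sefv_nonpositive_scores_are_unlikely_and_unrelated(sefv_table):
    for score in range(sefv_table.analytic_min, 1):
        band, related = classify(score, sefv_table)
        assert band == "unlikely"
        assert related is False
        assert classify(score, sefv_table, rule="category")[1] is False


def test_sefv_binary_rules_disagree_in_the_possible_band(sefv_table):
    # category rule: possible (4-5) is related; threshold rule (>6) is not
    for score in (4, 5, 6):
        assert classify(score, sefv_table, rule="threshold")[1] is False
    assert classify(4, sefv_table, rule="category")[1] is True


# ---------------------------------------------------------------------------
# Engine properties
# ---------------------------------------------------------------------------


def test_engine_is_table_agnostic(textbook_case, aldress_table):
    """Swapping the table on identical derived levels changes only the points."""
    doubled = aldress_table.model_copy(
        update={
            "items": tuple(
                it.model_copy(update={"levels": {k: 2 * v for k, v in it.levels.items()}})
                for it in aldress_table.items
            ),
            "category_bands": (
                aldress_table.category_bands[0].model_copy(
                    update={"min_score": -24, "max_score": 28}
                ),
            ),
            "binary_map": None,
        }
    )
    levels = {
        "chronology": "compatible",
        "dechallenge": "improved",
        "rechallenge": "not_done",
        "notoriety": "well_known",
        "alternative_infection": "screens_negative",
        "immunology": "not_done",
        "concomitant_suspect": "none",
    }
    a = score_levels("p", "d", levels, aldress_table)
    b = score_levels("p", "d", levels, doubled)
    assert b.net_score == 2 * a.net_score


def test_band_gap_is_a_configuration_error():
    config = {
        "algorithm": "toy",
        "positivity_threshold": 1,
        "items": [{"id": "x", "levels": {"lo": -1, "hi": 2}}],
        "bands": [
            {"name": "a", "min_score": -1, "max_score": -1},
            {"name": "b", "min_score": 1, "max_score": 2},  # omits score 0
        ],
    }
    with pytest.raises(ConfigurationError, match="gap"):
        load_score_table(config)


def test_unknown_level_is_a_configuration_error(aldress_table):
    with pytest.raises(ConfigurationError, match="no level"):
        aldress_table.points("chronology", "simultaneous")


def test_shipped_defaults_load_with_documented_shapes(aldress_table, sefv_table):
    assert aldress_table.positivity_threshold == 7
    assert len(sefv_table.items) == 7
    assert [it.id for it in sefv_table.items] == [
        "chronology",
        "literature",
        "withdrawal",
        "rechallenge",
        "alternative_cause",
        "contributing_factors",
        "complementary_explorations",
    ]


_LEVEL_ORDER = {
    "chronology": ["excluding", "incompatible", "partially_compatible", "compatible"],
    "dechallenge": ["not_improved", "not_withdrawn", "unassessable", "improved"],
    "rechallenge": ["negative", "not_done", "positive"],
    "notoriety": ["unknown", "occasionally_reported", "well_known"],
    "alternative_infection": ["positive", "not_recorded", "screens_negative"],
    "immunology": ["negative", "not_done", "patch_positive", "ltt_positive"],
    "concomitant_suspect": ["penalty", "none"],
}


@given(
    levels=st.fixed_dictionaries(
        {item: st.sampled_from(order) for item, order in _LEVEL_ORDER.items()}
    ),
    item=st.sampled_from(sorted(_LEVEL_ORDER)),
)
def test_upgrading_one_item_level_never_lowers_score_or_flips_to_unrelated(levels, item):
    table = default_table("aldress")
    order = _LEVEL_ORDER[item]
    upgraded = dict(levels)
    upgraded[item] = order[-1]  # best level
    a = score_levels("p", "d", levels, table)
    b = score_levels("p", "d", upgraded, table)
    assert b.net_score >= a.net_score
    if a.related:
        assert b.related
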