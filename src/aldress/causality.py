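"""Declarative score-table engine and the two drug-causality algorithms.

The engine is table-agnostic: an algorithm is (a) a :class:`ScoreTable`
mapping each item's level to integer points, with a strict positivity
threshold and contiguous category bands, and (b) a *level deriver* that
turns a (patient, exposure) pair into one level per item. SEFV and ALDRESS
share the engine and differ only in their tables and derivers.

Two binary ("related"/"unrelated") rules are available:

* ``threshold`` (default) — related iff ``net_score > positivity_threshold``,
  the rule used for validation (ALDRESS ``> 7``, SEFV ``> 6``);
* ``category`` — related iff the category band maps to related in the
  table's ``binary_map`` (the classical unlikely/conditional vs
  possible/probable/definite split). For SEFV the two rules disagree for
  scores 4-6; the strict threshold wins by default.

ALDRESS scoring is gated on the RegiSCAR DRESS validation score: a patient
whose RegiSCAR total is not strictly greater than +2 cannot be assessed and
raises :class:`GateNotMetError`.
"""

from __future__ import annotations

import datetime as dt
import functools
import hashlib
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .records import (
    NOTORIETY_RANK,
    Dechallenge,
    DrugExposure,
    ImmunoTestResult,
    PatientRecord,
    Rechallenge,
    TestResult,
)

__all__ = [
    "ConfigurationError",
    "GateNotMetError",
    "ScoreItem",
    "CategoryBand",
    "ScoreTable",
    "load_score_table",
    "default_table",
    "Overlap",
    "Compatibility",
    "ChronologyFinding",
    "assess_chronology_sefv",
    "assess_chronology_aldress",
    "CausalityAssessment",
    "classify",
    "score_levels",
    "score_drug",
    "assess_cohort",
    "patient_level_calls",
    "micro_level",
    "immunology_level",
]


class ConfigurationError(ValueError):
    """A score-table config is internally inconsistent or incomplete."""


class GateNotMetError(ValueError):
    """ALDRESS precondition failure: RegiSCAR inclusion score not > +2."""

    def __init__(self, patient_id: str, regiscar_total: int):
        self.patient_id = patient_id
        self.regiscar_total = regiscar_total
        super().__init__(
            f"patient {patient_id!r}: RegiSCAR total {regiscar_total:+d} does not "
            f"meet the inclusion gate (> +2) required for ALDRESS assessment"
        )


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------


class ScoreItem(BaseModel):
    model_config = ConfigDict(frozen=True)

    id: str
    description: str = ""
    levels: Mapping[str, int]

    @model_validator(mode="after")
    def _nonempty(self) -> "ScoreItem":
        if not self.levels:
            raise ValueError(f"item {self.id!r} has no levels")
        return self


class CategoryBand(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    min_score: int
    max_score: int

    @model_validator(mode="after")
    def _ordered(self) -> "CategoryBand":
        if self.max_score < self.min_score:
            raise ValueError(f"band {self.name!r}: max_score < min_score")
        return self


class ScoreTable(BaseModel):
    """Point allocation, positivity threshold, and category bands for one algorithm."""

    model_config = ConfigDict(frozen=True)

    algorithm_name: str
    items: tuple[ScoreItem, ...] = Field(min_length=1)
    positivity_threshold: int
    category_bands: tuple[CategoryBand, ...] = Field(min_length=1)
    binary_map: Optional[Mapping[str, str]] = None

    @model_validator(mode="after")
    def _validate_table(self) -> "ScoreTable":
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate item ids in table {self.algorithm_name!r}")
        lo, hi = self.analytic_min, self.analytic_max
        bands = sorted(self.category_bands, key=lambda b: b.min_score)
        if bands[0].min_score > lo or bands[-1].max_score < hi:
            raise ValueError(
                f"table {self.algorithm_name!r}: bands cover "
                f"[{bands[0].min_score}, {bands[-1].max_score}] but reachable scores "
                f"span [{lo}, {hi}]"
            )
        for a, b in zip(bands, bands[1:]):
            if b.min_score != a.max_score + 1:
                raise ValueError(
                    f"table {self.algorithm_name!r}: bands {a.name!r} and {b.name!r} "
                    f"{'overlap' if b.min_score <= a.max_score else 'leave a gap'} "
                    f"between scores {a.max_score} and {b.min_score}"
                )
        if self.binary_map is not None:
            missing = {b.name for b in bands} - set(self.binary_map)
            if missing:
                raise ValueError(
                    f"table {self.algorithm_name!r}: binary_map misses bands {sorted(missing)}"
                )
            bad = set(self.binary_map.values()) - {"related", "unrelated"}
            if bad:
                raise ValueError(f"binary_map values must be related/unrelated, got {sorted(bad)}")
        return self

    @property
    def analytic_min(self) -> int:
        return sum(min(it.levels.values()) for it in self.items)

    @property
    def analytic_max(self) -> int:
        return sum(max(it.levels.values()) for it in self.items)

    def points(self, item_id: str, level: str) -> int:
        for it in self.items:
            if it.id == item_id:
                try:
                    return it.levels[level]
                except KeyError:
                    raise ConfigurationError(
                        f"table {self.algorithm_name!r}: item {item_id!r} has no "
                        f"level {level!r} (known: {sorted(it.levels)})"
                    ) from None
        raise ConfigurationError(
            f"table {self.algorithm_name!r} has no item {item_id!r}"
        )

    def band(self, score: int) -> str:
        for b in self.category_bands:
            if b.min_score <= score <= b.max_score:
                return b.name
        raise ConfigurationError(
            f"table {self.algorithm_name!r}: score {score} falls outside every band"
        )

    def checksum(self) -> str:
        """Stable digest of the table content, for run provenance logs."""
        canon = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _table_from_dict(doc: dict) -> ScoreTable:
    try:
        return ScoreTable.model_validate(
            {
                "algorithm_name": doc["algorithm"],
                "items": doc["items"],
                "positivity_threshold": doc["positivity_threshold"],
                "category_bands": doc["bands"],
                "binary_map": doc.get("binary"),
            }
        )
    except KeyError as exc:
        raise ConfigurationError(f"score-table config misses key {exc}") from exc
    except ValidationError as exc:
        first = exc.errors()[0]
        raise ConfigurationError(
            f"invalid score table: {'.'.join(str(x) for x in first['loc'])}: {first['msg']}"
        ) from exc


def load_score_table(config: Union[str, Path, dict]) -> ScoreTable:
    """Load and validate a :class:`ScoreTable` from a YAML file or a dict."""
    if isinstance(config, dict):
        return _table_from_dict(config)
    text = Path(config).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{config}: expected a mapping at top level")
    return _table_from_dict(doc)


@functools.lru_cache(maxsize=None)
def default_table(name: str) -> ScoreTable:
    """Shipped default table: ``aldress``, ``sefv`` or ``regiscar``."""
    if name not in {"aldress", "sefv", "regiscar"}:
        raise ConfigurationError(f"no shipped table named {name!r}")
    ref = resources.files("aldress").joinpath(f"tables/{name}.yaml")
    return _table_from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# Chronology
# ---------------------------------------------------------------------------


class Overlap(str, Enum):
    onset_during_exposure = "onset_during_exposure"
    onset_after_stop = "onset_after_stop"
    onset_before_start = "onset_before_start"


class Compatibility(str, Enum):
    compatible = "compatible"
    partially_compatible = "partially_compatible"
    incompatible = "incompatible"
    excluding = "excluding"


class ChronologyFinding(BaseModel):
    model_config = ConfigDict(frozen=True)

    latency_days: int
    overlap: Overlap
    compatibility: Compatibility

    @model_validator(mode="after")
    def _consistent(self) -> "ChronologyFinding":
        if self.overlap is Overlap.onset_before_start and self.compatibility is not Compatibility.excluding:
            raise ValueError("onset before drug start forces compatibility=excluding")
        return self


def _overlap(exposure: DrugExposure, index_date: dt.date) -> Overlap:
    if exposure.start_date > index_date:
        return Overlap.onset_before_start
    if exposure.stop_date is not None and exposure.stop_date < index_date:
        return Overlap.onset_after_stop
    return Overlap.onset_during_exposure


def assess_chronology_sefv(exposure: DrugExposure, index_date: dt.date) -> ChronologyFinding:
    """SEFV latency windows: 1-7 d compatible, 8-21 d partially compatible,
    > 21 d incompatible; a drug started on or after onset is excluding."""
    latency = (index_date - exposure.start_date).days
    if latency <= 0:
        compat = Compatibility.excluding
    elif latency <= 7:
        compat = Compatibility.compatible
    elif latency <= 21:
        compat = Compatibility.partially_compatible
    else:
        compat = Compatibility.incompatible
    ov = _overlap(exposure, index_date)
    if ov is Overlap.onset_before_start:
        compat = Compatibility.excluding
    return ChronologyFinding(latency_days=latency, overlap=ov, compatibility=compat)


def assess_chronology_aldress(exposure: DrugExposure, index_date: dt.date) -> ChronologyFinding:
    """DRESS-specific latency windows centred on the typical 2-8 week onset:
    15-56 d compatible, 8-14 or 57-90 d partially compatible, 1-7 or > 90 d
    incompatible; a drug started on or after onset is excluding."""
    latency = (index_date - exposure.start_date).days
    if latency <= 0:
        compat = Compatibility.excluding
    elif 15 <= latency <= 56:
        compat = Compatibility.compatible
    elif 8 <= latency <= 14 or 57 <= latency <= 90:
        compat = Compatibility.partially_compatible
    else:
        compat = Compatibility.incompatible
    ov = _overlap(exposure, index_date)
    if ov is Overlap.onset_before_start:
        compat = Compatibility.excluding
    return ChronologyFinding(latency_days=latency, overlap=ov, compatibility=compat)


# ---------------------------------------------------------------------------
# Level derivation
# ---------------------------------------------------------------------------


def micro_level(patient: PatientRecord) -> str:
    """Collapse the microbiology panel into one alternative-cause level.

    Any positive result offers an alternative infectious explanation; with no
    positives, at least one recorded negative counts as a (partial) negative
    screen; an empty panel carries no information.
    """
    results = [m.result for m in patient.microbiology]
    if any(r is TestResult.positive for r in results):
        return "positive"
    if any(r is TestResult.negative for r in results):
        return "screens_negative"
    return "not_recorded"


def immunology_level(patient: PatientRecord) -> str:
    imm = patient.immunology
    if imm.ltt is ImmunoTestResult.positive:
        return "ltt_positive"
    if imm.patch_test is ImmunoTestResult.positive:
        return "patch_positive"
    if imm.ltt is ImmunoTestResult.negative or imm.patch_test is ImmunoTestResult.negative:
        return "negative"
    return "not_done"


def _has_concomitant_suspect(patient: PatientRecord, exposure: DrugExposure) -> bool:
    rank = NOTORIETY_RANK[exposure.notoriety]
    return any(
        other is not exposure and NOTORIETY_RANK[other.notoriety] >= rank
        for other in patient.exposures
    )


_DECHALLENGE_LEVEL = {
    Dechallenge.improved_after_withdrawal: "improved",
    Dechallenge.not_improved: "not_improved",
    Dechallenge.not_withdrawn: "not_withdrawn",
    Dechallenge.unassessable: "unassessable",
}


def _aldress_levels(patient: PatientRecord, exposure: DrugExposure) -> dict[str, str]:
    chron = assess_chronology_aldress(exposure, patient.index_date)
    return {
        "chronology": chron.compatibility.value,
        "dechallenge": _DECHALLENGE_LEVEL[exposure.dechallenge],
        "rechallenge": exposure.rechallenge.value,
        "notoriety": exposure.notoriety.value,
        "alternative_infection": micro_level(patient),
        "immunology": immunology_level(patient),
        "concomitant_suspect": (
            "penalty" if _has_concomitant_suspect(patient, exposure) else "none"
        ),
    }


def _sefv_levels(patient: PatientRecord, exposure: DrugExposure) -> dict[str, str]:
    chron = assess_chronology_sefv(exposure, patient.index_date)
    micro = micro_level(patient)
    alternative = {
        "positive": "plausible_alternative",
        "screens_negative": "excluded",
        "not_recorded": "no_information",
    }[micro]
    imm = immunology_level(patient)
    return {
        "chronology": chron.compatibility.value,
        "literature": exposure.notoriety.value,
        "withdrawal": _DECHALLENGE_LEVEL[exposure.dechallenge],
        "rechallenge": exposure.rechallenge.value,
        "alternative_cause": alternative,
        "contributing_factors": (
            "present"
            if patient.autoimmune_history.value != "none_or_unknown"
            else "absent"
        ),
        "complementary_explorations": (
            "supportive" if imm in {"ltt_positive", "patch_positive"} else "uninformative"
        ),
    }


LevelDeriver = Callable[[PatientRecord, DrugExposure], dict[str, str]]

DERIVERS: dict[str, LevelDeriver] = {
    "aldress": _aldress_levels,
    "sefv": _sefv_levels,
}


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


class CausalityAssessment(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    drug_name: str
    algorithm: str
    per_item_points: Mapping[str, int]
    net_score: int
    category: str
    related: bool

    @model_validator(mode="after")
    def _sum_invariant(self) -> "CausalityAssessment":
        total = sum(self.per_item_points.values())
        if total != self.net_score:
            raise ValueError(f"net_score {self.net_score} != sum of item points {total}")
        return self


def classify(score: int, table: ScoreTable, rule: str = "threshold") -> tuple[str, bool]:
    """Category band and binary relatedness for a net score.

    The threshold rule is strict: ``score == positivity_threshold`` is
    unrelated, ``score == positivity_threshold + 1`` is related.
    """
    band = table.band(score)
    if rule == "threshold":
        related = score > table.positivity_threshold
    elif rule == "category":
        if table.binary_map is None:
            raise ConfigurationError(
                f"table {table.algorithm_name!r} has no binary_map; category rule unavailable"
            )
        related = table.binary_map[band] == "related"
    else:
        raise ConfigurationError(f"unknown binary rule {rule!r}")
    return band, related


def score_levels(
    patient_id: str,
    drug_name: str,
    levels: Mapping[str, str],
    table: ScoreTable,
    rule: str = "threshold",
) -> CausalityAssessment:
    """Table-agnostic core: itemized points, net score, band, binary call."""
    expected = {it.id for it in table.items}
    if set(levels) != expected:
        raise ConfigurationError(
            f"table {table.algorithm_name!r}: derived items {sorted(levels)} do not "
            f"match table items {sorted(expected)}"
        )
    per_item = {item_id: table.points(item_id, level) for item_id, level in levels.items()}
    net = sum(per_item.values())
    band, related = classify(net, table, rule=rule)
    return CausalityAssessment(
        patient_id=patient_id,
        drug_name=drug_name,
        algorithm=table.algorithm_name,
        per_item_points=per_item,
        net_score=net,
        category=band,
        related=related,
    )


def score_drug(
    patient: PatientRecord,
    exposure: DrugExposure,
    table: ScoreTable,
    rule: str = "threshold",
) -> CausalityAssessment:
    """Assess one (patient, drug exposure) pair with the table's algorithm.

    For ALDRESS the patient must pass the RegiSCAR inclusion gate (total
    score strictly greater than +2); otherwise :class:`GateNotMetError` is
    raised naming the offending score.
    """
    deriver = DERIVERS.get(table.algorithm_name)
    if deriver is None:
        raise ConfigurationError(
            f"no level deriver for algorithm {table.algorithm_name!r}; "
            f"use score_levels() with explicit levels"
        )
    if table.algorithm_name == "aldress":
        from .regiscar import meets_inclusion, regiscar_score

        result = regiscar_score(patient.regiscar)
        if not meets_inclusion(result):
            raise GateNotMetError(patient.patient_id, result.total_score)
    return score_levels(
        patient.patient_id, exposure.drug_name, deriver(patient, exposure), table, rule=rule
    )


def assess_cohort(
    records: list[PatientRecord],
    table: ScoreTable,
    rule: str = "threshold",
) -> list[CausalityAssessment]:
    """One assessment per (patient, exposure) pair, in input order."""
    return [score_drug(p, e, table, rule=rule) for p in records for e in p.exposures]


_COMPAT_ORDER = {
    Compatibility.compatible: 3,
    Compatibility.partially_compatible: 2,
    Compatibility.incompatible: 1,
    Compatibility.excluding: 0,
}


def score_patient_drug(
    patient: PatientRecord,
    drug_name: str,
    table: ScoreTable,
    rule: str = "threshold",
) -> CausalityAssessment:
    """Assess one drug of a patient; with repeated exposure episodes of the
    same drug, the episode with the most compatible chronology is scored."""
    episodes = [e for e in patient.exposures if e.drug_name == drug_name]
    if not episodes:
        raise ValueError(f"patient {patient.patient_id!r} has no exposure to {drug_name!r}")
    chron = (
        assess_chronology_aldress
        if table.algorithm_name == "aldress"
        else assess_chronology_sefv
    )
    best = max(
        episodes,
        key=lambda e: (
            _COMPAT_ORDER[chron(e, patient.index_date).compatibility],
            -abs((patient.index_date - e.start_date).days),
        ),
    )
    return score_drug(patient, best, table, rule=rule)


def patient_level_calls(
    records: list[PatientRecord],
    table: ScoreTable,
    rule: str = "threshold",
) -> tuple[list[bool], list[bool]]:
    """Patient-level (truth, predicted) vectors for diagnostic evaluation.

    Truth is the case/control label (case = the single administered drug is
    the culprit, i.e. causality is attributable). The algorithm's
    patient-level call is positive when it flags *any* of the patient's
    suspected drugs as related. Unlabeled patients are rejected.
    """
    truth, predicted = [], []
    for p in records:
        if p.group.value == "unlabeled":
            raise ValueError(
                f"patient {p.patient_id!r} has no case/control label; "
                f"evaluation requires the 'group' column"
            )
        truth.append(p.group.value == "case")
        calls = [score_drug(p, e, table, rule=rule).related for e in p.exposures]
        predicted.append(any(calls))
    return truth, predicted
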