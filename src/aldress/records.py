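"""Typed domain model for DRESS drug-causality assessment, with CSV/JSON readers and writers.

A cohort is a list of :class:`PatientRecord`. Two interchange formats are
supported:

* **CSV** — one row per (patient, drug) pair. Patient-level columns are
  repeated on every row belonging to the same ``patient_id`` and must be
  identical across those rows; a mismatch is an error, never a silent
  overwrite. Microbiology is encoded as one column per pathogen
  (``micro_cmv`` etc.) holding ``method:result`` (e.g. ``pcr:positive``);
  an empty cell means the test was not recorded.
* **JSON** — a top-level array of nested patient objects mirroring
  :class:`PatientRecord`.

Dates are ISO-8601 calendar dates. All intervals are closed in whole days;
the latency ("time to onset") of an exposure is ``index_date - start_date``
in days, with day 0 meaning the same day. Missing categorical information
is always an explicit enum member (``unknown``, ``not_recorded``,
``not_done``), never an absent field, so scoring rules can address it
deterministically.
"""

from __future__ import annotations

import datetime as dt
import io
import json
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Optional, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

__all__ = [
    "Sex",
    "AutoimmuneHistory",
    "Group",
    "Notoriety",
    "Dechallenge",
    "Rechallenge",
    "Pathogen",
    "TestMethod",
    "TestResult",
    "TernaryFlag",
    "BiopsyFinding",
    "EosinophiliaGrade",
    "ImmunoTestResult",
    "RegiscarInputs",
    "MicrobiologyResult",
    "ImmunologyResult",
    "DrugExposure",
    "PatientRecord",
    "CohortParseError",
    "read_cohort",
    "write_cohort",
]


class CohortParseError(ValueError):
    """Raised when an interchange document violates the cohort schema."""


class Sex(str, Enum):
    male = "male"
    female = "female"


class AutoimmuneHistory(str, Enum):
    none_or_unknown = "none_or_unknown"
    rheumatoid_arthritis = "rheumatoid_arthritis"
    psoriatic_arthritis = "psoriatic_arthritis"
    ankylosing_spondylitis = "ankylosing_spondylitis"
    other = "other"


class Group(str, Enum):
    case = "case"
    control = "control"
    unlabeled = "unlabeled"


class Notoriety(str, Enum):
    """Strength of the prior literature association drug <-> reaction."""

    well_known = "well_known"
    occasionally_reported = "occasionally_reported"
    unknown = "unknown"


#: Ordering used when comparing notorieties between concomitant drugs.
NOTORIETY_RANK = {
    Notoriety.well_known: 2,
    Notoriety.occasionally_reported: 1,
    Notoriety.unknown: 0,
}


class Dechallenge(str, Enum):
    improved_after_withdrawal = "improved_after_withdrawal"
    not_improved = "not_improved"
    not_withdrawn = "not_withdrawn"
    unassessable = "unassessable"


class Rechallenge(str, Enum):
    positive = "positive"
    negative = "negative"
    not_done = "not_done"


class Pathogen(str, Enum):
    hhv6 = "hhv6"
    ebv = "ebv"
    cmv = "cmv"
    hsv = "hsv"
    vzv = "vzv"
    parvovirus = "parvovirus"
    hcv = "hcv"
    hbv = "hbv"
    hiv = "hiv"
    mycobacteria = "mycobacteria"


_PATHOGEN_ORDER = {p: i for i, p in enumerate(Pathogen)}


class TestMethod(str, Enum):
    pcr = "pcr"
    immunoassay = "immunoassay"
    unspecified = "unspecified"


class TestResult(str, Enum):
    positive = "positive"
    negative = "negative"
    not_recorded = "not_recorded"


class TernaryFlag(str, Enum):
    yes = "yes"
    no = "no"
    unknown = "unknown"


class BiopsyFinding(str, Enum):
    yes = "yes"
    no = "no"
    not_done = "not_done"


class EosinophiliaGrade(str, Enum):
    none = "none"
    moderate = "moderate"
    marked = "marked"
    unknown = "unknown"


class ImmunoTestResult(str, Enum):
    positive = "positive"
    negative = "negative"
    not_done = "not_done"


class RegiscarInputs(BaseModel):
    """Raw clinical findings entering the RegiSCAR DRESS validation score."""

    model_config = ConfigDict(frozen=True)

    fever_ge_38_5: TernaryFlag = TernaryFlag.unknown
    lymphadenopathy: TernaryFlag = TernaryFlag.unknown
    eosinophilia_grade: EosinophiliaGrade = EosinophiliaGrade.unknown
    atypical_lymphocytes: TernaryFlag = TernaryFlag.unknown
    skin_extent_gt50: TernaryFlag = TernaryFlag.unknown
    rash_suggestive: TernaryFlag = TernaryFlag.unknown
    biopsy_suggestive: BiopsyFinding = BiopsyFinding.not_done
    organs_involved: int = Field(0, ge=0, le=10)
    resolution_ge_15_days: TernaryFlag = TernaryFlag.unknown
    alternative_causes_excluded: TernaryFlag = TernaryFlag.unknown


class MicrobiologyResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    pathogen: Pathogen
    method: TestMethod = TestMethod.unspecified
    result: TestResult = TestResult.not_recorded


class ImmunologyResult(BaseModel):
    """Lymphocyte transformation test and epicutaneous patch test outcome."""

    model_config = ConfigDict(frozen=True)

    ltt: ImmunoTestResult = ImmunoTestResult.not_done
    patch_test: ImmunoTestResult = ImmunoTestResult.not_done


class DrugExposure(BaseModel):
    model_config = ConfigDict(frozen=True)

    drug_name: str
    start_date: dt.date
    stop_date: Optional[dt.date] = None
    notoriety: Notoriety = Notoriety.unknown
    dechallenge: Dechallenge = Dechallenge.unassessable
    rechallenge: Rechallenge = Rechallenge.not_done
    is_culprit_truth: Optional[bool] = None

    @model_validator(mode="after")
    def _check_dates(self) -> "DrugExposure":
        if self.stop_date is not None and self.stop_date < self.start_date:
            raise ValueError(
                f"stop_date {self.stop_date} precedes start_date {self.start_date} "
                f"for drug {self.drug_name!r}"
            )
        return self


class PatientRecord(BaseModel):
    """One subject of a DRESS case-control cohort.

    ``group == case`` means the culprit drug was the only drug administered
    (exactly one exposure); ``group == control`` means more than one drug was
    under suspicion (at least two exposures).
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    age: float = Field(ge=0)
    sex: Sex
    autoimmune_history: AutoimmuneHistory = AutoimmuneHistory.none_or_unknown
    index_date: dt.date
    resolution_date: Optional[dt.date] = None
    regiscar: RegiscarInputs = RegiscarInputs()
    exposures: list[DrugExposure] = Field(min_length=1)
    microbiology: list[MicrobiologyResult] = Field(default_factory=list)
    immunology: ImmunologyResult = ImmunologyResult()
    group: Group = Group.unlabeled

    @field_validator("microbiology")
    @classmethod
    def _normalize_microbiology(
        cls, v: list[MicrobiologyResult]
    ) -> list[MicrobiologyResult]:
        # Canonical form: drop not_recorded entries (absent pathogen means
        # not recorded), forbid duplicates, sort by pathogen.
        recorded = [m for m in v if m.result is not TestResult.not_recorded]
        seen: set[Pathogen] = set()
        for m in recorded:
            if m.pathogen in seen:
                raise ValueError(f"duplicate microbiology entry for {m.pathogen.value}")
            seen.add(m.pathogen)
        return sorted(recorded, key=lambda m: _PATHOGEN_ORDER[m.pathogen])

    @model_validator(mode="after")
    def _check_invariants(self) -> "PatientRecord":
        if self.resolution_date is not None and self.resolution_date < self.index_date:
            raise ValueError(
                f"patient {self.patient_id!r}: resolution_date {self.resolution_date} "
                f"precedes index_date {self.index_date}"
            )
        n = len(self.exposures)
        if self.group is Group.case and n != 1:
            raise ValueError(
                f"patient {self.patient_id!r}: a case must have exactly one "
                f"exposure, found {n}"
            )
        if self.group is Group.control and n < 2:
            raise ValueError(
                f"patient {self.patient_id!r}: a control must have at least two "
                f"exposures, found {n}"
            )
        return self

    def micro_result(self, pathogen: Pathogen) -> TestResult:
        """Result for one pathogen; absent record means not recorded."""
        for m in self.microbiology:
            if m.pathogen is pathogen:
                return m.result
        return TestResult.not_recorded


# ---------------------------------------------------------------------------
# Tabular (CSV) dialect
# ---------------------------------------------------------------------------

_REGISCAR_FIELDS = list(RegiscarInputs.model_fields)
_PATIENT_COLUMNS = (
    ["patient_id", "age", "sex", "autoimmune_history", "index_date", "resolution_date", "group"]
    + [f"regiscar_{f}" for f in _REGISCAR_FIELDS]
    + [f"micro_{p.value}" for p in Pathogen]
    + ["ltt", "patch_test"]
)
_DRUG_COLUMNS = [
    "drug_name",
    "start_date",
    "stop_date",
    "notoriety",
    "dechallenge",
    "rechallenge",
    "is_culprit_truth",
]
CSV_COLUMNS = _PATIENT_COLUMNS + _DRUG_COLUMNS


def _date_out(d: Optional[dt.date]) -> str:
    return "" if d is None else d.isoformat()


def _record_to_rows(rec: PatientRecord) -> list[dict[str, str]]:
    base: dict[str, str] = {
        "patient_id": rec.patient_id,
        "age": repr(float(rec.age)),
        "sex": rec.sex.value,
        "autoimmune_history": rec.autoimmune_history.value,
        "index_date": rec.index_date.isoformat(),
        "resolution_date": _date_out(rec.resolution_date),
        "group": rec.group.value,
        "ltt": rec.immunology.ltt.value,
        "patch_test": rec.immunology.patch_test.value,
    }
    for f in _REGISCAR_FIELDS:
        v = getattr(rec.regiscar, f)
        base[f"regiscar_{f}"] = str(v) if isinstance(v, int) else v.value
    for p in Pathogen:
        base[f"micro_{p.value}"] = ""
    for m in rec.microbiology:
        base[f"micro_{m.pathogen.value}"] = f"{m.method.value}:{m.result.value}"
    rows = []
    for e in rec.exposures:
        row = dict(base)
        row.update(
            drug_name=e.drug_name,
            start_date=e.start_date.isoformat(),
            stop_date=_date_out(e.stop_date),
            notoriety=e.notoriety.value,
            dechallenge=e.dechallenge.value,
            rechallenge=e.rechallenge.value,
            is_culprit_truth="" if e.is_culprit_truth is None else str(e.is_culprit_truth).lower(),
        )
        rows.append(row)
    return rows


def _cell(row: dict[str, str], col: str, rownum: int) -> str:
    try:
        return row[col]
    except KeyError:
        raise CohortParseError(f"row {rownum}: missing column {col!r}") from None


def _rows_to_record(pid: str, rows: list[tuple[int, dict[str, str]]]) -> PatientRecord:
    first_num, first = rows[0]
    for num, row in rows[1:]:
        for col in _PATIENT_COLUMNS:
            if _cell(row, col, num) != _cell(first, col, first_num):
                raise CohortParseError(
                    f"row {num}: patient-level column {col!r} disagrees with row "
                    f"{first_num} for patient {pid!r} "
                    f"({row[col]!r} != {first[col]!r})"
                )
    micro = []
    for p in Pathogen:
        cell = _cell(first, f"micro_{p.value}", first_num).strip()
        if not cell:
            continue
        try:
            method, result = cell.split(":", 1)
        except ValueError:
            raise CohortParseError(
                f"row {first_num}: field micro_{p.value}: expected 'method:result', got {cell!r}"
            ) from None
        micro.append({"pathogen": p.value, "method": method, "result": result})
    exposures = []
    for num, row in rows:
        exposures.append(
            {
                "drug_name": _cell(row, "drug_name", num),
                "start_date": _cell(row, "start_date", num),
                "stop_date": _cell(row, "stop_date", num) or None,
                "notoriety": _cell(row, "notoriety", num),
                "dechallenge": _cell(row, "dechallenge", num),
                "rechallenge": _cell(row, "rechallenge", num),
                "is_culprit_truth": {"": None, "true": True, "false": False}.get(
                    _cell(row, "is_culprit_truth", num).strip().lower()
                ),
            }
        )
    payload = {
        "patient_id": pid,
        "age": first["age"],
        "sex": first["sex"],
        "autoimmune_history": first["autoimmune_history"],
        "index_date": first["index_date"],
        "resolution_date": first["resolution_date"] or None,
        "group": first["group"],
        "regiscar": {f: first[f"regiscar_{f}"] for f in _REGISCAR_FIELDS},
        "microbiology": micro,
        "immunology": {"ltt": first["ltt"], "patch_test": first["patch_test"]},
        "exposures": exposures,
    }
    try:
        return PatientRecord.model_validate(payload)
    except ValidationError as exc:
        first_err = exc.errors()[0]
        loc = ".".join(str(x) for x in first_err["loc"])
        raise CohortParseError(
            f"patient {pid!r} (rows starting at {first_num}): field {loc}: {first_err['msg']}"
        ) from exc


Source = Union[str, Path, IO[str]]


def _infer_format(source: Source, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt.lower()
    if isinstance(source, (str, Path)):
        suffix = Path(source).suffix.lower().lstrip(".")
        if suffix in {"csv", "json"}:
            return suffix
    raise CohortParseError("format is ambiguous; pass fmt='csv' or fmt='json'")


def read_cohort(source: Source, fmt: Optional[str] = None) -> list[PatientRecord]:
    """Read a cohort from a CSV/JSON path or open text stream.

    Per-drug rows sharing a ``patient_id`` are merged into one
    :class:`PatientRecord`; merging is insensitive to row order apart from
    the order of the exposures themselves.
    """
    fmt = _infer_format(source, fmt)
    if fmt == "csv":
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise CohortParseError(f"missing columns: {', '.join(missing)}")
        grouped: dict[str, list[tuple[int, dict[str, str]]]] = {}
        for i, row in enumerate(df.to_dict(orient="records")):
            pid = row["patient_id"]
            if not pid:
                raise CohortParseError(f"row {i + 2}: empty patient_id")
            grouped.setdefault(pid, []).append((i + 2, row))  # 1-based + header
        return [_rows_to_record(pid, rows) for pid, rows in grouped.items()]
    if fmt == "json":
        if isinstance(source, (str, Path)):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = source.read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise CohortParseError(f"invalid JSON: {exc}") from exc
        if not isinstance(data, list):
            raise CohortParseError("JSON cohort must be a top-level array of patients")
        records = []
        for i, obj in enumerate(data):
            try:
                records.append(PatientRecord.model_validate(obj))
            except ValidationError as exc:
                first_err = exc.errors()[0]
                loc = ".".join(str(x) for x in first_err["loc"])
                raise CohortParseError(
                    f"patient #{i}: field {loc}: {first_err['msg']}"
                ) from exc
        return records
    raise CohortParseError(f"unknown format {fmt!r}")


def write_cohort(
    records: Iterable[PatientRecord],
    sink: Optional[Source] = None,
    fmt: str = "csv",
) -> str:
    """Serialize a cohort; returns the document text and optionally writes it.

    The output is re-readable by :func:`read_cohort` with full fidelity.
    """
    records = list(records)
    fmt = fmt.lower()
    if fmt == "csv":
        rows = [r for rec in records for r in _record_to_rows(rec)]
        df = pd.DataFrame(rows, columns=CSV_COLUMNS)
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        text = buf.getvalue()
    elif fmt == "json":
        text = json.dumps(
            [rec.model_dump(mode="json", exclude_none=False) for rec in records],
            indent=1,
        )
    else:
        raise CohortParseError(f"unknown format {fmt!r}")
    if sink is not None:
        if isinstance(sink, (str, Path)):
            Path(sink).write_text(text, encoding="utf-8")
        else:
            sink.write(text)
    return text
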