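"""Seeded generator of DRESS case-control cohorts with planted ground truth.

The generator emulates the marginal structure of a 37-patient case-control
population: 7 single-drug cases and 30 multi-drug controls, a fixed culprit
drug multinomial (lamotrigine the most frequent at 9/37), mean culprit
latency of 23 days, per-pathogen microbiology positive/negative/missing
rates, LTT outcome rates, and demographic margins (age 41.62 +/- 17.09,
54.1% male). Every generated record passes full record validation, and all
patients satisfy the RegiSCAR > +2 inclusion gate by construction.

Culprit and innocent exposures are drawn from documented "culprit-like"
and "innocent-like" conditional evidence profiles chosen so that the
default ALDRESS table separates cases from controls perfectly. The
``planted_error`` knob then degrades exactly ``case_miss`` case culprits
and promotes exactly ``control_false_alarm`` control innocents, so that a
correctly configured ALDRESS engine misclassifies exactly those patients.
These conditional profiles are a test-fixture contract, not a claim about
any real cohort; see the package methods note for what they do and do not
emulate.
"""

from __future__ import annotations

import datetime as dt
import functools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .records import (
    AutoimmuneHistory,
    BiopsyFinding,
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

__all__ = [
    "CohortProfile",
    "GeneratedCohort",
    "CohortSummary",
    "generate",
    "summarize",
    "DEFAULT_DRUG_COUNTS",
    "DEFAULT_MICROBIOLOGY_COUNTS",
]


#: Culprit-drug frequency table (counts out of 37).
DEFAULT_DRUG_COUNTS: Mapping[str, int] = {
    "amoxicillin": 4,
    "amoxicillin_clavulanic_acid": 7,
    "benznidazole": 1,
    "carbamazepine": 7,
    "cotrimoxazole": 5,
    "eslicarbazepine": 1,
    "lamotrigine": 9,
    "phenytoin": 1,
    "sulfasalazine": 2,
}

#: Per-pathogen (positive, negative, not recorded) counts out of 37. The
#: hepatitis-B screen is not reported separately and defaults to never
#: recorded.
DEFAULT_MICROBIOLOGY_COUNTS: Mapping[Pathogen, tuple[int, int, int]] = {
    Pathogen.mycobacteria: (2, 2, 33),
    Pathogen.ebv: (4, 12, 21),
    Pathogen.hhv6: (0, 17, 20),
    Pathogen.cmv: (7, 14, 16),
    Pathogen.hcv: (0, 16, 21),
    Pathogen.hbv: (0, 0, 37),
    Pathogen.hiv: (0, 17, 20),
    Pathogen.parvovirus: (1, 13, 23),
    Pathogen.hsv: (4, 7, 26),
    Pathogen.vzv: (2, 2, 33),
}

#: Low-notoriety co-medications used for the innocent exposures of controls.
CONCOMITANT_POOL: tuple[str, ...] = (
    "paracetamol",
    "omeprazole",
    "ibuprofen",
    "metamizole",
    "furosemide",
    "enalapril",
    "atorvastatin",
    "amlodipine",
    "salbutamol",
    "levothyroxine",
)

_BASE_DATE = dt.date(2016, 1, 1)


@dataclass(frozen=True)
class CohortProfile:
    """Marginal structure of the simulated cohort.

    ``planted_error = (case_miss, control_false_alarm)`` requests that
    exactly that many case culprits be degraded below the ALDRESS
    positivity threshold and that many control patients receive one
    promoted (false-alarm) exposure.
    """

    n_cases: int = 7
    n_controls: int = 30
    drug_freqs: Mapping[str, float] = field(
        default_factory=lambda: {
            d: c / sum(DEFAULT_DRUG_COUNTS.values()) for d, c in DEFAULT_DRUG_COUNTS.items()
        }
    )
    age_mean: float = 41.62
    age_sd: float = 17.09
    age_range: tuple[float, float] = (16.0, 95.0)
    male_fraction: float = 0.541
    onset_mean_days: float = 23.0
    onset_sd_days: float = 7.0
    compatible_window: tuple[int, int] = (15, 56)
    microbiology_rates: Mapping[Pathogen, tuple[float, float, float]] = field(
        default_factory=lambda: {
            p: (a / 37, b / 37, c / 37)
            for p, (a, b, c) in DEFAULT_MICROBIOLOGY_COUNTS.items()
        }
    )
    # LTT outcomes: 3 positive / 17 negative reported out of 37; the
    # remainder (unreported plus the 13 explicit "not done") is folded into
    # not_done.
    ltt_rates: tuple[float, float, float] = (3 / 37, 17 / 37, 17 / 37)
    patch_positive_given_ltt: float = 2 / 3
    autoimmune_rates: Mapping[AutoimmuneHistory, float] = field(
        default_factory=lambda: {
            AutoimmuneHistory.none_or_unknown: 33 / 38,
            AutoimmuneHistory.rheumatoid_arthritis: 2 / 38,
            AutoimmuneHistory.psoriatic_arthritis: 2 / 38,
            AutoimmuneHistory.ankylosing_spondylitis: 1 / 38,
        }
    )
    planted_error: tuple[int, int] = (0, 0)

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0 or self.n_total < 1:
            raise ValueError("cohort sizes must be nonnegative and total at least 1")
        total = sum(self.drug_freqs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"drug_freqs must sum to 1, got {total}")
        for p, (a, b, c) in self.microbiology_rates.items():
            if not math.isclose(a + b + c, 1.0, abs_tol=1e-9):
                raise ValueError(f"microbiology rates for {p} must sum to 1")
        if not math.isclose(sum(self.ltt_rates), 1.0, abs_tol=1e-9):
            raise ValueError("ltt_rates must sum to 1")
        a, b = self.planted_error
        if a < 0 or b < 0 or a > self.n_cases or b > self.n_controls:
            raise ValueError(
                f"planted_error {self.planted_error} infeasible for "
                f"{self.n_cases} cases / {self.n_controls} controls"
            )


@dataclass(frozen=True)
class GeneratedCohort:
    records: list[PatientRecord]
    seed: int
    profile: CohortProfile


# ---------------------------------------------------------------------------
# Culprit latency: log-normal onset model conditioned on the DRESS-
# compatible chronology window, calibrated so the conditional mean equals
# the configured mean time to onset.
# ---------------------------------------------------------------------------


def _lognorm_params(mean: float, sd: float) -> tuple[float, float]:
    sig2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sig2 / 2.0, math.sqrt(sig2)


def _window_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    mu, sig = _lognorm_params(mean, sd)
    z = norm.cdf((math.log(hi) - mu) / sig) - norm.cdf((math.log(lo) - mu) / sig)
    part = mean * (
        norm.cdf((math.log(hi) - mu - sig**2) / sig)
        - norm.cdf((math.log(lo) - mu - sig**2) / sig)
    )
    return part / z


@functools.lru_cache(maxsize=None)
def _calibrated_latency_params(
    target_mean: float, sd: float, lo: int, hi: int
) -> tuple[float, float, float, float]:
    """(mu, sigma, cdf_lo, cdf_hi) of the underlying log-normal whose
    [lo, hi]-conditioned mean equals ``target_mean``."""

    def f(m: float) -> float:
        return _window_mean(m, sd, lo, hi) - target_mean

    grid = np.linspace(max(1.0, lo / 10), hi * 1.5, 120)
    vals = [f(m) for m in grid]
    bracket = None
    for a, b, fa, fb in zip(grid, grid[1:], vals, vals[1:]):
        if fa == 0.0 or fa * fb < 0:
            bracket = (a, b)
            break
    if bracket is None:
        raise ValueError(
            f"onset mean {target_mean} is unattainable inside the latency window "
            f"[{lo}, {hi}] with sd {sd}"
        )
    m0 = brentq(f, *bracket)
    mu, sig = _lognorm_params(m0, sd)
    cdf = lambda x: norm.cdf((math.log(x) - mu) / sig)  # noqa: E731
    return mu, sig, cdf(lo), cdf(hi)


def _sample_compatible_latency(rng: np.random.Generator, profile: CohortProfile) -> int:
    lo, hi = profile.compatible_window
    mu, sig, c_lo, c_hi = _calibrated_latency_params(
        profile.onset_mean_days, profile.onset_sd_days, lo, hi
    )
    u = rng.uniform(c_lo, c_hi)
    x = math.exp(mu + sig * norm.ppf(u))
    return int(min(max(round(x), lo), hi))


# ---------------------------------------------------------------------------
# Patient-level draws
# ---------------------------------------------------------------------------


def _choice(rng: np.random.Generator, options: Sequence, probs: Sequence[float]):
    return options[int(rng.choice(len(options), p=np.asarray(probs) / np.sum(probs)))]


def _draw_age(rng: np.random.Generator, profile: CohortProfile) -> float:
    lo, hi = profile.age_range
    for _ in range(1000):
        a = rng.normal(profile.age_mean, profile.age_sd)
        if lo <= a <= hi:
            return round(float(a), 1)
    return round((lo + hi) / 2, 1)


def _draw_regiscar(rng: np.random.Generator) -> RegiscarInputs:
    # Floor of marked eosinophilia, suggestive rash, >= 1 organ and slow
    # resolution guarantees a RegiSCAR total of at least +4 (inclusion gate).
    yes, no = TernaryFlag.yes, TernaryFlag.no
    return RegiscarInputs(
        fever_ge_38_5=yes,
        lymphadenopathy=yes if rng.random() < 0.6 else no,
        eosinophilia_grade=EosinophiliaGrade.marked,
        atypical_lymphocytes=yes if rng.random() < 0.5 else no,
        skin_extent_gt50=yes if rng.random() < 0.4 else no,
        rash_suggestive=yes,
        biopsy_suggestive=(
            BiopsyFinding.yes if rng.random() < 0.3 else BiopsyFinding.not_done
        ),
        organs_involved=int(rng.integers(1, 4)),
        resolution_ge_15_days=yes,
        alternative_causes_excluded=yes if rng.random() < 0.7 else TernaryFlag.unknown,
    )


def _draw_microbiology(
    rng: np.random.Generator, profile: CohortProfile
) -> list[MicrobiologyResult]:
    out = []
    for pathogen, (p_pos, p_neg, p_none) in profile.microbiology_rates.items():
        result = _choice(
            rng,
            [TestResult.positive, TestResult.negative, TestResult.not_recorded],
            [p_pos, p_neg, p_none],
        )
        if result is TestResult.not_recorded:
            continue
        method = TestMethod.pcr if rng.random() < 0.7 else TestMethod.immunoassay
        out.append(MicrobiologyResult(pathogen=pathogen, method=method, result=result))
    return out


def _draw_immunology(
    rng: np.random.Generator,
    profile: CohortProfile,
    is_case: bool,
    micro_positive: bool,
) -> ImmunologyResult:
    p_pos, p_neg, p_nd = profile.ltt_rates
    if is_case:
        # LTT positivity is concentrated in the single-drug cases, where the
        # tested drug is unambiguous; the cohort-wide positive rate is
        # preserved in expectation.
        n_cases = max(profile.n_cases, 1)
        p_pos_here = min(1.0, p_pos * profile.n_total / n_cases)
    else:
        p_pos_here = 0.0
    rest = max(1.0 - p_pos_here, 1e-12)
    scale = rest / max(p_neg + p_nd, 1e-12)
    ltt = _choice(
        rng,
        [ImmunoTestResult.positive, ImmunoTestResult.negative, ImmunoTestResult.not_done],
        [p_pos_here, p_neg * scale, p_nd * scale],
    )
    if micro_positive and ltt is ImmunoTestResult.negative:
        # With a documented intercurrent infection the LTT is typically not
        # pursued; this also keeps the combined infection/immunology penalty
        # bounded, which the planting contract relies on.
        ltt = ImmunoTestResult.not_done
    patch = ImmunoTestResult.not_done
    if ltt is ImmunoTestResult.positive and rng.random() < profile.patch_positive_given_ltt:
        patch = ImmunoTestResult.positive
    return ImmunologyResult(ltt=ltt, patch_test=patch)


# Evidence points carried by patient-level findings under the default
# ALDRESS table; used to decide when the culprit-like profile needs a
# documented positive rechallenge to stay above the positivity threshold.
_MICRO_PTS = {"positive": -2, "screens_negative": 1, "not_recorded": 0}
_IMM_PTS = {"ltt_positive": 3, "patch_positive": 2, "negative": -1, "not_done": 0}


def _patient_level_points(micro: list[MicrobiologyResult], imm: ImmunologyResult) -> int:
    results = [m.result for m in micro]
    if any(r is TestResult.positive for r in results):
        m = "positive"
    elif any(r is TestResult.negative for r in results):
        m = "screens_negative"
    else:
        m = "not_recorded"
    if imm.ltt is ImmunoTestResult.positive:
        i = "ltt_positive"
    elif imm.patch_test is ImmunoTestResult.positive:
        i = "patch_positive"
    elif ImmunoTestResult.negative in (imm.ltt, imm.patch_test):
        i = "negative"
    else:
        i = "not_done"
    return _MICRO_PTS[m] + _IMM_PTS[i]


# ---------------------------------------------------------------------------
# Exposure construction
# ---------------------------------------------------------------------------


def _stop_after_index(rng: np.random.Generator, index_date: dt.date) -> dt.date:
    return index_date + dt.timedelta(days=int(rng.integers(0, 4)))


def _culprit_exposure(
    rng: np.random.Generator,
    profile: CohortProfile,
    drug: str,
    index_date: dt.date,
    evidence_points: int,
    diluted: bool,
) -> DrugExposure:
    """Culprit-like evidence profile.

    In a single-drug case the culprit shows the full profile (compatible
    chronology, improvement on withdrawal, well-known drug); when
    patient-level findings would mask it, a documented inadvertent positive
    rechallenge keeps the net score above threshold. In multi-drug controls
    the same drug presents with *diluted* evidence: all suspects were
    withdrawn simultaneously, so dechallenge is unassessable and no
    rechallenge is on record.
    """
    latency = _sample_compatible_latency(rng, profile)
    start = index_date - dt.timedelta(days=latency)
    if diluted:
        withdrawn = rng.random() < 0.8
        return DrugExposure(
            drug_name=drug,
            start_date=start,
            stop_date=_stop_after_index(rng, index_date) if withdrawn else None,
            notoriety=(
                Notoriety.well_known if rng.random() < 0.7 else Notoriety.occasionally_reported
            ),
            dechallenge=Dechallenge.unassessable if withdrawn else Dechallenge.not_withdrawn,
            rechallenge=Rechallenge.not_done,
            is_culprit_truth=True,
        )
    return DrugExposure(
        drug_name=drug,
        start_date=start,
        stop_date=_stop_after_index(rng, index_date),
        notoriety=Notoriety.well_known,
        dechallenge=Dechallenge.improved_after_withdrawal,
        rechallenge=Rechallenge.positive if evidence_points <= 0 else Rechallenge.not_done,
        is_culprit_truth=True,
    )


def _degraded_culprit(
    rng: np.random.Generator, drug: str, index_date: dt.date
) -> DrugExposure:
    """Planted miss: short latency, unassessable dechallenge, modest notoriety."""
    latency = int(rng.integers(8, 15))
    return DrugExposure(
        drug_name=drug,
        start_date=index_date - dt.timedelta(days=latency),
        stop_date=_stop_after_index(rng, index_date),
        notoriety=Notoriety.occasionally_reported,
        dechallenge=Dechallenge.unassessable,
        rechallenge=Rechallenge.not_done,
        is_culprit_truth=True,
    )


def _innocent_exposure(
    rng: np.random.Generator, drug: str, index_date: dt.date
) -> DrugExposure:
    # Co-medications are mostly recent additions (started during the
    # prodrome, days before onset); a minority are long-standing treatments.
    if rng.random() < 0.8:
        latency = int(rng.integers(1, 8))
    else:
        latency = int(rng.integers(8, 91))
    dech = _choice(
        rng,
        [Dechallenge.unassessable, Dechallenge.not_withdrawn, Dechallenge.not_improved],
        [0.6, 0.3, 0.1],
    )
    notor = _choice(
        rng,
        [Notoriety.occasionally_reported, Notoriety.unknown, Notoriety.well_known],
        [0.3, 0.5, 0.2],
    )
    return DrugExposure(
        drug_name=drug,
        start_date=index_date - dt.timedelta(days=latency),
        stop_date=(
            None
            if dech is Dechallenge.not_withdrawn
            else _stop_after_index(rng, index_date)
        ),
        notoriety=notor,
        dechallenge=dech,
        rechallenge=Rechallenge.not_done,
        is_culprit_truth=False,
    )


def _promote_false_alarm(
    rng: np.random.Generator,
    profile: CohortProfile,
    exposures: list[DrugExposure],
    index_date: dt.date,
    evidence_points: int,
) -> list[DrugExposure]:
    """Planted false alarm: one innocent gains the full culprit-like
    evidence profile; every other suspect is capped below well-known
    notoriety so the promoted drug carries no concomitant penalty."""
    innocent_idx = [i for i, e in enumerate(exposures) if not e.is_culprit_truth]
    target = int(rng.choice(innocent_idx))
    out = []
    for i, e in enumerate(exposures):
        if i == target:
            latency = _sample_compatible_latency(rng, profile)
            out.append(
                e.model_copy(
                    update=dict(
                        start_date=index_date - dt.timedelta(days=latency),
                        stop_date=_stop_after_index(rng, index_date),
                        notoriety=Notoriety.well_known,
                        dechallenge=Dechallenge.improved_after_withdrawal,
                        rechallenge=(
                            Rechallenge.positive
                            if evidence_points <= 0
                            else Rechallenge.not_done
                        ),
                    )
                )
            )
        elif e.notoriety is Notoriety.well_known:
            out.append(e.model_copy(update={"notoriety": Notoriety.occasionally_reported}))
        else:
            out.append(e)
    return out


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate(profile: Optional[CohortProfile] = None, seed: int = 0) -> GeneratedCohort:
    """Generate a validated cohort; identical (profile, seed) pairs yield
    byte-identical cohorts."""
    if profile is None:
        profile = CohortProfile()
    rng = np.random.default_rng(seed)
    n_miss, n_fp = profile.planted_error
    miss_idx = set(map(int, rng.choice(profile.n_cases, size=n_miss, replace=False))) if n_miss else set()
    fp_idx = set(map(int, rng.choice(profile.n_controls, size=n_fp, replace=False))) if n_fp else set()

    drugs = list(profile.drug_freqs)
    drug_p = np.array([profile.drug_freqs[d] for d in drugs])

    records: list[PatientRecord] = []
    for i in range(profile.n_total):
        is_case = i < profile.n_cases
        pid = f"P{i + 1:03d}"
        index_date = _BASE_DATE + dt.timedelta(days=int(rng.integers(0, 2500)))
        micro = _draw_microbiology(rng, profile)
        micro_positive = any(m.result is TestResult.positive for m in micro)
        imm = _draw_immunology(rng, profile, is_case, micro_positive)
        evidence = _patient_level_points(micro, imm)
        culprit_drug = str(_choice(rng, drugs, drug_p))

        if is_case:
            if i in miss_idx:
                exposures = [_degraded_culprit(rng, culprit_drug, index_date)]
            else:
                exposures = [
                    _culprit_exposure(
                        rng, profile, culprit_drug, index_date, evidence, diluted=False
                    )
                ]
            group = Group.case
        else:
            n_drugs = int(rng.integers(2, 5))
            pool = [d for d in CONCOMITANT_POOL]
            picks = rng.choice(len(pool), size=n_drugs - 1, replace=False)
            exposures = [
                _culprit_exposure(
                    rng, profile, culprit_drug, index_date, evidence, diluted=True
                )
            ] + [_innocent_exposure(rng, pool[int(k)], index_date) for k in picks]
            order = rng.permutation(len(exposures))
            exposures = [exposures[int(k)] for k in order]
            if (i - profile.n_cases) in fp_idx:
                exposures = _promote_false_alarm(
                    rng, profile, exposures, index_date, evidence
                )
            group = Group.control

        resolution = index_date + dt.timedelta(days=int(rng.integers(15, 46)))
        records.append(
            PatientRecord(
                patient_id=pid,
                age=_draw_age(rng, profile),
                sex=Sex.male if rng.random() < profile.male_fraction else Sex.female,
                autoimmune_history=_choice(
                    rng,
                    list(profile.autoimmune_rates),
                    list(profile.autoimmune_rates.values()),
                ),
                index_date=index_date,
                resolution_date=resolution,
                regiscar=_draw_regiscar(rng),
                exposures=exposures,
                microbiology=micro,
                immunology=imm,
                group=group,
            )
        )
    return GeneratedCohort(records=records, seed=seed, profile=profile)


# ---------------------------------------------------------------------------
# Descriptive summary
# ---------------------------------------------------------------------------


def _primary_suspect(record: PatientRecord) -> DrugExposure:
    if len(record.exposures) == 1:
        return record.exposures[0]
    for e in record.exposures:
        if e.is_culprit_truth:
            return e
    return record.exposures[0]


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive per-drug frequency table and cohort demographics."""

    drug_table: pd.DataFrame  # columns: drug, n, percentage (1 dp)
    n_patients: int
    n_cases: int
    n_controls: int
    age_mean: float
    age_sd: float
    n_male: int
    n_female: int
    mean_onset_days: float

    def to_tsv(self) -> str:
        lines = ["Suspected Medication\tN\tPercentage (%)"]
        for row in self.drug_table.itertuples(index=False):
            lines.append(f"{row.drug}\t{row.n}\t{row.percentage:.1f}")
        total_pct = float(self.drug_table["percentage"].sum())
        lines.append(f"Total\t{self.n_patients}\t{total_pct:.1f}")
        return "\n".join(lines) + "\n"


def summarize(records: Sequence[PatientRecord]) -> CohortSummary:
    """Per-drug counts/percentages plus demographic and latency summary.

    One suspected drug is counted per patient: the single administered drug
    for cases, otherwise the ground-truth culprit when flagged, otherwise
    the first listed exposure. Time to onset is the latency of that drug.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    suspects = [_primary_suspect(r) for r in records]
    counts: dict[str, int] = {}
    for e in suspects:
        counts[e.drug_name] = counts.get(e.drug_name, 0) + 1
    n = len(records)
    table = pd.DataFrame(
        [
            {"drug": d, "n": c, "percentage": round(100.0 * c / n, 1)}
            for d, c in sorted(counts.items())
        ]
    )
    ages = np.array([r.age for r in records], dtype=float)
    onsets = [
        (r.index_date - e.start_date).days for r, e in zip(records, suspects)
    ]
    return CohortSummary(
        drug_table=table,
        n_patients=n,
        n_cases=sum(r.group is Group.case for r in records),
        n_controls=sum(r.group is Group.control for r in records),
        age_mean=float(ages.mean()),
        age_sd=float(ages.std(ddof=1)) if n > 1 else 0.0,
        n_male=sum(r.sex is Sex.male for r in records),
        n_female=sum(r.sex is Sex.female for r in records),
        mean_onset_days=float(np.mean(onsets)),
    )
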