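"""RegiSCAR DRESS validation score and the causality-assessment inclusion gate.

The RegiSCAR score grades how well a presentation fits DRESS: fever,
lymphadenopathy, eosinophilia, atypical lymphocytes, skin involvement and
morphology, biopsy, internal organ involvement, time to resolution, and
exclusion of alternative causes. Totals map to diagnostic certainty bands
(excluded / possible / probable / definite), and a total strictly greater
than +2 is the inclusion gate for drug-causality assessment with ALDRESS.
"""

from __future__ import annotations

from typing import Mapping, Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .causality import ScoreTable, default_table
from .records import BiopsyFinding, EosinophiliaGrade, RegiscarInputs, TernaryFlag

__all__ = ["RegiscarResult", "regiscar_score", "meets_inclusion"]


class RegiscarResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    total_score: int
    per_item_points: Mapping[str, int]
    category: str

    @model_validator(mode="after")
    def _sum_invariant(self) -> "RegiscarResult":
        total = sum(self.per_item_points.values())
        if total != self.total_score:
            raise ValueError(f"total_score {self.total_score} != item sum {total}")
        return self


def _levels(inputs: RegiscarInputs) -> dict[str, str]:
    def yes_else(flag: TernaryFlag, other: str) -> str:
        return "yes" if flag is TernaryFlag.yes else other

    organs = inputs.organs_involved
    return {
        "fever_ge_38_5": yes_else(inputs.fever_ge_38_5, "no_or_unknown"),
        "lymphadenopathy": inputs.lymphadenopathy.value,
        "eosinophilia": inputs.eosinophilia_grade.value,
        "atypical_lymphocytes": inputs.atypical_lymphocytes.value,
        "skin_extent": (
            "gt50"
            if inputs.skin_extent_gt50 is TernaryFlag.yes
            else ("le50" if inputs.skin_extent_gt50 is TernaryFlag.no else "unknown")
        ),
        "rash_suggestive": inputs.rash_suggestive.value,
        "biopsy": (
            "not_done"
            if inputs.biopsy_suggestive is BiopsyFinding.not_done
            else inputs.biopsy_suggestive.value
        ),
        "organ_involvement": "none" if organs == 0 else ("one" if organs == 1 else "two_or_more"),
        "resolution": yes_else(inputs.resolution_ge_15_days, "no_or_unknown"),
        "alternative_causes": inputs.alternative_causes_excluded.value,
    }


def regiscar_score(
    inputs: RegiscarInputs, table: Optional[ScoreTable] = None
) -> RegiscarResult:
    """Itemized RegiSCAR total and diagnostic category.

    Bands under the default table: <= +1 excluded, +2..+3 possible,
    +4 probable, >= +5 definite.
    """
    if table is None:
        table = default_table("regiscar")
    levels = _levels(inputs)
    per_item = {item: table.points(item, level) for item, level in levels.items()}
    total = sum(per_item.values())
    return RegiscarResult(
        total_score=total, per_item_points=per_item, category=table.band(total)
    )


def meets_inclusion(result: RegiscarResult) -> bool:
    """Inclusion gate for causality assessment: RegiSCAR total strictly > +2."""
    return result.total_score > 2
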