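"""Inter-rater and inter-algorithm agreement: percent agreement and Cohen's kappa.

Kappa is computed as kappa = (p_o - p_e) / (1 - p_e), where the observed and
chance-expected proportions are weighted sums over the k x k contingency
table of the two rating vectors. Weights credit partial agreement between
ordinal categories: w_ij = 1 for unweighted agreement on the diagonal,
w_ij = 1 - |i-j|/(k-1) for linear weights and w_ij = 1 - (|i-j|/(k-1))^2
for quadratic weights (unweighted is the identity-weight special case).

The asymptotic standard error is the large-sample variance under the
alternative (Fleiss-Cohen-Everitt), and it is used for both the z statistic
(z = kappa / ase) and the normal-theory confidence interval
(kappa +/- z_{alpha/2} * ase); the printed z, p and CI of a kappa row are
therefore mutually consistent by construction. Interpretation follows the
Landis-Koch bands (slight / fair / moderate / substantial / near perfect).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Hashable, Optional, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "Weighting",
    "KappaInterpretation",
    "KappaResult",
    "percent_agreement",
    "contingency_table",
    "cohen_kappa",
    "kappa_from_table",
    "interpret_kappa",
]


class Weighting(str, Enum):
    unweighted = "unweighted"
    linear = "linear"
    quadratic = "quadratic"


class KappaInterpretation(str, Enum):
    none = "none"
    slight = "slight"
    fair = "fair"
    moderate = "moderate"
    substantial = "substantial"
    near_perfect = "near_perfect"


def interpret_kappa(kappa: float) -> KappaInterpretation:
    """Landis-Koch band: <0.10 none, 0.10-0.20 slight, 0.21-0.40 fair,
    0.41-0.60 moderate, 0.61-0.80 substantial, >0.80 near perfect."""
    if not -1.0 <= kappa <= 1.0 + 1e-12:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa < 0.095:
        return KappaInterpretation.none
    if kappa < 0.205:
        return KappaInterpretation.slight
    if kappa < 0.405:
        return KappaInterpretation.fair
    if kappa < 0.605:
        return KappaInterpretation.moderate
    if kappa < 0.805:
        return KappaInterpretation.substantial
    return KappaInterpretation.near_perfect


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ase: float
    z: float
    p_value: float
    ci_low: float
    ci_high: float
    weighting: Weighting
    interpretation: KappaInterpretation
    alpha: float = 0.05

    @classmethod
    def from_estimate(
        cls, kappa: float, ase: float, weighting: Weighting = Weighting.unweighted,
        alpha: float = 0.05,
    ) -> "KappaResult":
        """Derive z, two-sided p and the CI from a kappa and its ASE."""
        z = kappa / ase
        p = 2.0 * float(norm.sf(abs(z)))
        crit = float(norm.ppf(1 - alpha / 2))
        return cls(
            kappa=kappa,
            ase=ase,
            z=z,
            p_value=p,
            ci_low=kappa - crit * ase,
            ci_high=kappa + crit * ase,
            weighting=weighting,
            interpretation=interpret_kappa(kappa),
            alpha=alpha,
        )

    def to_tsv_row(self) -> str:
        """One row mirroring the usual kappa-table layout
        (Kappa, Value, ASE, Z, Pr, 95% CI)."""
        label = {"unweighted": "Unweighted", "linear": "Weighted (linear)",
                 "quadratic": "Weighted (quadratic)"}[self.weighting.value]
        return (
            f"{label}\t{self.kappa:.4f}\t{self.ase:.4g}\t{self.z:.4g}\t"
            f"{self.p_value:.4g}\t{self.ci_low:.3f}-{self.ci_high:.3f}"
        )


def percent_agreement(scores_a: Sequence, scores_b: Sequence) -> float:
    """Fraction of positions where the two vectors agree exactly."""
    if len(scores_a) != len(scores_b):
        raise ValueError(f"length mismatch: {len(scores_a)} vs {len(scores_b)}")
    if len(scores_a) == 0:
        raise ValueError("cannot compute agreement on empty vectors")
    return sum(1 for a, b in zip(scores_a, scores_b) if a == b) / len(scores_a)


def contingency_table(
    ratings_a: Sequence[Hashable],
    ratings_b: Sequence[Hashable],
    categories: Optional[Sequence[Hashable]] = None,
) -> tuple[np.ndarray, list]:
    """k x k cross-tabulation of two rating vectors over a shared ordered
    category set (defaults to the sorted union of observed categories)."""
    if len(ratings_a) != len(ratings_b):
        raise ValueError(f"length mismatch: {len(ratings_a)} vs {len(ratings_b)}")
    if len(ratings_a) < 2:
        raise ValueError("need at least two rated subjects")
    if categories is None:
        categories = sorted(set(ratings_a) | set(ratings_b))
    cats = list(categories)
    index = {c: i for i, c in enumerate(cats)}
    unknown = (set(ratings_a) | set(ratings_b)) - set(index)
    if unknown:
        raise ValueError(f"ratings outside the category set: {sorted(map(str, unknown))}")
    table = np.zeros((len(cats), len(cats)), dtype=float)
    for a, b in zip(ratings_a, ratings_b):
        table[index[a], index[b]] += 1
    return table, cats


def _weight_matrix(k: int, weighting: Weighting) -> np.ndarray:
    if weighting is Weighting.unweighted:
        return np.eye(k)
    i, j = np.indices((k, k))
    if k == 1:
        return np.ones((1, 1))
    d = np.abs(i - j) / (k - 1)
    return 1.0 - d if weighting is Weighting.linear else 1.0 - d**2


def kappa_from_table(
    table: np.ndarray,
    weighting: Weighting = Weighting.unweighted,
    alpha: float = 0.05,
) -> KappaResult:
    """Weighted kappa with its Fleiss-Cohen-Everitt asymptotic SE from a
    square contingency table of counts."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError(f"contingency table must be square, got shape {t.shape}")
    n = t.sum()
    if n < 2:
        raise ValueError("need at least two rated subjects")
    weighting = Weighting(weighting)
    k = t.shape[0]
    w = _weight_matrix(k, weighting)
    p = t / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float((w * p).sum())
    p_e = float((w * np.outer(row, col)).sum())
    if p_e >= 1.0 - 1e-12:
        raise ValueError(
            "chance agreement is 1 (all ratings in a single identical category); "
            "kappa is undefined"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    # Large-sample variance under the alternative hypothesis.
    wbar_i = w @ col  # row-wise expected weights
    wbar_j = row @ w  # column-wise expected weights
    term = (w * (1.0 - p_e) - (wbar_i[:, None] + wbar_j[None, :]) * (1.0 - p_o)) ** 2
    var = ((p * term).sum() - (p_o * p_e - 2.0 * p_e + p_o) ** 2) / (n * (1.0 - p_e) ** 4)
    ase = float(np.sqrt(max(var, 0.0)))
    if ase == 0.0:
        # Degenerate (e.g. perfect agreement spread over categories); the
        # normal-theory machinery still needs a finite SE.
        z = np.inf if kappa > 0 else (-np.inf if kappa < 0 else 0.0)
        return KappaResult(
            kappa=float(kappa), ase=0.0, z=z, p_value=0.0 if kappa != 0 else 1.0,
            ci_low=float(kappa), ci_high=float(kappa), weighting=weighting,
            interpretation=interpret_kappa(float(kappa)), alpha=alpha,
        )
    return KappaResult.from_estimate(float(kappa), ase, weighting=weighting, alpha=alpha)


def cohen_kappa(
    ratings_a: Sequence[Hashable],
    ratings_b: Sequence[Hashable],
    weighting: Weighting = Weighting.unweighted,
    categories: Optional[Sequence[Hashable]] = None,
    alpha: float = 0.05,
) -> KappaResult:
    """Cohen's kappa (optionally weighted) between two raters or algorithms.

    ``categories`` fixes the shared ordered category set; ordering matters
    for the weighted variants.
    """
    table, _ = contingency_table(ratings_a, ratings_b, categories)
    return kappa_from_table(table, weighting=weighting, alpha=alpha)
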