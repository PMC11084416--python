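"""Diagnostic accuracy of binary causality calls against reference labels.

Everything is driven by a 2x2 confusion matrix (tp, fn, fp, tn). The four
proportions (sensitivity, specificity, PPV, NPV) and accuracy carry exact
Clopper-Pearson binomial confidence intervals; the positive likelihood
ratio LR+ = sensitivity / (1 - specificity) is computed from the unrounded
proportions and carries no interval. Association between truth and calls is
tested with Fisher's exact test (two-sided, sum of tables with point
probability not exceeding the observed one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy.stats import binomtest
from scipy.stats import fisher_exact as _scipy_fisher

__all__ = [
    "ConfusionMatrix",
    "MetricWithCI",
    "DiagnosticReport",
    "confusion",
    "exact_binomial_ci",
    "diagnostic_report",
    "fisher_exact",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 cross-tabulation of reference truth vs predicted calls."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n < 1:
            raise ValueError("confusion matrix must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(truth: Sequence[bool], predicted: Sequence[bool]) -> ConfusionMatrix:
    if len(truth) != len(predicted):
        raise ValueError(f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted")
    if len(truth) == 0:
        raise ValueError("cannot cross-tabulate empty vectors")
    tp = sum(1 for t, p in zip(truth, predicted) if t and p)
    fn = sum(1 for t, p in zip(truth, predicted) if t and not p)
    fp = sum(1 for t, p in zip(truth, predicted) if not t and p)
    tn = sum(1 for t, p in zip(truth, predicted) if not t and not p)
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def exact_binomial_ci(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Clopper-Pearson exact interval for a binomial proportion.

    The lower bound inverts the upper binomial tail at alpha/2 (0 when
    x = 0); the upper bound inverts the lower tail at alpha/2 (1 when
    x = n).
    """
    if not (isinstance(x, int) and isinstance(n, int)):
        raise ValueError("x and n must be integers")
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    ci = binomtest(x, n).proportion_ci(confidence_level=1 - alpha, method="exact")
    return float(ci.low), float(ci.high)


@dataclass(frozen=True)
class MetricWithCI:
    """A proportion with its exact binomial confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("confidence interval must bracket the estimate")

    def __str__(self) -> str:
        return f"{self.estimate:.4f} ({self.ci_low:.4f} to {self.ci_high:.4f})"


def _proportion(x: int, n: int, alpha: float) -> Optional[MetricWithCI]:
    if n == 0:
        return None  # undefined, never silently 0
    low, high = exact_binomial_ci(x, n, alpha)
    return MetricWithCI(
        estimate=x / n, ci_low=low, ci_high=high, numerator=x, denominator=n, alpha=alpha
    )


@dataclass(frozen=True)
class DiagnosticReport:
    """Sensitivity, specificity, PPV, NPV, accuracy (each with an exact CI)
    and LR+. A metric whose denominator is empty is None (undefined)."""

    cm: ConfusionMatrix
    sensitivity: Optional[MetricWithCI]
    specificity: Optional[MetricWithCI]
    ppv: Optional[MetricWithCI]
    npv: Optional[MetricWithCI]
    accuracy: MetricWithCI
    lr_positive: Optional[float]
    alpha: float = 0.05

    _ROWS = ("sensitivity", "specificity", "ppv", "npv", "accuracy")

    def to_dict(self) -> dict:
        out: dict = {"confusion": vars(self.cm), "alpha": self.alpha}
        for name in self._ROWS:
            m = getattr(self, name)
            out[name] = (
                None
                if m is None
                else {
                    "estimate": m.estimate,
                    "ci_low": m.ci_low,
                    "ci_high": m.ci_high,
                    "numerator": m.numerator,
                    "denominator": m.denominator,
                }
            )
        out["lr_positive"] = self.lr_positive
        return out

    def to_tsv(self) -> str:
        """Flat rows mirroring the usual accuracy-table layout
        (Metric, Value, 95% CI)."""
        pct = round((1 - self.alpha) * 100)
        lines = [f"Metric\tValue\t{pct}% Confidence Interval"]
        labels = {
            "sensitivity": "Sensitivity",
            "specificity": "Specificity",
            "ppv": "Positive Predictive Value",
            "npv": "Negative Predictive Value",
            "accuracy": "Accuracy",
        }
        for name in self._ROWS:
            m = getattr(self, name)
            if m is None:
                lines.append(f"{labels[name]}\tundefined\t")
            else:
                lines.append(
                    f"{labels[name]}\t{m.estimate:.4f}\t{m.ci_low:.4f} to {m.ci_high:.4f}"
                )
        lr = "undefined" if self.lr_positive is None else f"{self.lr_positive:.2f}"
        lines.append(f"Likelihood Ratio\t{lr}\t")
        return "\n".join(lines) + "\n"


def diagnostic_report(cm: ConfusionMatrix, alpha: float = 0.05) -> DiagnosticReport:
    sens = _proportion(cm.tp, cm.tp + cm.fn, alpha)
    spec = _proportion(cm.tn, cm.tn + cm.fp, alpha)
    ppv = _proportion(cm.tp, cm.tp + cm.fp, alpha)
    npv = _proportion(cm.tn, cm.tn + cm.fn, alpha)
    accuracy = _proportion(cm.tp + cm.tn, cm.n, alpha)
    assert accuracy is not None  # n >= 1 by construction
    lr: Optional[float] = None
    if sens is not None and spec is not None and spec.estimate < 1.0:
        lr = sens.estimate / (1.0 - spec.estimate)
    return DiagnosticReport(
        cm=cm,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=accuracy,
        lr_positive=lr,
        alpha=alpha,
    )


def fisher_exact(cm: ConfusionMatrix) -> float:
    """Two-sided Fisher exact p for the 2x2 table at fixed margins."""
    p = _scipy_fisher([[cm.tp, cm.fn], [cm.fp, cm.tn]], alternative="two-sided")[1]
    return float(min(1.0, p))
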