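"""Inverse-variance fixed-effects meta-analysis with Higgins I² heterogeneity.

Study effects are log odds ratios with standard errors. When a study
reports only an OR with a 95% CI, the standard error is recovered from the
CI width on the log scale: se = (ln(hi) - ln(lo)) / (2 z). Pooling weights
each study by 1/se²; Cochran's Q measures dispersion of the study effects
around the pooled value and I² = max(0, (Q - df)/Q) x 100 expresses the
share attributable to between-study heterogeneity (I² <= 60% is treated as
mild-to-moderate, > 60% as substantial).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .clogit import Z_95
from .errors import UsageError, WillisError

__all__ = ["StudyEffect", "MetaResult", "se_from_ci", "pool", "higgins_i2", "heterogeneity_band"]


class DomainError(WillisError):
    """Numerically invalid meta-analysis input."""


@dataclass(frozen=True)
class StudyEffect:
    """One study's log odds ratio, its standard error, and a label."""

    log_or: float
    se: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise DomainError(f"se must be > 0, got {self.se}")

    @classmethod
    def from_or_ci(cls, or_hat: float, ci_low: float, ci_high: float, label: str = "") -> "StudyEffect":
        return cls(log_or=math.log(or_hat), se=se_from_ci(or_hat, ci_low, ci_high), label=label)


@dataclass(frozen=True)
class MetaResult:
    """Pooled fixed-effects odds ratio with CI, Cochran's Q and Higgins I²."""

    pooled_or: float
    ci_low: float
    ci_high: float
    q: float
    df: int
    i2_percent: float

    @property
    def band(self) -> str:
        return heterogeneity_band(self.i2_percent)


def se_from_ci(or_hat: float, ci_low: float, ci_high: float) -> float:
    """Standard error of the log OR back-derived from a 95% CI.

    Assumes the CI is symmetric on the log scale (Wald-type), the standard
    construction for odds ratios.
    """
    if not (or_hat > 0 and ci_low > 0 and ci_high > 0):
        raise DomainError("OR and CI bounds must be positive")
    if not ci_low <= or_hat <= ci_high:
        raise DomainError(f"need ci_low <= OR <= ci_high, got {ci_low}, {or_hat}, {ci_high}")
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z_95)
    if se <= 0:
        raise DomainError("degenerate CI: se must be > 0")
    return se


def pool(studies: Sequence[StudyEffect]) -> MetaResult:
    """Inverse-variance fixed-effects pooling of study log odds ratios."""
    if not studies:
        raise UsageError("need at least one study")
    weights = [1.0 / s.se**2 for s in studies]
    w_sum = sum(weights)
    pooled = sum(w * s.log_or for w, s in zip(weights, studies)) / w_sum
    pooled_se = 1.0 / math.sqrt(w_sum)
    q = sum(w * (s.log_or - pooled) ** 2 for w, s in zip(weights, studies))
    df = len(studies) - 1
    i2 = higgins_i2(q, df) if df >= 1 else 0.0
    return MetaResult(
        pooled_or=math.exp(pooled),
        ci_low=math.exp(pooled - Z_95 * pooled_se),
        ci_high=math.exp(pooled + Z_95 * pooled_se),
        q=q,
        df=df,
        i2_percent=i2,
    )


def higgins_i2(q: float, df: int) -> float:
    """Higgins I² in percent: max(0, (Q - df)/Q) x 100, defined as 0 at Q=0."""
    if df < 1:
        raise DomainError("df must be >= 1")
    if q < 0:
        raise DomainError("Q must be >= 0")
    if q == 0.0:
        return 0.0
    return max(0.0, (q - df) / q) * 100.0


def heterogeneity_band(i2_percent: float) -> str:
    """Qualitative heterogeneity label: mild/moderate up to 60%, substantial above."""
    return "mild/moderate" if i2_percent <= 60.0 else "substantial"
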