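"""Events/trials concordance between a reference proband and a set of FDRs.

For a given outcome (one named variant, or "any variation") a first-degree
relative is *concordant* with the reference proband when they share that
variant — for the "any" outcome, when their profiles share at least one
variant (sharing a strict subset counts). A family's concordance is the
count of concordant FDRs over the number evaluated.

When a family is evaluated against another family's proband (a comparison
family in the matched design), the evaluated family's own proband is never
among the FDRs: the comparison proband is discordant with the index proband
by construction of the matching, so including them would bias concordance
downward.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from .errors import UsageError
from .model import CowProfile, Variant

__all__ = ["Outcome", "ConcordanceCount", "fdr_concordant", "family_concordance", "pooled_concordance"]


class Outcome(str, Enum):
    """An analysis outcome: one of the four variants, or any shared variant."""

    CLASSICAL = "classical"
    A1_ASYMMETRY = "a1_asymmetry"
    INCOMPLETE_PCOM = "incomplete_pcom"
    FETAL_PC = "fetal_pc"
    ANY = "any"

    @property
    def variant(self) -> Optional[Variant]:
        return None if self is Outcome.ANY else Variant(self.value)

    def applies_to(self, reference_profile: CowProfile) -> bool:
        """Whether a reference proband with this profile defines this outcome."""
        if self is Outcome.ANY:
            return not reference_profile.is_empty
        return self.variant in reference_profile


ALL_OUTCOMES: tuple[Outcome, ...] = (
    Outcome.CLASSICAL,
    Outcome.A1_ASYMMETRY,
    Outcome.INCOMPLETE_PCOM,
    Outcome.FETAL_PC,
    Outcome.ANY,
)


@dataclass(frozen=True)
class ConcordanceCount:
    """Concordant FDRs (events) over FDRs evaluated (trials)."""

    events: int
    trials: int

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise UsageError("trials must be >= 1")
        if not 0 <= self.events <= self.trials:
            raise UsageError(f"events must be in [0, trials], got {self.events}/{self.trials}")

    @property
    def proportion(self) -> float:
        return self.events / self.trials

    def __str__(self) -> str:
        return f"{self.events}/{self.trials}"


def fdr_concordant(reference_profile: CowProfile, fdr_profile: CowProfile, outcome: Outcome) -> bool:
    """Is this FDR concordant with the reference proband for the outcome?

    Single-variant outcomes are only defined when the reference proband
    carries that variant; the "any" outcome asks for a non-empty profile
    intersection and is symmetric in its two arguments.
    """
    if outcome is Outcome.ANY:
        return reference_profile.intersects(fdr_profile)
    if outcome.variant not in reference_profile:
        raise UsageError(
            f"outcome {outcome.value} is not carried by the reference proband "
            f"({sorted(v.value for v in reference_profile.variants) or 'empty profile'})"
        )
    return outcome.variant in fdr_profile


def family_concordance(
    reference_profile: CowProfile,
    fdr_profiles: Sequence[CowProfile],
    outcome: Outcome,
) -> ConcordanceCount:
    """Concordance count of a family's FDRs against a reference proband."""
    if not fdr_profiles:
        raise UsageError("fdr_profiles must be non-empty")
    events = sum(fdr_concordant(reference_profile, p, outcome) for p in fdr_profiles)
    return ConcordanceCount(events=events, trials=len(fdr_profiles))


def pooled_concordance(counts: Iterable[ConcordanceCount], method: str = "pooled") -> float:
    """Aggregate concordance over families.

    ``method="pooled"`` (default) is the FDR-weighted ratio of total events
    to total trials, matching the data the events/trials regression sees;
    ``method="family_mean"`` averages per-family proportions instead.
    """
    counts = list(counts)
    if not counts:
        raise UsageError("counts must be non-empty")
    if method == "pooled":
        return sum(c.events for c in counts) / sum(c.trials for c in counts)
    if method == "family_mean":
        return sum(c.proportion for c in counts) / len(counts)
    raise UsageError(f"unknown method {method!r}")
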