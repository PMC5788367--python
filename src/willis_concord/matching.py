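"""Constrained random matching of families and the resampling analysis.

Every family in the cohort serves as an *index* family. Per iteration each
index family is matched, with replacement, to a random *comparison* family
drawn from the families whose proband's variant profile is admissible under
the pool rule — by default, disjoint from the index proband's profile, so
the comparison proband is discordant with the index proband by
construction. One matching is shared by all outcomes within an iteration.

For each outcome, index families whose proband carries the outcome
contribute one stratum: the index arm counts concordant FDRs of the index
family, the comparison arm counts FDRs of the matched family who are
concordant *with the index proband* (the comparison family's own proband is
never counted). The strata feed the exact conditional logistic fit, and the
whole procedure is repeated (1001 iterations by default), reporting per
outcome the medians of the odds ratio, the CI bounds taken componentwise,
and the pooled index/comparison concordances.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .clogit import FitResult, Stratum, fit
from .concordance import (
    ALL_OUTCOMES,
    ConcordanceCount,
    Outcome,
    family_concordance,
    pooled_concordance,
)
from .errors import AggregationError, FitError, MatchingError, UsageError
from .model import Cohort, CowProfile, FamilyUnit

__all__ = [
    "POOL_RULES",
    "OutcomeIteration",
    "IterationResult",
    "OutcomeSummary",
    "AggregateResult",
    "analysis_ready",
    "comparison_pool",
    "draw_matching",
    "iterate_once",
    "run_resampling",
]

log = logging.getLogger(__name__)

POOL_RULES = ("disjoint", "not-identical")


@dataclass(frozen=True)
class OutcomeIteration:
    """One iteration's strata and fit for a single outcome."""

    outcome: Outcome
    strata: tuple[Stratum, ...]
    fit_result: Optional[FitResult]
    index_concordance: Optional[float]
    comparison_concordance: Optional[float]


@dataclass(frozen=True)
class IterationResult:
    """All outcomes of one matching iteration."""

    matching: Mapping[str, str]  # index family_id -> comparison family_id
    outcomes: Mapping[Outcome, OutcomeIteration]


@dataclass(frozen=True)
class OutcomeSummary:
    """Medians over converged iterations for one outcome."""

    outcome: Outcome
    n_index_families: int
    median_or: float
    median_ci_low: float
    median_ci_high: float
    median_index_concordance: float
    median_comparison_concordance: float
    n_converged: int


@dataclass(frozen=True)
class AggregateResult:
    """Per-outcome medians over the resampling iterations."""

    group_label: str
    outcomes: Mapping[Outcome, OutcomeSummary]
    n_iterations: int
    seed: int


def analysis_ready(cohort: Cohort, rules=None) -> tuple[Cohort, dict[str, CowProfile]]:
    """Resolve member profiles and drop families with an empty proband profile.

    A proband fitting none of the four categories defines no outcome and
    has an undefined comparison constraint; such families are excluded from
    all analyses with a warning.
    """
    profiles: dict[str, CowProfile] = {}
    kept: list[FamilyUnit] = []
    for fam in cohort:
        proband_profile = fam.proband.profile(rules)
        if proband_profile.is_empty:
            log.warning(
                "family %s excluded from analysis: proband has no named variant",
                fam.family_id,
            )
            continue
        kept.append(fam)
        for member in fam.members:
            profiles[f"{fam.family_id}/{member.member_id}"] = member.profile(rules)
    return cohort.with_families(kept), profiles


def _proband_profile(fam: FamilyUnit, profiles: Mapping[str, CowProfile]) -> CowProfile:
    return profiles[f"{fam.family_id}/{fam.proband.member_id}"]


def _fdr_profiles(fam: FamilyUnit, profiles: Mapping[str, CowProfile]) -> list[CowProfile]:
    return [profiles[f"{fam.family_id}/{m.member_id}"] for m in fam.fdrs]


def comparison_pool(
    index_family: FamilyUnit,
    cohort: Cohort,
    profiles: Mapping[str, CowProfile],
    pool_rule: str = "disjoint",
) -> list[FamilyUnit]:
    """Admissible comparison families for one index family, ordered by id.

    Under the default ``disjoint`` rule a candidate's proband must share no
    variant with the index proband (so the candidate proband is discordant
    for every outcome the index proband defines); ``not-identical`` only
    requires the profiles to differ as sets.
    """
    if pool_rule not in POOL_RULES:
        raise UsageError(f"pool_rule must be one of {POOL_RULES}")
    ref = _proband_profile(index_family, profiles)
    if ref.is_empty:
        raise UsageError(f"index family {index_family.family_id}: proband profile is empty")
    pool = []
    for fam in sorted(cohort, key=lambda f: f.family_id):
        if fam.family_id == index_family.family_id:
            continue
        cand = _proband_profile(fam, profiles)
        ok = ref.is_disjoint(cand) if pool_rule == "disjoint" else cand.variants != ref.variants
        if ok:
            pool.append(fam)
    if not pool:
        raise MatchingError(
            f"no admissible comparison family for index family {index_family.family_id} "
            f"(proband variants: {sorted(v.value for v in ref.variants)}, rule={pool_rule})"
        )
    return pool


def _pools(cohort, profiles, pool_rule):
    return {f.family_id: comparison_pool(f, cohort, profiles, pool_rule) for f in cohort}


def draw_matching(
    cohort: Cohort,
    rng: np.random.Generator,
    profiles: Mapping[str, CowProfile],
    pool_rule: str = "disjoint",
    pools: Optional[Mapping[str, list[FamilyUnit]]] = None,
) -> dict[str, FamilyUnit]:
    """One random matching: each index family -> uniform draw from its pool.

    Drawn with replacement across index families: the same comparison
    family may serve several index families.
    """
    if pools is None:
        pools = _pools(cohort, profiles, pool_rule)
    return {
        fam.family_id: pools[fam.family_id][rng.integers(len(pools[fam.family_id]))]
        for fam in cohort
    }


def _evaluate_matching(
    cohort: Cohort,
    matching: Mapping[str, FamilyUnit],
    profiles: Mapping[str, CowProfile],
    outcomes: Sequence[Outcome],
) -> IterationResult:
    per_outcome: dict[Outcome, OutcomeIteration] = {}
    for outcome in outcomes:
        strata: list[Stratum] = []
        for fam in cohort:
            ref = _proband_profile(fam, profiles)
            if not outcome.applies_to(ref):
                continue
            index_count = family_concordance(ref, _fdr_profiles(fam, profiles), outcome)
            comp_fam = matching[fam.family_id]
            comp_count = family_concordance(ref, _fdr_profiles(comp_fam, profiles), outcome)
            strata.append(
                Stratum(
                    index_events=index_count.events,
                    index_trials=index_count.trials,
                    comparison_events=comp_count.events,
                    comparison_trials=comp_count.trials,
                )
            )
        if not strata:
            per_outcome[outcome] = OutcomeIteration(outcome, (), None, None, None)
            continue
        try:
            fit_result = fit(strata)
        except FitError:
            fit_result = None
        index_conc = pooled_concordance(
            [ConcordanceCount(s.index_events, s.index_trials) for s in strata]
        )
        comp_conc = pooled_concordance(
            [ConcordanceCount(s.comparison_events, s.comparison_trials) for s in strata]
        )
        per_outcome[outcome] = OutcomeIteration(
            outcome, tuple(strata), fit_result, index_conc, comp_conc
        )
    return IterationResult(
        matching={k: v.family_id for k, v in matching.items()},
        outcomes=per_outcome,
    )


def iterate_once(
    cohort: Cohort,
    rng: np.random.Generator,
    profiles: Optional[Mapping[str, CowProfile]] = None,
    outcomes: Sequence[Outcome] = ALL_OUTCOMES,
    pool_rule: str = "disjoint",
    pools: Optional[Mapping[str, list[FamilyUnit]]] = None,
) -> IterationResult:
    """Draw one matching and evaluate strata and fits for every outcome."""
    if profiles is None:
        cohort, profiles = analysis_ready(cohort)
    matching = draw_matching(cohort, rng, profiles, pool_rule, pools)
    return _evaluate_matching(cohort, matching, profiles, outcomes)


def run_resampling(
    cohort: Cohort,
    n_iterations: int = 1001,
    seed: int = 0,
    outcomes: Sequence[Outcome] = ALL_OUTCOMES,
    pool_rule: str = "disjoint",
    rules=None,
) -> AggregateResult:
    """Full resampling analysis: repeated matching, fit, median aggregation.

    Per outcome, medians of the odds ratio, both CI bounds (componentwise)
    and the pooled index/comparison concordances are taken over converged
    iterations. Reproducible given (cohort, n_iterations, seed); iteration
    substreams are spawned by counter so results do not depend on execution
    order.

    Raises
    ------
    AggregationError
        If more than half the iterations fail to converge for an outcome.
    """
    if n_iterations < 1:
        raise UsageError("n_iterations must be >= 1")
    ready, profiles = analysis_ready(cohort, rules)
    if not len(ready):
        raise UsageError("no analysable families (all proband profiles empty?)")
    pools = _pools(ready, profiles, pool_rule)
    streams = np.random.SeedSequence(seed).spawn(n_iterations)

    per_outcome_records: dict[Outcome, list[OutcomeIteration]] = {o: [] for o in outcomes}
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        result = iterate_once(ready, rng, profiles, outcomes, pool_rule, pools)
        for o in outcomes:
            per_outcome_records[o].append(result.outcomes[o])
        if log.isEnabledFor(logging.DEBUG):
            for o in outcomes:
                fr = result.outcomes[o].fit_result
                log.debug("iter %d outcome %s: %s", i, o.value, fr)

    summaries: dict[Outcome, OutcomeSummary] = {}
    for o in outcomes:
        records = per_outcome_records[o]
        with_strata = [r for r in records if r.strata]
        if not with_strata:
            log.info("outcome %s skipped: no index proband carries it", o.value)
            continue
        n_index = len(with_strata[0].strata)
        converged = [
            r for r in with_strata if r.fit_result is not None and r.fit_result.converged
        ]
        if len(converged) < 0.5 * n_iterations:
            raise AggregationError(
                f"outcome {o.value}: only {len(converged)}/{n_iterations} iterations converged"
            )
        summaries[o] = OutcomeSummary(
            outcome=o,
            n_index_families=n_index,
            median_or=float(np.median([r.fit_result.or_hat for r in converged])),
            median_ci_low=float(np.median([r.fit_result.ci_low for r in converged])),
            median_ci_high=float(np.median([r.fit_result.ci_high for r in converged])),
            median_index_concordance=float(np.median([r.index_concordance for r in converged])),
            median_comparison_concordance=float(
                np.median([r.comparison_concordance for r in converged])
            ),
            n_converged=len(converged),
        )
    return AggregateResult(
        group_label=ready.group_label,
        outcomes=summaries,
        n_iterations=n_iterations,
        seed=seed,
    )
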