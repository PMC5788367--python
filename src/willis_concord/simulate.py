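"""Synthetic cohorts with tunable within-family aggregation of CoW variants.

The generator reproduces the statistical structure the analysis assumes
without using any study data: families of a proband plus 1-14 imaged FDRs
(size distribution defaulting to the published group-1 family-size counts),
marginal variant prevalences near the published prevalence table, free
co-occurrence of the three non-classical variants, and a per-variant
family-level normal random intercept on the logit scale whose standard
deviation sigma_v controls how strongly variant v aggregates within
families (sigma_v = 0: members independent).

The classical configuration is derived, not drawn: a member carrying no
non-classical variant is classical with probability
p_classical / prod_v (1 - p_v), which makes the marginal classical
prevalence come out at p_classical while honouring the rule that classical
excludes every other category.

Profiles can optionally be rendered into six vessel diameters that classify
back to exactly the generating profile, so the diameter-based pipeline path
is testable end to end.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from .classify import ClassificationRules, classify
from .clogit import Stratum
from .errors import GenerationError, ParameterError
from .model import (
    NON_CLASSICAL,
    Cohort,
    CowProfile,
    FamilyUnit,
    IndividualRecord,
    Variant,
    VesselDiameters,
)

__all__ = [
    "SimulationParams",
    "sample_profiles",
    "profiles_to_diameters",
    "generate_cohort",
    "simulate_strata",
]

# Published group-1 family-size counts: number of families with k imaged FDRs.
GROUP1_FDR_COUNTS: dict[int, int] = {1: 76, 2: 25, 3: 6, 4: 4, 5: 4, 6: 3, 7: 2, 11: 1, 14: 1}

DEFAULT_PREVALENCE: dict[Variant, float] = {
    Variant.CLASSICAL: 0.18,
    Variant.A1_ASYMMETRY: 0.22,
    Variant.INCOMPLETE_PCOM: 0.62,
    Variant.FETAL_PC: 0.26,
}


def _normalised_size_dist(counts: Mapping[int, int | float]) -> dict[int, float]:
    total = sum(counts.values())
    return {int(k): v / total for k, v in sorted(counts.items())}


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings.

    Parameters
    ----------
    n_families : int
        Number of family units to generate.
    fdr_count_distribution : mapping size -> probability
        Distribution of the number of imaged FDRs per family; defaults to
        the published group-1 counts, normalised.
    variant_prevalence : mapping variant -> probability
        Target marginal prevalence of each variant category.
    familial_sd : mapping variant -> sigma
        Standard deviation of the family-level logit intercept per
        non-classical variant; 0 (the default) makes members independent.
    emit_diameters : bool
        Also render each profile into six consistent vessel diameters.
    seed : int
        Seed of the generator's random stream.
    """

    n_families: int = 122
    fdr_count_distribution: Mapping[int, float] = field(
        default_factory=lambda: _normalised_size_dist(GROUP1_FDR_COUNTS)
    )
    variant_prevalence: Mapping[Variant, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    familial_sd: Mapping[Variant, float] = field(default_factory=dict)
    emit_diameters: bool = False
    seed: int = 0
    group_label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ParameterError("n_families must be >= 1")
        probs = dict(self.fdr_count_distribution)
        if not math.isclose(sum(probs.values()), 1.0, abs_tol=1e-9):
            raise ParameterError("fdr_count_distribution must sum to 1")
        if any(k < 1 for k in probs):
            raise ParameterError("family sizes must be >= 1 FDR")
        for v, p in self.variant_prevalence.items():
            if not 0.0 < p < 1.0:
                raise ParameterError(f"prevalence of {Variant(v).value} must be in (0,1)")
        for v, s in self.familial_sd.items():
            if s < 0:
                raise ParameterError(f"familial_sd of {Variant(v).value} must be >= 0")

    def sigma(self, v: Variant) -> float:
        return float(self.familial_sd.get(v, 0.0))

    def prevalence(self, v: Variant) -> float:
        return float(self.variant_prevalence[v])

    @property
    def classical_conditional_prob(self) -> float:
        """P(classical | no non-classical variant) hitting the marginal target."""
        no_variant_mass = math.prod(1.0 - self.prevalence(v) for v in NON_CLASSICAL)
        p = self.prevalence(Variant.CLASSICAL) / no_variant_mass
        if p >= 1.0:
            raise ParameterError(
                f"classical prevalence {self.prevalence(Variant.CLASSICAL)} exceeds the "
                f"no-variant mass {no_variant_mass:.4f} implied by the other prevalences"
            )
        return p


def sample_profiles(
    params: SimulationParams, rng: Optional[np.random.Generator] = None
) -> Cohort:
    """Generate a cohort of variant profiles (no diameters).

    The first member of each family is the proband; family sizes and
    per-member variant indicators are drawn as documented in the module
    docstring.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    sizes = np.array(list(params.fdr_count_distribution.keys()))
    size_probs = np.array(list(params.fdr_count_distribution.values()))
    p_classical_cond = params.classical_conditional_prob

    families = []
    for i in range(params.n_families):
        family_id = f"F{i:05d}"
        n_members = 1 + int(rng.choice(sizes, p=size_probs))
        carries = np.zeros((n_members, len(NON_CLASSICAL)), dtype=bool)
        for j, v in enumerate(NON_CLASSICAL):
            b = rng.normal(0.0, params.sigma(v)) if params.sigma(v) > 0 else 0.0
            p = expit(logit(params.prevalence(v)) + b)
            carries[:, j] = rng.random(n_members) < p
        members = []
        for m in range(n_members):
            variants = {v for j, v in enumerate(NON_CLASSICAL) if carries[m, j]}
            if not variants and rng.random() < p_classical_cond:
                variants = {Variant.CLASSICAL}
            members.append(
                IndividualRecord(
                    family_id=family_id,
                    member_id=f"M{m:03d}",
                    role="proband" if m == 0 else "fdr",
                    precoded_profile=CowProfile(frozenset(variants)),
                )
            )
        families.append(FamilyUnit(family_id, members[0], tuple(members[1:])))
    return Cohort(group_label=params.group_label, families=tuple(families))


def _draw_non_fetal_pcom_side(rng, p1: float, threshold: float, fetal_cap: float):
    """PcomA above the hypoplasia threshold but not fetal on this side."""
    hi = fetal_cap * p1
    lo = threshold + 0.05
    if hi <= lo:  # P1 too small to allow a normal PcomA; caller re-draws P1
        return None
    return rng.uniform(lo, hi)


def profiles_to_diameters(
    profile: CowProfile,
    rules: ClassificationRules = ClassificationRules(),
    rng: Optional[np.random.Generator] = None,
    max_attempts: int = 100,
) -> VesselDiameters:
    """Render a profile into six diameters that classify back to it exactly.

    Normal segments are drawn from 1.5-3.0 mm; the affected segments are
    then constrained per the rules (e.g. a hypoplastic PcomA below the
    threshold, a fetal PcomA above 1+fraction times its P1). Construction
    is verified by classification and re-drawn on failure.
    """
    if rng is None:
        rng = np.random.default_rng()
    t = rules.hypoplasia_threshold_mm
    fetal_cap = 1.0 + rules.fetal_excess_fraction
    asym = rules.a1_asymmetry_fraction

    for _ in range(max_attempts):
        if Variant.CLASSICAL in profile:
            a1_left = rng.uniform(1.5, 3.0)
            a1_right = a1_left * rng.uniform(1.0 - asym + 0.05, 1.0)
            p1 = rng.uniform(1.5, 3.0, size=2)
            pcom = [_draw_non_fetal_pcom_side(rng, p, t, fetal_cap) for p in p1]
            if any(v is None for v in pcom):
                continue
            cand = VesselDiameters(a1_left, a1_right, p1[0], p1[1], pcom[0], pcom[1])
        else:
            # A1 pair
            if Variant.A1_ASYMMETRY in profile:
                a1_left = rng.uniform(1.8, 3.0)
                a1_right = a1_left * rng.uniform(0.0, max(0.0, 1.0 - asym - 0.1))
            elif profile.is_empty:
                # break "classical" via symmetric hypoplastic A1s (not a category)
                a1_left = rng.uniform(0.3, t - 0.05)
                a1_right = a1_left * rng.uniform(0.8, 1.0)
            else:
                a1_left = rng.uniform(1.5, 3.0)
                a1_right = a1_left * rng.uniform(1.0 - asym + 0.05, 1.0)
            # posterior circulation, per side
            fetal_side = int(rng.integers(2)) if Variant.FETAL_PC in profile else -1
            hypo_side = int(rng.integers(2)) if Variant.INCOMPLETE_PCOM in profile else -1
            if fetal_side >= 0 and fetal_side == hypo_side:
                hypo_side = 1 - fetal_side
            p1_sides: list[float] = []
            pcom_sides: list[float] = []
            ok = True
            for side in range(2):
                if side == fetal_side:
                    p1 = rng.uniform(1.0, 2.0)
                    pcom = p1 * rng.uniform(fetal_cap + 0.1, fetal_cap + 0.5)
                elif side == hypo_side:
                    p1 = rng.uniform(1.5, 3.0)
                    pcom = rng.uniform(0.0, t - 0.05)
                    if pcom > fetal_cap * p1:  # hypoplastic must not read as fetal
                        ok = False
                        break
                else:
                    p1 = rng.uniform(1.5, 3.0)
                    pcom = _draw_non_fetal_pcom_side(rng, p1, t, fetal_cap)
                    if pcom is None:
                        ok = False
                        break
                p1_sides.append(p1)
                pcom_sides.append(pcom)
            if not ok:
                continue
            cand = VesselDiameters(
                a1_left, a1_right, p1_sides[0], p1_sides[1], pcom_sides[0], pcom_sides[1]
            )
        if classify(cand, rules) == profile:
            return cand
    raise GenerationError(
        f"could not render profile {sorted(v.value for v in profile.variants)} "
        f"after {max_attempts} attempts"
    )


def generate_cohort(
    params: SimulationParams, rules: ClassificationRules = ClassificationRules()
) -> Cohort:
    """Full generator: profiles, plus consistent diameters when requested."""
    rng = np.random.default_rng(params.seed)
    cohort = sample_profiles(params, rng)
    if not params.emit_diameters:
        return cohort
    families = []
    for fam in cohort:
        members = []
        for member in fam.members:
            d = profiles_to_diameters(member.precoded_profile, rules, rng)
            members.append(
                IndividualRecord(
                    family_id=member.family_id,
                    member_id=member.member_id,
                    role=member.role,
                    diameters=d,
                    precoded_profile=member.precoded_profile,
                )
            )
        families.append(FamilyUnit(fam.family_id, members[0], tuple(members[1:])))
    return Cohort(group_label=cohort.group_label, families=tuple(families))


def simulate_strata(
    n_strata: int,
    psi: float,
    rng: np.random.Generator,
    baseline_p: float = 0.4,
    trials_choices: Sequence[int] = (1, 2, 3, 4, 5, 6),
) -> list[Stratum]:
    """Matched binomial strata with a known common odds ratio ``psi``.

    Each stratum draws a baseline log-odds jitter (a stratum nuisance), a
    comparison arm at those odds and an index arm with odds multiplied by
    ``psi`` — the generating model of the conditional likelihood, used for
    parameter-recovery checks.
    """
    if psi <= 0:
        raise ParameterError("psi must be > 0")
    strata = []
    base_logodds = math.log(baseline_p / (1.0 - baseline_p))
    for _ in range(n_strata):
        alpha = base_logodds + rng.normal(0.0, 0.5)
        p0 = expit(alpha)
        p1 = expit(alpha + math.log(psi))
        n1 = int(rng.choice(trials_choices))
        n2 = int(rng.choice(trials_choices))
        strata.append(
            Stratum(
                index_events=int(rng.binomial(n1, p1)),
                index_trials=n1,
                comparison_events=int(rng.binomial(n2, p0)),
                comparison_trials=n2,
            )
        )
    return strata
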