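"""Core domain types: vessel diameters, variant profiles, families, cohorts.

The unit of analysis is the family: one designated proband plus one or more
imaged first-degree relatives (FDRs). Each individual carries a set of
circle of Willis variant categories (a :class:`CowProfile`), derived either
from six arterial diameters or supplied pre-coded.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

from .errors import IntegrityError, UsageError

__all__ = [
    "Variant",
    "CowProfile",
    "VesselDiameters",
    "IndividualRecord",
    "FamilyUnit",
    "Cohort",
]


class Variant(str, Enum):
    """The four circle of Willis variant categories.

    CLASSICAL is a complete, symmetric circle (all six segments above the
    hypoplasia threshold, no A1 asymmetry, no fetal posterior circulation)
    and is by definition exclusive of the other three. The three
    non-classical variants may co-occur within one individual.
    """

    CLASSICAL = "classical"
    A1_ASYMMETRY = "a1_asymmetry"
    INCOMPLETE_PCOM = "incomplete_pcom"
    FETAL_PC = "fetal_pc"


NON_CLASSICAL: tuple[Variant, ...] = (
    Variant.A1_ASYMMETRY,
    Variant.INCOMPLETE_PCOM,
    Variant.FETAL_PC,
)


@dataclass(frozen=True)
class CowProfile:
    """The set of variant categories an individual carries.

    May be empty (a configuration fitting none of the four categories, e.g.
    a hypoplastic P1 with otherwise normal vessels). CLASSICAL, when
    present, must be the only element.
    """

    variants: frozenset[Variant] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", frozenset(self.variants))
        if Variant.CLASSICAL in self.variants and len(self.variants) > 1:
            raise IntegrityError(
                "CLASSICAL excludes all other variants; got "
                f"{sorted(v.value for v in self.variants)}"
            )

    @classmethod
    def of(cls, *variants: Variant) -> "CowProfile":
        return cls(frozenset(variants))

    def __contains__(self, v: Variant) -> bool:
        return v in self.variants

    def __iter__(self):
        return iter(sorted(self.variants, key=lambda v: v.value))

    def __len__(self) -> int:
        return len(self.variants)

    def __bool__(self) -> bool:
        return bool(self.variants)

    def intersects(self, other: "CowProfile") -> bool:
        return bool(self.variants & other.variants)

    def is_disjoint(self, other: "CowProfile") -> bool:
        return not self.intersects(other)

    @property
    def is_empty(self) -> bool:
        return not self.variants


@dataclass(frozen=True)
class VesselDiameters:
    """Six circle of Willis segment diameters in millimetres.

    ``0.0`` codes a vessel judged absent/aplastic (informative: below any
    threshold); ``None`` codes a missing measurement (not informative).
    """

    a1_left: Optional[float]
    a1_right: Optional[float]
    p1_left: Optional[float]
    p1_right: Optional[float]
    pcom_left: Optional[float]
    pcom_right: Optional[float]

    FIELD_NAMES = ("a1_left", "a1_right", "p1_left", "p1_right", "pcom_left", "pcom_right")

    def __post_init__(self) -> None:
        for name in self.FIELD_NAMES:
            v = getattr(self, name)
            if v is None:
                continue
            v = float(v)
            if math.isnan(v):
                v = None
            elif v < 0.0:
                raise IntegrityError(f"diameter {name} must be >= 0 mm, got {v}")
            object.__setattr__(self, name, v)

    def as_tuple(self) -> tuple[Optional[float], ...]:
        return tuple(getattr(self, n) for n in self.FIELD_NAMES)

    @property
    def complete(self) -> bool:
        return all(v is not None for v in self.as_tuple())

    def missing_fields(self) -> tuple[str, ...]:
        return tuple(n for n in self.FIELD_NAMES if getattr(self, n) is None)

    def scaled(self, c: float) -> "VesselDiameters":
        return VesselDiameters(
            *(None if v is None else v * c for v in self.as_tuple())
        )


@dataclass(frozen=True)
class IndividualRecord:
    """One imaged family member."""

    family_id: str
    member_id: str
    role: str  # "proband" | "fdr"
    diameters: Optional[VesselDiameters] = None
    precoded_profile: Optional[CowProfile] = None
    sex: Optional[str] = None
    modality: Optional[str] = None  # "MRA" | "CTA" | "DSA"
    slice_thickness_mm: Optional[float] = None
    quality_ok: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.role not in ("proband", "fdr"):
            raise IntegrityError(
                f"role must be 'proband' or 'fdr', got {self.role!r} "
                f"({self.family_id}/{self.member_id})"
            )

    @property
    def is_proband(self) -> bool:
        return self.role == "proband"

    def profile(self, rules=None) -> CowProfile:
        """Variant profile: pre-coded if supplied, else classified from diameters."""
        if self.precoded_profile is not None:
            return self.precoded_profile
        if self.diameters is None:
            raise UsageError(
                f"{self.family_id}/{self.member_id} has neither diameters nor "
                "a pre-coded profile"
            )
        from .classify import ClassificationRules, classify

        return classify(self.diameters, rules or ClassificationRules())


@dataclass(frozen=True)
class FamilyUnit:
    """A proband plus at least one imaged first-degree relative."""

    family_id: str
    proband: IndividualRecord
    fdrs: tuple[IndividualRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fdrs", tuple(self.fdrs))
        if not self.proband.is_proband:
            raise IntegrityError(f"family {self.family_id}: proband slot has role=fdr")
        if any(m.is_proband for m in self.fdrs):
            raise IntegrityError(f"family {self.family_id}: more than one proband")
        if len(self.fdrs) < 1:
            raise IntegrityError(f"family {self.family_id}: no FDRs")
        ids = [self.proband.member_id] + [m.member_id for m in self.fdrs]
        if len(set(ids)) != len(ids):
            raise IntegrityError(f"family {self.family_id}: duplicate member_id")

    @property
    def members(self) -> tuple[IndividualRecord, ...]:
        return (self.proband, *self.fdrs)

    @property
    def n_fdrs(self) -> int:
        return len(self.fdrs)


@dataclass(frozen=True)
class Cohort:
    """A labelled group of family units with unique family ids."""

    group_label: str
    families: tuple[FamilyUnit, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "families", tuple(self.families))
        ids = [f.family_id for f in self.families]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate family_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self) -> Iterable[FamilyUnit]:
        return iter(self.families)

    @property
    def n_fdrs(self) -> int:
        return sum(f.n_fdrs for f in self.families)

    def family(self, family_id: str) -> FamilyUnit:
        for f in self.families:
            if f.family_id == family_id:
                return f
        raise KeyError(family_id)

    def with_families(self, families: Iterable[FamilyUnit]) -> "Cohort":
        return replace(self, families=tuple(families))
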