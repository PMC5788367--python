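"""Rule-based classification of a circle of Willis from six segment diameters.

Four categories are recognised, each defined by simple diameter thresholds:

* **classical** — all six segments (both A1s, both P1s, both PcomAs) above
  the hypoplasia threshold, with no A1 asymmetry and no fetal posterior
  circulation;
* **A1 asymmetry** — relative difference between the A1 diameters above the
  asymmetry fraction (denominator: the larger A1, so unilateral absence is
  a 100% difference);
* **incomplete PcomA** — either PcomA below the hypoplasia threshold;
* **fetal posterior circulation** — a PcomA more than the fetal excess
  fraction larger than the ipsilateral P1.

All thresholds are strict inequalities. The non-classical categories may
co-occur; classical excludes everything else by construction. A circle
fitting none of the categories (e.g. hypoplastic P1 with otherwise normal
vessels) yields an empty profile.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import ClassificationError, MissingDataError, ParameterError
from .model import CowProfile, Variant, VesselDiameters

__all__ = ["ClassificationRules", "is_a1_asymmetric", "is_incomplete_pcom", "is_fetal_pc", "classify"]


@dataclass(frozen=True)
class ClassificationRules:
    """Thresholds of the variant definitions.

    Parameters
    ----------
    hypoplasia_threshold_mm : float
        Diameter below which a segment counts as hypoplastic/absent (mm).
    a1_asymmetry_fraction : float
        Relative A1 difference above which the circle is A1-asymmetric.
    fetal_excess_fraction : float
        Fractional excess of PcomA over ipsilateral P1 defining fetal PC.
    """

    hypoplasia_threshold_mm: float = 0.8
    a1_asymmetry_fraction: float = 0.33
    fetal_excess_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.hypoplasia_threshold_mm <= 0:
            raise ParameterError("hypoplasia_threshold_mm must be > 0")
        if not 0 < self.a1_asymmetry_fraction < 1:
            raise ParameterError("a1_asymmetry_fraction must be in (0, 1)")
        if self.fetal_excess_fraction <= 0:
            raise ParameterError("fetal_excess_fraction must be > 0")


def _require(name: str, value) -> float:
    if value is None:
        raise MissingDataError(f"missing diameter: {name}")
    return value


def is_a1_asymmetric(a1_left, a1_right, rules: ClassificationRules = ClassificationRules()) -> bool:
    """True if the relative A1 diameter difference exceeds the asymmetry fraction.

    The difference is normalised by the larger A1, so the measure lies in
    [0, 1] and unilateral absence scores 1. Bilateral A1 absence is outside
    the supported categories and raises :class:`ClassificationError`.
    """
    left = _require("a1_left", a1_left)
    right = _require("a1_right", a1_right)
    larger = max(left, right)
    if larger == 0.0:
        raise ClassificationError("bilateral A1 absent")
    return abs(left - right) / larger > rules.a1_asymmetry_fraction


def is_incomplete_pcom(pcom_left, pcom_right, rules: ClassificationRules = ClassificationRules()) -> bool:
    """True if either PcomA is below the hypoplasia threshold (strict)."""
    left = _require("pcom_left", pcom_left)
    right = _require("pcom_right", pcom_right)
    t = rules.hypoplasia_threshold_mm
    return left < t or right < t


def is_fetal_pc(pcom, p1, rules: ClassificationRules = ClassificationRules()) -> bool:
    """True if this side's PcomA exceeds its P1 by more than the fetal fraction.

    Evaluated per side; an individual has fetal posterior circulation if
    either side qualifies.
    """
    pc = _require("pcom", pcom)
    p = _require("p1", p1)
    return pc > (1.0 + rules.fetal_excess_fraction) * p


def classify(diameters: VesselDiameters, rules: ClassificationRules = ClassificationRules()) -> CowProfile:
    """Classify six diameters into a (possibly empty) variant profile.

    Raises
    ------
    MissingDataError
        If any of the six diameters is missing.
    ClassificationError
        If both A1 segments are absent (configuration outside the four
        categories).
    """
    if not diameters.complete:
        raise MissingDataError(
            "cannot classify with missing diameters: "
            + ", ".join(diameters.missing_fields())
        )
    d = diameters
    variants: set[Variant] = set()
    if is_fetal_pc(d.pcom_left, d.p1_left, rules) or is_fetal_pc(d.pcom_right, d.p1_right, rules):
        variants.add(Variant.FETAL_PC)
    if is_a1_asymmetric(d.a1_left, d.a1_right, rules):
        variants.add(Variant.A1_ASYMMETRY)
    if is_incomplete_pcom(d.pcom_left, d.pcom_right, rules):
        variants.add(Variant.INCOMPLETE_PCOM)
    if not variants:
        t = rules.hypoplasia_threshold_mm
        if all(v > t for v in d.as_tuple()):
            variants.add(Variant.CLASSICAL)
    return CowProfile(frozenset(variants))
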