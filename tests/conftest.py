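"""Shared fixtures: the published worked-example families and cohort builders."""
from __future__ import annotations

import pytest

from willis_concord import CowProfile, Variant
from willis_concord.model import Cohort, FamilyUnit, IndividualRecord

CLASSICAL = CowProfile.of(Variant.CLASSICAL)
A1 = CowProfile.of(Variant.A1_ASYMMETRY)
PCOM = CowProfile.of(Variant.INCOMPLETE_PCOM)
FETAL = CowProfile.of(Variant.FETAL_PC)
EMPTY = CowProfile.of()


def make_family(family_id: str, proband_profile: CowProfile, fdr_profiles) -> FamilyUnit:
    proband = IndividualRecord(family_id, "P", "proband", precoded_profile=proband_profile)
    fdrs = tuple(
        IndividualRecord(family_id, f"R{i}", "fdr", precoded_profile=p)
        for i, p in enumerate(fdr_profiles)
    )
    return FamilyUnit(family_id, proband, fdrs)


def make_cohort(spec: dict[str, tuple[CowProfile, list[CowProfile]]], label="test") -> Cohort:
    families = tuple(make_family(fid, prob, fdrs) for fid, (prob, fdrs) in spec.items())
    return Cohort(group_label=label, families=families)


@pytest.fixture
def index_family_profiles():
    """The published six-member index family: proband with incomplete PcomA +
    A1 asymmetry, five FDRs (classical; incomplete PcomA; incomplete PcomA +
    A1 asymmetry; fetal PC; incomplete PcomA)."""
    proband = CowProfile.of(Variant.INCOMPLETE_PCOM, Variant.A1_ASYMMETRY)
    fdrs = [
        CLASSICAL,
        PCOM,
        CowProfile.of(Variant.INCOMPLETE_PCOM, Variant.A1_ASYMMETRY),
        FETAL,
        PCOM,
    ]
    return proband, fdrs


@pytest.fixture
def comparison_family_profiles():
    """The published five-member comparison family: classical proband, four
    FDRs (A1 asymmetry + fetal PC; classical; incomplete PcomA; classical)."""
    proband = CLASSICAL
    fdrs = [
        CowProfile.of(Variant.A1_ASYMMETRY, Variant.FETAL_PC),
        CLASSICAL,
        PCOM,
        CLASSICAL,
    ]
    return proband, fdrs


@pytest.fixture
def worked_example_cohort(index_family_profiles, comparison_family_profiles):
    """Two-family cohort built from the worked-example families."""
    ip, ifdrs = index_family_profiles
    cp, cfdrs = comparison_family_profiles
    return make_cohort({"FAM_INDEX": (ip, ifdrs), "FAM_COMP": (cp, cfdrs)})
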