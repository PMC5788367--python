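"""Reading, validating and writing cohort tables and result tables.

The interchange format is a flat CSV with one row per imaged individual:

    group, family_id, member_id, role,
    a1_left, a1_right, p1_left, p1_right, pcom_left, pcom_right,
    [classical, a1_asymmetry, incomplete_pcom, fetal_pc],
    [sex, modality, slice_thickness_mm, quality_ok]

Diameters are millimetres; an empty cell is a missing measurement, 0.0 an
absent vessel. The four 0/1 variant columns are optional pre-coded
profiles; when both diameters and flags are present the classification of
the diameters must reproduce the flags, otherwise reading fails. An XLSX
file with the same columns (optionally renamed via a schema mapping) is
accepted as a convenience.
"""
from __future__ import annotations

import io as _stdlib_io
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .classify import ClassificationRules, classify
from .concordance import Outcome
from .errors import IntegrityError, SchemaError
from .matching import AggregateResult
from .meta import MetaResult
from .model import (
    Cohort,
    CowProfile,
    FamilyUnit,
    IndividualRecord,
    Variant,
    VesselDiameters,
)

__all__ = [
    "DIAMETER_COLUMNS",
    "FLAG_COLUMNS",
    "read_cohort",
    "read_cohort_file",
    "apply_exclusions",
    "write_cohort",
    "write_results",
    "cohort_to_frame",
]

MANDATORY_COLUMNS = ("family_id", "member_id", "role")
DIAMETER_COLUMNS = ("a1_left", "a1_right", "p1_left", "p1_right", "pcom_left", "pcom_right")
FLAG_COLUMNS = ("classical", "a1_asymmetry", "incomplete_pcom", "fetal_pc")
OPTIONAL_COLUMNS = ("sex", "modality", "slice_thickness_mm", "quality_ok")


def _opt_float(row, col) -> Optional[float]:
    if col not in row or pd.isna(row[col]):
        return None
    return float(row[col])


def _opt_bool(row, col) -> Optional[bool]:
    if col not in row or pd.isna(row[col]):
        return None
    v = row[col]
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    return bool(v)


def _row_profile(row) -> Optional[CowProfile]:
    present = [c for c in FLAG_COLUMNS if c in row.index and not pd.isna(row[c])]
    if not present:
        return None
    variants = frozenset(Variant(c) for c in FLAG_COLUMNS if c in present and int(row[c]) == 1)
    return CowProfile(variants)


def _row_diameters(row) -> Optional[VesselDiameters]:
    if not any(c in row.index for c in DIAMETER_COLUMNS):
        return None
    values = [_opt_float(row, c) for c in DIAMETER_COLUMNS]
    if all(v is None for v in values):
        return None
    return VesselDiameters(*values)


def read_cohort(
    table: pd.DataFrame,
    group_label: str = "",
    rules: ClassificationRules = ClassificationRules(),
) -> Cohort:
    """Build a validated :class:`Cohort` from a row-per-individual table.

    Raises
    ------
    SchemaError
        If a mandatory column is missing.
    IntegrityError
        On duplicate (family_id, member_id), a family with zero or several
        probands, or a pre-coded profile contradicting the diameters.
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    keys = list(zip(table["family_id"].astype(str), table["member_id"].astype(str)))
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise IntegrityError(f"duplicate (family_id, member_id): {dupes}")

    families = []
    for family_id, rows in table.groupby("family_id", sort=True):
        members = []
        for _, row in rows.iterrows():
            diameters = _row_diameters(row)
            precoded = _row_profile(row)
            rec = IndividualRecord(
                family_id=str(family_id),
                member_id=str(row["member_id"]),
                role=str(row["role"]).strip().lower(),
                diameters=diameters,
                precoded_profile=precoded,
                sex=None if "sex" not in row.index or pd.isna(row.get("sex")) else str(row["sex"]),
                modality=None
                if "modality" not in row.index or pd.isna(row.get("modality"))
                else str(row["modality"]).strip().upper(),
                slice_thickness_mm=_opt_float(row, "slice_thickness_mm"),
                quality_ok=_opt_bool(row, "quality_ok"),
            )
            if rec.diameters is None and rec.precoded_profile is None:
                raise IntegrityError(
                    f"{rec.family_id}/{rec.member_id}: neither diameters nor variant flags"
                )
            if rec.diameters is not None and rec.precoded_profile is not None:
                if rec.diameters.complete and classify(rec.diameters, rules) != rec.precoded_profile:
                    raise IntegrityError(
                        f"{rec.family_id}/{rec.member_id}: pre-coded variant flags "
                        "contradict the classification of the diameters"
                    )
            members.append(rec)
        probands = [m for m in members if m.is_proband]
        if len(probands) != 1:
            raise IntegrityError(
                f"family {family_id}: expected exactly one proband, found {len(probands)}"
            )
        fdrs = tuple(m for m in members if not m.is_proband)
        if not fdrs:
            raise IntegrityError(f"family {family_id}: no FDR rows")
        families.append(FamilyUnit(str(family_id), probands[0], fdrs))
    if "group" in table.columns and not group_label:
        labels = table["group"].dropna().unique()
        if len(labels) == 1:
            group_label = str(labels[0])
    return Cohort(group_label=group_label, families=tuple(families))


def read_cohort_file(
    path: Union[str, Path],
    group_label: str = "",
    rules: ClassificationRules = ClassificationRules(),
    column_map: Optional[Mapping[str, str]] = None,
) -> Cohort:
    """Read a cohort from CSV or XLSX, optionally renaming columns first.

    ``column_map`` maps source column names to the canonical schema, for
    files whose headers differ (e.g. supplementary data exports).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        table = pd.read_excel(path)
    else:
        table = pd.read_csv(path, comment="#", float_precision="round_trip")
    if column_map:
        table = table.rename(columns=dict(column_map))
    return read_cohort(table, group_label, rules)


def apply_exclusions(cohort: Cohort) -> tuple[Cohort, list[dict]]:
    """Drop individuals failing the imaging criteria, then unusable families.

    Individual-level exclusions: digital subtraction angiography only, CTA
    with slice thickness over 1 mm, or poor-quality imaging. A family is
    then dropped when its proband was excluded or no FDR remains. The
    returned log has one dict per exclusion with keys family_id, member_id
    (None for family-level drops) and reason. Idempotent.
    """
    log: list[dict] = []
    kept_families = []
    for fam in cohort:
        kept, excluded = [], []
        for member in fam.members:
            reason = None
            if member.modality == "DSA":
                reason = "DSA only"
            elif (
                member.modality == "CTA"
                and member.slice_thickness_mm is not None
                and member.slice_thickness_mm > 1.0
            ):
                reason = "CTA slice >1mm"
            elif member.quality_ok is False:
                reason = "poor quality imaging"
            if reason:
                excluded.append(member)
                log.append(
                    {"family_id": fam.family_id, "member_id": member.member_id, "reason": reason}
                )
            else:
                kept.append(member)
        proband = next((m for m in kept if m.is_proband), None)
        fdrs = tuple(m for m in kept if not m.is_proband)
        if proband is None:
            log.append(
                {"family_id": fam.family_id, "member_id": None, "reason": "proband excluded"}
            )
        elif not fdrs:
            log.append(
                {"family_id": fam.family_id, "member_id": None, "reason": "no FDR remaining"}
            )
        else:
            kept_families.append(FamilyUnit(fam.family_id, proband, fdrs))
    return cohort.with_families(kept_families), log


def cohort_to_frame(cohort: Cohort, include_flags: bool = True) -> pd.DataFrame:
    """Flatten a cohort back to the canonical row-per-individual table."""
    rows = []
    for fam in cohort:
        for member in fam.members:
            row: dict = {
                "group": cohort.group_label,
                "family_id": member.family_id,
                "member_id": member.member_id,
                "role": member.role,
            }
            if member.diameters is not None:
                for col, v in zip(DIAMETER_COLUMNS, member.diameters.as_tuple()):
                    row[col] = v
            if include_flags and member.precoded_profile is not None:
                for col in FLAG_COLUMNS:
                    row[col] = int(Variant(col) in member.precoded_profile)
            for col, v in (
                ("sex", member.sex),
                ("modality", member.modality),
                ("slice_thickness_mm", member.slice_thickness_mm),
                ("quality_ok", member.quality_ok),
            ):
                if v is not None:
                    row[col] = v
            rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(cohort: Cohort, destination: Union[str, Path]) -> None:
    """Write a cohort to the canonical CSV schema."""
    cohort_to_frame(cohort).to_csv(destination, index=False)


def _aggregate_frame(result: AggregateResult) -> pd.DataFrame:
    rows = []
    for summary in result.outcomes.values():
        rows.append(
            {
                "outcome": summary.outcome.value,
                "n_index_families": summary.n_index_families,
                "median_index_concordance": summary.median_index_concordance,
                "median_comparison_concordance": summary.median_comparison_concordance,
                "median_or": summary.median_or,
                "median_ci_low": summary.median_ci_low,
                "median_ci_high": summary.median_ci_high,
                "n_converged": summary.n_converged,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "outcome",
            "n_index_families",
            "median_index_concordance",
            "median_comparison_concordance",
            "median_or",
            "median_ci_low",
            "median_ci_high",
            "n_converged",
        ],
    )


def _meta_frame(results: Mapping[Outcome, MetaResult]) -> pd.DataFrame:
    rows = []
    for outcome, r in results.items():
        rows.append(
            {
                "outcome": Outcome(outcome).value,
                "pooled_or": r.pooled_or,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "q": r.q,
                "df": r.df,
                "i2_percent": r.i2_percent,
                "heterogeneity": r.band,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["outcome", "pooled_or", "ci_low", "ci_high", "q", "df", "i2_percent", "heterogeneity"],
    )


def write_results(
    result: Union[AggregateResult, Mapping[Outcome, MetaResult]],
    destination: Union[str, Path],
    provenance: Optional[Mapping[str, object]] = None,
) -> None:
    """Write a result table to CSV, one row per outcome.

    A provenance header ('#'-prefixed comment lines: seed, iterations,
    config) precedes the data so the file alone determines a re-run; pandas
    reads it back with ``comment='#'`` at full float precision.
    """
    if isinstance(result, AggregateResult):
        frame = _aggregate_frame(result)
        header = {"group": result.group_label, "n_iterations": result.n_iterations, "seed": result.seed}
    else:
        frame = _meta_frame(result)
        header = {}
    if provenance:
        header.update(provenance)
    buf = _stdlib_io.StringIO()
    for k, v in header.items():
        buf.write(f"# {k}: {v}\n")
    # shortest-roundtrip float formatting so reading back is bit-exact
    frame.to_csv(buf, index=False, float_format=lambda x: repr(float(x)))
    Path(destination).write_text(buf.getvalue())
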