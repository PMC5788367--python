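"""End-to-end study orchestration: read, exclude, classify, resample, pool.

Groups are analysed separately; when two or more groups are supplied, each
outcome present in every group's aggregate is pooled by inverse-variance
fixed-effects meta-analysis of the groups' median ORs and CIs (standard
errors back-derived from the CI widths on the log scale).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .classify import ClassificationRules
from .concordance import ALL_OUTCOMES, Outcome
from .errors import UsageError
from .io import apply_exclusions, read_cohort_file, write_results
from .matching import AggregateResult, run_resampling
from .meta import MetaResult, StudyEffect, pool

__all__ = ["RunConfig", "run_full_study", "meta_analyse_groups"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Reproducible configuration of a full study run."""

    inputs: Sequence[str]
    group_labels: Sequence[str] = ()
    iterations: int = 1001
    seed: int = 0
    pool_rule: str = "disjoint"
    outcomes: Sequence[Outcome] = ALL_OUTCOMES
    rules: ClassificationRules = field(default_factory=ClassificationRules)
    output_dir: Optional[str] = None
    column_map: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        if not self.inputs:
            raise UsageError("at least one input cohort is required")
        if self.iterations < 1:
            raise UsageError("iterations must be >= 1")
        if self.group_labels and len(self.group_labels) != len(self.inputs):
            raise UsageError("group_labels must match inputs in length")


def meta_analyse_groups(
    aggregates: Sequence[AggregateResult],
) -> dict[Outcome, MetaResult]:
    """Pool per-outcome median ORs/CIs across groups (fixed effects)."""
    results: dict[Outcome, MetaResult] = {}
    shared = set(aggregates[0].outcomes)
    for agg in aggregates[1:]:
        shared &= set(agg.outcomes)
    for outcome in sorted(shared, key=lambda o: o.value):
        studies = [
            StudyEffect.from_or_ci(
                agg.outcomes[outcome].median_or,
                agg.outcomes[outcome].median_ci_low,
                agg.outcomes[outcome].median_ci_high,
                label=agg.group_label,
            )
            for agg in aggregates
        ]
        results[outcome] = pool(studies)
    return results


def run_full_study(
    config: RunConfig,
) -> tuple[dict[str, AggregateResult], Optional[dict[Outcome, MetaResult]]]:
    """Run every group through the pipeline and pool across groups.

    Returns the per-group aggregates and, when at least two groups were
    supplied, the per-outcome meta-analysis (otherwise ``None``). Result
    tables are written to ``config.output_dir`` when set.
    """
    labels = list(config.group_labels) or [Path(p).stem for p in config.inputs]
    aggregates: dict[str, AggregateResult] = {}
    for path, label in zip(config.inputs, labels):
        cohort = read_cohort_file(path, label, config.rules, config.column_map)
        cohort, exclusion_log = apply_exclusions(cohort)
        for entry in exclusion_log:
            log.warning("excluded %(family_id)s/%(member_id)s: %(reason)s", entry)
        aggregates[label] = run_resampling(
            cohort,
            n_iterations=config.iterations,
            seed=config.seed,
            outcomes=config.outcomes,
            pool_rule=config.pool_rule,
            rules=config.rules,
        )
        log.info("group %s: %d families analysed", label, len(cohort))

    meta: Optional[dict[Outcome, MetaResult]] = None
    if len(aggregates) >= 2:
        meta = meta_analyse_groups(list(aggregates.values()))
    else:
        log.info("single group supplied; meta-analysis stage skipped")

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        provenance = {"iterations": config.iterations, "seed": config.seed, "pool_rule": config.pool_rule}
        for label, agg in aggregates.items():
            write_results(agg, out / f"aggregate_{label}.csv", provenance)
        if meta is not None:
            write_results(meta, out / "meta.csv", provenance)
    return aggregates, meta
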