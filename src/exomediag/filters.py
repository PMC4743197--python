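"""The variant filter cascade applied per family before inheritance modelling.

Stages, in order: read-depth floor, population-frequency cap across the
consulted databases, same-run control-sample artifact removal, and the
phenotype-driven gene-panel split. Variants whose gene does not match the
phenotype query are *retained* in a separate "unmatched" pool (they remain
eligible for the known-pathogenic fallback), not discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ValidationError
from .types import (
    AnnotatedVariant,
    CASCADE_DATABASES,
    DEFAULT_HPO_QUERY,
    GenePanel,
    Pedigree,
    VariantKey,
)

logger = logging.getLogger(__name__)


@dataclass
class CascadeConfig:
    """Thresholds of the filter cascade.

    min_reads
        Minimum read depth in every affected carrier (default 5: variants
        covered by fewer than five reads are removed).
    max_af
        Benign-frequency cap; a variant is removed when its allele frequency
        is strictly above this value (default 0.02) in any consulted database.
    databases
        Databases consulted by the frequency filter.
    control_min_count
        Minimum number of same-run control samples carrying the identical
        allele for it to be called an artifact (default 4 of 8).
    hpo_query_terms
        HPO terms defining the phenotype of interest for the panel split.
    """

    min_reads: int = 5
    max_af: float = 0.02
    databases: tuple[str, ...] = CASCADE_DATABASES
    control_min_count: int = 4
    hpo_query_terms: frozenset[str] = DEFAULT_HPO_QUERY

    def __post_init__(self) -> None:
        if self.min_reads < 0:
            raise ValidationError("min_reads must be >= 0")
        if not 0.0 <= self.max_af <= 1.0:
            raise ValidationError("max_af must lie in [0, 1]")


@dataclass
class FilterTrace:
    """Per-stage accounting: (stage name, n in, n removed, n out)."""

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_removed: int) -> None:
        n_out = n_in - n_removed
        if n_out < 0:
            raise ValidationError(f"stage {name} removed more variants than it saw")
        if self.stages and self.stages[-1][3] != n_in:
            raise ValidationError(
                f"stage {name} input {n_in} != previous stage output "
                f"{self.stages[-1][3]}"
            )
        self.stages.append((name, n_in, n_removed, n_out))

    @property
    def n_in(self) -> int:
        return self.stages[0][1] if self.stages else 0

    @property
    def n_out(self) -> int:
        return self.stages[-1][3] if self.stages else 0

    def to_rows(self) -> list[dict]:
        return [
            {"stage": s, "n_in": a, "n_removed": r, "n_out": o}
            for s, a, r, o in self.stages
        ]


def filter_min_reads(
    variants: Iterable[AnnotatedVariant],
    pedigree: Pedigree,
    min_reads: int = 5,
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Remove variants covered by fewer than ``min_reads`` reads in any
    affected carrier. Evaluated per affected individual: a variant survives
    for the family only if it is adequately covered in every affected member
    that carries it. Missing depth counts as 0 and removes the variant."""
    kept, removed = [], []
    affected = [i.individual_id for i in pedigree.affected_members()]
    for v in variants:
        bad = False
        for sample in affected:
            if v.is_carrier(sample) and v.depth(sample) < min_reads:
                if sample not in v.read_depths:
                    logger.warning(
                        "missing depth for %s at %s:%d treated as 0",
                        sample, v.chrom, v.pos,
                    )
                bad = True
                break
        (removed if bad else kept).append(v)
    return kept, removed


def filter_population_frequency(
    variants: Iterable[AnnotatedVariant],
    databases: Sequence[str] = CASCADE_DATABASES,
    max_af: float = 0.02,
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Remove variants with allele frequency strictly above ``max_af`` in at
    least one consulted database. A database in which the allele was never
    observed contributes nothing (absence is not a frequency of 0)."""
    kept, removed = [], []
    for v in variants:
        for db, freq in v.pop_freqs.items():
            if freq < 0:
                raise ValidationError(
                    f"negative allele frequency {freq} in {db} at {v.chrom}:{v.pos}"
                )
        if any(
            db in v.pop_freqs and v.pop_freqs[db] > max_af for db in databases
        ):
            removed.append(v)
        else:
            kept.append(v)
    return kept, removed


def filter_run_controls(
    variants: Iterable[AnnotatedVariant],
    control_variant_sets: dict[str, set[VariantKey]],
    control_min_count: int = 4,
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Remove allele-identical variants recurring in the same-run control
    samples (sequencing artifacts): removed when present in at least
    ``control_min_count`` controls. With no controls the stage is skipped."""
    variants = list(variants)
    if not control_variant_sets:
        logger.warning("no control samples supplied; artifact stage skipped")
        return variants, []
    kept, removed = [], []
    for v in variants:
        count = sum(1 for keys in control_variant_sets.values() if v.key in keys)
        (removed if count >= control_min_count else kept).append(v)
    return kept, removed


def filter_phenotype_panel(
    variants: Iterable[AnnotatedVariant],
    panel: GenePanel,
    hpo_query_terms: Iterable[str] = DEFAULT_HPO_QUERY,
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Split variants into (matched, unmatched) by phenotype-relevant genes.

    A variant matches when its gene has at least one panel HPO term in the
    query set (plain set intersection; ontology-closure matching would need
    an ontology and is not applied here). Variants without a gene symbol are
    routed to the unmatched pool.
    """
    matched, unmatched = [], []
    query = set(hpo_query_terms)
    for v in variants:
        if not v.gene:
            logger.info("variant %s:%d has no gene symbol; unmatched", v.chrom, v.pos)
            unmatched.append(v)
        elif panel.gene_matches_terms(v.gene, query):
            matched.append(v)
        else:
            unmatched.append(v)
    return matched, unmatched


def apply_cascade(
    variants: Iterable[AnnotatedVariant],
    pedigree: Pedigree,
    config: CascadeConfig | None = None,
    panel: GenePanel | None = None,
    control_variant_sets: dict[str, set[VariantKey]] | None = None,
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant], FilterTrace,
           dict[str, list[AnnotatedVariant]]]:
    """Run the full cascade in order: depth, frequency, controls, phenotype.

    Returns ``(matched, unmatched, trace, removals)`` where ``removals`` maps
    stage name to the variants that stage removed. Every input variant ends
    up in exactly one of matched, unmatched, or a removal list.
    """
    config = config or CascadeConfig()
    variants = list(variants)
    trace = FilterTrace()
    removals: dict[str, list[AnnotatedVariant]] = {}

    n = len(variants)
    variants, gone = filter_min_reads(variants, pedigree, config.min_reads)
    trace.add("min_reads", n, len(gone))
    removals["min_reads"] = gone

    n = len(variants)
    variants, gone = filter_population_frequency(
        variants, config.databases, config.max_af
    )
    trace.add("population_frequency", n, len(gone))
    removals["population_frequency"] = gone

    n = len(variants)
    variants, gone = filter_run_controls(
        variants, control_variant_sets or {}, config.control_min_count
    )
    trace.add("run_controls", n, len(gone))
    removals["run_controls"] = gone

    n = len(variants)
    if panel is None:
        panel = GenePanel([])
    matched, unmatched = filter_phenotype_panel(
        variants, panel, config.hpo_query_terms
    )
    trace.add("phenotype_panel", n, len(unmatched))
    return matched, unmatched, trace, removals
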