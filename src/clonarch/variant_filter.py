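"""Somatic-variant quality filter chain and cancer-gene subsetting.

Four rules, applied in order:

1. population frequency <= ``pop_freq_max`` (missing = never observed, passes);
2. alt-supporting reads strictly greater than ``min_alt_reads_exclusive``;
3. VAF >= ``vaf_min``;
4. functional consequence only (drops synonymous and noncoding calls).

The report records the number of survivors after every rule, so the chain
is auditable (counts are monotone non-increasing).
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .models import FilterReport, MutationRecord, NONFUNCTIONAL_CLASSES

RULES = ("population_freq", "supporting_reads", "vaf", "functional")


def apply_quality_filters(
    records: Sequence[MutationRecord],
    pop_freq_max: float = 0.01,
    min_alt_reads_exclusive: int = 3,
    vaf_min: float = 0.01,
    functional_only: bool = True,
) -> tuple[list[MutationRecord], FilterReport]:
    """Apply the four-rule quality chain; returns survivors and a report."""
    counts: dict[str, int] = {}
    kept = list(records)

    kept = [r for r in kept if r.population_freq is None or r.population_freq <= pop_freq_max]
    counts["population_freq"] = len(kept)

    kept = [r for r in kept if r.alt_count > min_alt_reads_exclusive]
    counts["supporting_reads"] = len(kept)

    kept = [r for r in kept if r.depth > 0 and r.vaf >= vaf_min]
    counts["vaf"] = len(kept)

    if functional_only:
        kept = [r for r in kept if r.variant_class not in NONFUNCTIONAL_CLASSES]
    counts["functional"] = len(kept)

    report = FilterReport(
        counts_in=len(records), counts_after_each_rule=counts, counts_out=len(kept)
    )
    return kept, report


def subset_cancer_genes(
    records: Sequence[MutationRecord], cancer_gene_list: Iterable[str]
) -> list[MutationRecord]:
    """Keep records on known cancer genes (exact, case-sensitive symbol match)
    or already flagged as cancer-gene calls upstream."""
    genes = set(cancer_gene_list)
    if not genes:
        raise ValueError("cancer gene list is empty")
    return [r for r in records if r.gene in genes or r.is_cancer_gene]
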