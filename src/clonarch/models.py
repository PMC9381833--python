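"""Core domain types for paired-component tumor analysis.

A *component* is one histological region (lepidic or micropapillary) of a
lung adenocarcinoma, micro-dissected and sequenced on its own. All
coordinates are 1-based and inclusive at both ends (SEG convention);
chromosome names are stored without any ``chr`` prefix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

MutationKey = tuple[str, int, str, str]  # (chrom, pos, ref, alt)

FUNCTIONAL_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "splice", "inframe_indel", "other"}
)
NONFUNCTIONAL_CLASSES = frozenset({"synonymous", "noncoding"})
VARIANT_CLASSES = FUNCTIONAL_CLASSES | NONFUNCTIONAL_CLASSES


class Component(str, Enum):
    LEP = "LEP"
    MIP = "MIP"
    OTHER = "OTHER"


def normalize_chrom(chrom: str) -> str:
    """Strip any leading 'chr' prefix; chromosome names are bare ('7', 'X')."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


@dataclass
class MutationRecord:
    """One somatic SNV/InDel call in one sequenced component."""

    sample_id: str
    patient_id: str
    component: Component
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    variant_class: str
    alt_count: int
    ref_count: int
    population_freq: Optional[float] = None
    is_cancer_gene: bool = False
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        self.component = Component(self.component)
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.alt_count < 0 or self.ref_count < 0:
            raise ValueError("read counts must be non-negative")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.population_freq is not None:
            if isinstance(self.population_freq, float) and math.isnan(self.population_freq):
                self.population_freq = None
            elif not 0.0 <= self.population_freq <= 1.0:
                raise ValueError(f"population_freq outside [0,1]: {self.population_freq}")

    @property
    def key(self) -> MutationKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def depth(self) -> int:
        return self.alt_count + self.ref_count

    @property
    def vaf(self) -> float:
        if self.depth == 0:
            raise ValueError(f"zero depth at {self.chrom}:{self.pos}")
        return self.alt_count / self.depth


@dataclass
class CopySegment:
    """One allele-specific copy-number segment of one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float
    major_cn: int
    minor_cn: int
    segment_ccf: Optional[float] = None

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.start > self.end:
            raise ValueError(f"segment start > end: {self.start} > {self.end}")
        if self.minor_cn > self.major_cn:
            raise ValueError("minor_cn exceeds major_cn")
        if self.major_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.segment_ccf is not None:
            if isinstance(self.segment_ccf, float) and math.isnan(self.segment_ccf):
                self.segment_ccf = None
            elif not 0.0 < self.segment_ccf <= 1.0:
                raise ValueError(f"segment_ccf outside (0,1]: {self.segment_ccf}")

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_cnloh(self) -> bool:
        """Copy-neutral loss of heterozygosity: total copy number 2, one allele lost."""
        return self.total_cn == 2 and self.minor_cn == 0

    def covers(self, chrom: str, pos: int) -> bool:
        return self.chrom == normalize_chrom(chrom) and self.start <= pos <= self.end


@dataclass
class ComponentSample:
    """A sequenced component with its purity/ploidy estimate."""

    sample_id: str
    patient_id: str
    component: Component
    purity: float
    ploidy: float = 2.0
    capture_size_mb: float = 53.0  # custom whole-exon capture, Mb

    def __post_init__(self) -> None:
        self.component = Component(self.component)
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity outside (0,1]: {self.purity}")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        if self.capture_size_mb <= 0:
            raise ValueError("capture_size_mb must be positive")


@dataclass
class GeneModel:
    gene: str
    chrom: str
    start: int
    end: int
    arm: str = "q"

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.start > self.end:
            raise ValueError(f"gene {self.gene}: start > end")
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be 'p' or 'q', got {self.arm!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class ClonalityCall:
    """CCF estimate with uncertainty and clonal/subclonal label for one mutation."""

    sample_id: str
    key: MutationKey
    vaf: float
    multiplicity: int
    ccf: float
    ccf_ci_low: float
    ccf_ci_high: float
    clonal_probability: float
    label: Optional[str] = None  # "clonal" | "subclonal"

    def __post_init__(self) -> None:
        if not self.ccf_ci_low <= self.ccf <= self.ccf_ci_high:
            raise ValueError("CCF point estimate outside its CI")
        if not 0.0 <= self.clonal_probability <= 1.0:
            raise ValueError("clonal_probability outside [0,1]")
        if self.label is not None and self.label not in ("clonal", "subclonal"):
            raise ValueError(f"bad label {self.label!r}")


@dataclass
class FilterReport:
    counts_in: int
    counts_after_each_rule: dict[str, int]
    counts_out: int

    def __post_init__(self) -> None:
        prev = self.counts_in
        for rule, n in self.counts_after_each_rule.items():
            if n > prev:
                raise ValueError(f"filter chain not monotone at rule {rule!r}")
            prev = n
        if self.counts_out != prev:
            raise ValueError("counts_out disagrees with last rule count")


@dataclass
class MutationIthMetrics:
    sample_id: str
    math: float
    ctmb: float
    subclonal_mut_proportion: float


@dataclass
class FocalCall:
    sample_id: str
    gene: str
    direction: str  # amplified | deleted | neutral
    statistic: float
    p: float
    q: float


@dataclass
class ScnaIthMetrics:
    sample_id: str
    subclonal_scna_proportion: Optional[float]  # segment-count basis; None if no altered segs
    subclonal_genome_fraction: float  # length-weighted
    arm_burden: dict[str, float] = field(default_factory=dict)
    chrom_burden: dict[str, float] = field(default_factory=dict)


@dataclass
class PairTree:
    """Two-leaf phylogeny of one patient's LEP/MIP component pair."""

    patient_id: str
    trunk_mutations: frozenset[MutationKey]
    branch_lep: frozenset[MutationKey]
    branch_mip: frozenset[MutationKey]
    shared_subclonal: frozenset[MutationKey]
    trunk_scna: frozenset[tuple[str, str]] = frozenset()
    branch_scna_lep: frozenset[tuple[str, str]] = frozenset()
    branch_scna_mip: frozenset[tuple[str, str]] = frozenset()
    trunk_drivers: frozenset[str] = frozenset()

    @property
    def shared_mutations(self) -> frozenset[MutationKey]:
        return self.trunk_mutations | self.shared_subclonal


@dataclass
class TransitionRecord:
    key: MutationKey
    label: str  # see phylogeny.TRANSITION_LABELS


@dataclass
class TestResult:
    name: str
    statistic: float
    p: float
    q: Optional[float] = None
    sidedness: str = "two-sided"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p outside [0,1]: {self.p}")


@dataclass
class AlterationFrequencyRow:
    gene: str
    alteration_type: str  # Mutation | Duplication | Deletion
    n_altered_lep: int
    n_lep: int
    n_altered_mip: int
    n_mip: int
    n_mutations_lep: Optional[int] = None
    n_mutations_mip: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_altered_lep > self.n_lep or self.n_altered_mip > self.n_mip:
            raise ValueError("altered count exceeds group size")
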