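"""Somatic copy-number analysis: CNLOH handling, focal calls, gene-level CN,
and SCNA-level intratumor-heterogeneity metrics.

Copy-neutral LOH (total copy number 2 with the minor allele lost) is
flagged first and excluded from all clonality-based SCNA metrics. Focal
calls test each gene's tumor log2 ratio against a normal-panel baseline
(z-test, BH-adjusted within sample, with a minimum log2 effect so trivial
wobbles are never called). Gene-level copy number is the copy number of
the segment covering the gene midpoint — deterministic and robust to genes
straddling a breakpoint.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .models import CopySegment, FocalCall, GeneModel, ScnaIthMetrics
from .stats import bh_adjust

logger = logging.getLogger(__name__)


def flag_cnloh(segments: Sequence[CopySegment]) -> tuple[list[CopySegment], list[CopySegment]]:
    """Split segments into (non-CNLOH, CNLOH).

    CNLOH = total copy number 2 AND minor copy number 0. Downstream
    clonality metrics must only see the first list.
    """
    keep: list[CopySegment] = []
    cnloh: list[CopySegment] = []
    for seg in segments:
        if seg.minor_cn is None:
            logger.warning(
                "segment %s:%d-%d of %s lacks minor_cn; skipped",
                seg.chrom, seg.start, seg.end, seg.sample_id,
            )
            continue
        (cnloh if seg.is_cnloh else keep).append(seg)
    return keep, cnloh


def call_focal_scna(
    gene_log2: Mapping[str, float],
    normal_baseline: Mapping[str, tuple[float, float]],
    sample_id: str = "",
    q_threshold: float = 0.05,
    effect_min: float = 0.2,
) -> list[FocalCall]:
    """Per-gene focal SCNA calls against a normal-panel baseline.

    ``normal_baseline`` maps gene -> (mean, sd) of log2 ratios in normals.
    Per gene: z = (log2_tumor - mean) / sd, two-sided normal p, BH across
    the sample's genes; amplified needs q <= q_threshold AND log2 >=
    +effect_min (deleted symmetric). Genes missing from the baseline are
    excluded and counted in the log.
    """
    genes = [g for g in sorted(gene_log2) if g in normal_baseline]
    n_missing = len(gene_log2) - len(genes)
    if n_missing:
        logger.info("%d gene(s) absent from normal baseline; excluded", n_missing)
    zs, ps = [], []
    for g in genes:
        mean, sd = normal_baseline[g]
        if sd <= 0:
            raise ValueError(f"non-positive baseline sd for gene {g}")
        z = (gene_log2[g] - mean) / sd
        zs.append(z)
        ps.append(2.0 * sps.norm.sf(abs(z)))
    qs = bh_adjust(ps) if ps else np.array([])
    calls = []
    for g, z, p, q in zip(genes, zs, ps, qs):
        direction = "neutral"
        if q <= q_threshold:
            if gene_log2[g] >= effect_min:
                direction = "amplified"
            elif gene_log2[g] <= -effect_min:
                direction = "deleted"
        calls.append(
            FocalCall(sample_id=sample_id, gene=g, direction=direction,
                      statistic=float(z), p=float(p), q=float(q))
        )
    return calls


def gene_level_cn(
    segments: Sequence[CopySegment], gene_model: Sequence[GeneModel]
) -> dict[str, Optional[int]]:
    """Total copy number per gene from the segment covering its midpoint;
    genes not covered by any segment map to None."""
    out: dict[str, Optional[int]] = {}
    for gene in gene_model:
        mid = gene.midpoint
        seg = next((s for s in segments if s.covers(gene.chrom, mid)), None)
        out[gene.gene] = None if seg is None else seg.total_cn
    return out


def scna_ith_metrics(
    segments: Sequence[CopySegment],
    ploidy: float,
    sample_id: str = "",
    subclonal_ccf_cutoff: float = 0.9,
    gene_model: Optional[Sequence[GeneModel]] = None,
    arm_lengths: Optional[Mapping[str, int]] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> ScnaIthMetrics:
    """SCNA-level ITH for one sample (CNLOH must already be excluded).

    A segment is *altered* when its total copy number differs from the
    rounded sample ploidy, and *subclonal* when segment_ccf falls below
    the cutoff. The proportion is on a segment-count basis; the genome
    fraction is length-weighted over the total segmented length. Arm and
    chromosome burdens are altered length over arm/chromosome length
    (segmented length when true lengths are not supplied).
    """
    base_cn = round(ploidy)
    altered = [s for s in segments if s.total_cn != base_cn]
    subclonal = [
        s for s in altered if s.segment_ccf is not None and s.segment_ccf < subclonal_ccf_cutoff
    ]
    total_len = sum(s.length for s in segments)
    proportion = len(subclonal) / len(altered) if altered else None
    genome_fraction = (sum(s.length for s in subclonal) / total_len) if total_len else 0.0

    arm_of: dict[tuple[str, int], str] = {}
    if gene_model is not None:
        # segment arm = arm of the gene nearest its midpoint (same chromosome)
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in gene_model:
            by_chrom.setdefault(g.chrom, []).append(g)
        for s in segments:
            mid = (s.start + s.end) // 2
            genes = by_chrom.get(s.chrom)
            if genes:
                nearest = min(genes, key=lambda g: abs(g.midpoint - mid))
                arm_of[(s.chrom, s.start)] = nearest.arm

    def _burden(keyfn, denominators: Optional[Mapping[str, int]]) -> dict[str, float]:
        alt_len: dict[str, float] = {}
        tot_len: dict[str, float] = {}
        for s in segments:
            k = keyfn(s)
            if k is None:
                continue
            tot_len[k] = tot_len.get(k, 0.0) + s.length
            if s.total_cn != base_cn:
                alt_len[k] = alt_len.get(k, 0.0) + s.length
        return {
            k: min(alt_len.get(k, 0.0) / (denominators.get(k, tot_len[k]) if denominators else tot_len[k]), 1.0)
            for k in tot_len
        }

    chrom_burden = _burden(lambda s: s.chrom, chrom_lengths)
    arm_burden: dict[str, float] = {}
    if arm_of:
        arm_burden = _burden(
            lambda s: f"{s.chrom}{arm_of[(s.chrom, s.start)]}" if (s.chrom, s.start) in arm_of else None,
            arm_lengths,
        )
    return ScnaIthMetrics(
        sample_id=sample_id,
        subclonal_scna_proportion=proportion,
        subclonal_genome_fraction=genome_fraction,
        arm_burden=arm_burden,
        chrom_burden=chrom_burden,
    )
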