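"""Cancer-cell-fraction estimation, clonal/subclonal calls, mutation-level ITH.

The CCF model is a deliberate simplification of full purity/ploidy
optimisation: with purity ``p``, local total copy number ``CN_t`` and
mutation multiplicity ``m``,

    CCF = VAF * (p * CN_t + 2 * (1 - p)) / (p * m)

Multiplicity is estimated from the data by rounding ``VAF * (p*CN_t +
2(1-p)) / p`` and clamping to [1, major_cn]. The 95% CI comes from
Clopper–Pearson bounds on the VAF pushed through the same linear map
(deliberately not truncated at 1, so the upper bound can exceed 1 — the
clonality rule needs that). The clonal probability is the posterior mass
of CCF >= ``ccf_clonal_threshold`` under a flat-prior Beta(alt+1, ref+1)
on the VAF.

A mutation is called clonal when the clonal probability exceeds 0.5 AND
the CCF CI upper bound reaches 1; everything else is subclonal.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .models import (
    ClonalityCall,
    ComponentSample,
    CopySegment,
    MutationIthMetrics,
    MutationRecord,
)


def clopper_pearson(alt: int, depth: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial CI on the success fraction."""
    if depth <= 0:
        raise ValueError("zero depth")
    ref = depth - alt
    low = 0.0 if alt == 0 else float(stats.beta.ppf(alpha / 2, alt, ref + 1))
    high = 1.0 if ref == 0 else float(stats.beta.ppf(1 - alpha / 2, alt + 1, ref))
    return low, high


def estimate_ccf(
    record: MutationRecord,
    sample: ComponentSample,
    segment: CopySegment,
    alpha: float = 0.05,
    ccf_clonal_threshold: float = 0.9,
) -> ClonalityCall:
    """CCF point estimate, 95% CI and clonal probability for one mutation.

    The returned call carries no clonal/subclonal label yet; see
    :func:`classify_clonality`.
    """
    if record.depth == 0:
        raise ValueError(f"zero depth for mutation {record.key}")
    if not segment.covers(record.chrom, record.pos):
        raise ValueError(
            f"mutation {record.key} not covered by segment "
            f"{segment.chrom}:{segment.start}-{segment.end}"
        )
    p = sample.purity
    cnt = segment.total_cn
    denom = p * cnt + 2.0 * (1.0 - p)
    vaf = record.vaf
    m = int(np.clip(round(vaf * denom / p), 1, max(segment.major_cn, 1)))
    factor = denom / (p * m)  # CCF = VAF * factor
    ccf = vaf * factor
    lo, hi = clopper_pearson(record.alt_count, record.depth, alpha=alpha)
    # posterior P(CCF >= threshold) under flat-prior Beta on the VAF
    vaf_at_threshold = ccf_clonal_threshold / factor
    if vaf_at_threshold >= 1.0:
        clonal_prob = 0.0
    else:
        clonal_prob = float(
            stats.beta.sf(vaf_at_threshold, record.alt_count + 1, record.ref_count + 1)
        )
    return ClonalityCall(
        sample_id=record.sample_id,
        key=record.key,
        vaf=vaf,
        multiplicity=m,
        ccf=ccf,
        ccf_ci_low=lo * factor,
        ccf_ci_high=hi * factor,
        clonal_probability=clonal_prob,
    )


def classify_clonality(
    call: ClonalityCall,
    prob_cutoff: float = 0.5,
    ci_high_min: float = 1.0,
    strict_ci: bool = False,
) -> ClonalityCall:
    """Set the clonal/subclonal label on a CCF call.

    Clonal requires both a clonal probability above ``prob_cutoff`` and a
    CCF CI upper bound reaching ``ci_high_min`` (``>=`` by default;
    ``strict_ci=True`` demands a strict excess).
    """
    ci_ok = call.ccf_ci_high > ci_high_min if strict_ci else call.ccf_ci_high >= ci_high_min
    call.label = "clonal" if (call.clonal_probability > prob_cutoff and ci_ok) else "subclonal"
    return call


def call_sample_clonality(
    records: Sequence[MutationRecord],
    sample: ComponentSample,
    segments: Sequence[CopySegment],
    alpha: float = 0.05,
    ccf_clonal_threshold: float = 0.9,
    prob_cutoff: float = 0.5,
) -> list[ClonalityCall]:
    """Estimate and classify every mutation of one sample against its segments."""
    calls = []
    for rec in records:
        seg = next((s for s in segments if s.covers(rec.chrom, rec.pos)), None)
        if seg is None:
            raise ValueError(f"no copy segment covers mutation {rec.key} in {sample.sample_id}")
        call = estimate_ccf(rec, sample, seg, alpha=alpha, ccf_clonal_threshold=ccf_clonal_threshold)
        calls.append(classify_clonality(call, prob_cutoff=prob_cutoff))
    return calls


def math_score(vafs: Sequence[float]) -> float:
    """Mutant-allele tumor heterogeneity: 100 * 1.4826 * MAD(VAF) / median(VAF)."""
    v = np.asarray(vafs, dtype=float)
    if v.size < 2:
        raise ValueError("MATH needs at least two VAF values")
    med = float(np.median(v))
    if med <= 0:
        raise ValueError("MATH undefined for zero median VAF")
    mad = float(np.median(np.abs(v - med)))
    return 100.0 * 1.4826 * mad / med


def mutation_ith_metrics(
    calls: Sequence[ClonalityCall], sample: ComponentSample
) -> MutationIthMetrics:
    """Per-sample mutation-level ITH: MATH, clonal TMB (per Mb of capture),
    subclonal mutation proportion."""
    if not calls:
        raise ValueError(f"no clonality calls for sample {sample.sample_id}")
    if any(c.label is None for c in calls):
        raise ValueError("unlabeled calls; run classify_clonality first")
    n_clonal = sum(1 for c in calls if c.label == "clonal")
    return MutationIthMetrics(
        sample_id=sample.sample_id,
        math=math_score([c.vaf for c in calls]),
        ctmb=n_clonal / sample.capture_size_mb,
        subclonal_mut_proportion=(len(calls) - n_clonal) / len(calls),
    )
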