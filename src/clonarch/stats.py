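"""Group-level statistics for subtype comparisons.

Alteration-frequency tallies across LEP/MIP groups, Fisher's exact test,
Benjamini–Hochberg adjustment, Mann–Whitney (exact by enumeration for the
small paired-cohort group sizes, tie-corrected normal approximation
otherwise), Spearman correlation, and one-sided Welch t-tests.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .models import AlterationFrequencyRow, FocalCall, MutationRecord, TestResult

#: pooled-size cutoff below which the Mann–Whitney p is computed by full
#: enumeration of group assignments (covers 5-vs-6 component cohorts).
MWU_EXACT_MAX_N = 12

_DIRECTION_TO_TYPE = {"amplified": "Duplication", "deleted": "Deletion"}


def alteration_frequency_table(
    mutations: Sequence[MutationRecord],
    focal_calls: Sequence[FocalCall],
    group_of: Mapping[str, str],
) -> list[AlterationFrequencyRow]:
    """Tally per-gene alteration frequency across the two groups.

    ``group_of`` maps every sample id to "LEP" or "MIP" and defines the
    group sizes (every mapped sample counts toward its denominator, also
    when it carries no alteration). A sample counts once per gene per
    alteration type regardless of how many mutations it carries there;
    mutation rows additionally report the raw mutation tallies.
    """
    n_group = {"LEP": 0, "MIP": 0}
    for g in group_of.values():
        if g not in n_group:
            raise ValueError(f"unknown group label {g!r} (expected LEP or MIP)")
        n_group[g] += 1

    def _group(sample_id: str) -> str:
        try:
            return group_of[sample_id]
        except KeyError:
            raise ValueError(f"sample {sample_id!r} has no group label") from None

    mut_samples: dict[str, dict[str, set[str]]] = {}
    mut_counts: dict[str, dict[str, int]] = {}
    for rec in mutations:
        g = _group(rec.sample_id)
        mut_samples.setdefault(rec.gene, {"LEP": set(), "MIP": set()})[g].add(rec.sample_id)
        mut_counts.setdefault(rec.gene, {"LEP": 0, "MIP": 0})[g] += 1

    cnv_samples: dict[tuple[str, str], dict[str, set[str]]] = {}
    for call in focal_calls:
        if call.direction == "neutral":
            continue
        g = _group(call.sample_id)
        key = (call.gene, _DIRECTION_TO_TYPE[call.direction])
        cnv_samples.setdefault(key, {"LEP": set(), "MIP": set()})[g].add(call.sample_id)

    rows: list[AlterationFrequencyRow] = []
    for gene in sorted(mut_samples):
        by = mut_samples[gene]
        rows.append(
            AlterationFrequencyRow(
                gene=gene,
                alteration_type="Mutation",
                n_altered_lep=len(by["LEP"]),
                n_lep=n_group["LEP"],
                n_altered_mip=len(by["MIP"]),
                n_mip=n_group["MIP"],
                n_mutations_lep=mut_counts[gene]["LEP"],
                n_mutations_mip=mut_counts[gene]["MIP"],
            )
        )
    for gene, alt_type in sorted(cnv_samples):
        by = cnv_samples[(gene, alt_type)]
        rows.append(
            AlterationFrequencyRow(
                gene=gene,
                alteration_type=alt_type,
                n_altered_lep=len(by["LEP"]),
                n_lep=n_group["LEP"],
                n_altered_mip=len(by["MIP"]),
                n_mip=n_group["MIP"],
            )
        )
    return rows


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher's exact test on [[a, b], [c, d]].

    Two-sided by the minimum-likelihood convention: sum hypergeometric
    probabilities of all tables with fixed margins whose probability does
    not exceed the observed table's.
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("Fisher table entries must be non-negative integers")
    if a + b + c + d == 0:
        return TestResult(name="fisher_exact", statistic=math.nan, p=1.0)
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TestResult(name="fisher_exact", statistic=float(odds), p=float(min(p, 1.0)))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR), input order kept."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    # ties count half, the Mann-Whitney convention
    diff = x[:, None] - y[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney(
    x: Sequence[float], y: Sequence[float], sided: str = "two-sided"
) -> TestResult:
    """Mann–Whitney U test.

    Exact permutation p (full enumeration of group assignments, ties
    allowed) when the pooled size is at most ``MWU_EXACT_MAX_N``;
    tie-corrected normal approximation otherwise. For the two-sided exact
    test, a relabelling is at least as extreme as the data when its U lies
    at least as far from the null mean n1*n2/2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _u_statistic(x, y)
    n1, n2 = x.size, y.size
    if n1 + n2 <= MWU_EXACT_MAX_N:
        pooled = np.concatenate([x, y])
        mean_u = n1 * n2 / 2.0
        hits = total = 0
        eps = 1e-12
        for idx in combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if sided == "two-sided":
                hits += abs(u - mean_u) >= abs(u_obs - mean_u) - eps
            elif sided == "greater":
                hits += u >= u_obs - eps
            elif sided == "less":
                hits += u <= u_obs + eps
            else:
                raise ValueError(f"bad sidedness {sided!r}")
        p = hits / total
        method = "exact-permutation"
    else:
        res = sps.mannwhitneyu(x, y, alternative=sided, method="asymptotic")
        p = float(res.pvalue)
        method = "normal-approximation"
    return TestResult(
        name="mann_whitney",
        statistic=u_obs,
        p=min(float(p), 1.0),
        sidedness=sided,
        extra={"method": method},
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties); NaN for a constant vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    return float(sps.spearmanr(x, y).statistic)


def t_test_one_sided(
    x: Sequence[float], y: Sequence[float], direction: str = "greater"
) -> TestResult:
    """One-sided Welch t-test; ``direction='greater'`` tests mean(x) > mean(y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least two observations")
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be greater/less, got {direction!r}")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult(name="welch_t", statistic=0.0, p=0.5, sidedness=direction)
        p = 0.0 if (np.mean(x) > np.mean(y)) == (direction == "greater") else 1.0
        return TestResult(name="welch_t", statistic=math.inf, p=p, sidedness=direction)
    res = sps.ttest_ind(x, y, equal_var=False, alternative=direction)
    return TestResult(
        name="welch_t", statistic=float(res.statistic), p=float(res.pvalue), sidedness=direction
    )


def predominance_percentages(counts: Mapping[str, int], ndigits: int = 1) -> dict[str, float]:
    """Percentage of patients per predominant histological subtype."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty cohort")
    return {k: round(100.0 * v / total, ndigits) for k, v in counts.items()}
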