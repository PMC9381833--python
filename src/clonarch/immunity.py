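"""Cancer-immunity-cycle step activity scoring by single-sample GSEA.

Each step of the cycle (antigen release, priming, trafficking,
infiltration, recognition, killing, ...) is a gene signature; per sample
the score is the Barbie-style integrated difference between the weighted
in-set ECDF and the uniform out-of-set ECDF over the expression-ranked
gene list. The rank statistic is the rank value itself, weighted by
``|rank|**alpha`` (alpha = 0.25 by default); ties are broken by gene name
so scores are deterministic. The raw score depends only on within-sample
ranks; an optional per-step min-max normalization across samples puts
steps on a common [0, 1] scale.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import GeneSet, TestResult
from .stats import bh_adjust, mann_whitney

logger = logging.getLogger(__name__)

MIN_SET_GENES = 2


def _sample_score(
    expr: pd.Series, genes_sorted: np.ndarray, in_set: np.ndarray, alpha: float
) -> float:
    # descending expression, ties by gene-name order (genes_sorted is name-sorted)
    order = np.argsort(-expr.to_numpy(), kind="stable")
    in_ranked = in_set[order]
    n = in_set.size
    ranks = np.arange(n, 0, -1, dtype=float)  # top gene gets the largest rank value
    w = np.abs(ranks) ** alpha
    w_in = np.where(in_ranked, w, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    n_out = n - int(in_ranked.sum())
    p_out = np.cumsum(~in_ranked) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    expr: pd.DataFrame,
    gene_sets: Sequence[GeneSet],
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Score every gene set in every sample; returns steps x samples.

    ``expr`` is genes x samples. Sets with fewer than two genes present in
    the matrix are skipped with a warning. With ``normalize=True`` each
    step's scores are min-max scaled across samples; switch off to get the
    raw rank-only scores (monotone-transform invariant).
    """
    if expr.index.has_duplicates:
        raise ValueError("duplicate gene rows in expression matrix")
    # canonical name-sorted orientation makes the tie-break stable
    expr = expr.sort_index(kind="stable")
    genes = expr.index.to_numpy()
    rows = {}
    for gs in gene_sets:
        in_set = np.isin(genes, sorted(gs.genes))
        if int(in_set.sum()) < MIN_SET_GENES:
            logger.warning("gene set %r has <%d genes in the matrix; skipped", gs.name, MIN_SET_GENES)
            continue
        if int(in_set.sum()) == len(genes):
            raise ValueError(f"gene set {gs.name!r} covers every gene; score undefined")
        rows[gs.name] = [
            _sample_score(expr[c], genes, in_set, alpha) for c in expr.columns
        ]
    scores = pd.DataFrame(rows, index=expr.columns).T
    if normalize and not scores.empty:
        lo = scores.min(axis=1)
        rng = scores.max(axis=1) - lo
        rng = rng.replace(0.0, 1.0)
        scores = scores.sub(lo, axis=0).div(rng, axis=0)
    return scores


def compare_step_activity(
    activity: pd.DataFrame, groups: Mapping[str, str]
) -> list[TestResult]:
    """Two-sided Mann–Whitney per step between the two groups, BH across steps.

    ``groups`` maps sample name -> group label (exactly two labels, each
    with at least two samples). The reported direction is the group whose
    median activity is higher.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    cols = {lab: [s for s in activity.columns if groups.get(s) == lab] for lab in labels}
    for lab, cs in cols.items():
        if len(cs) < 2:
            raise ValueError(f"group {lab!r} has fewer than two samples")
    results = []
    for step in activity.index:
        x = activity.loc[step, cols[labels[0]]].to_numpy(dtype=float)
        y = activity.loc[step, cols[labels[1]]].to_numpy(dtype=float)
        res = mann_whitney(x, y, sided="two-sided")
        res.name = step
        med_diff = float(np.median(x) - np.median(y))
        res.extra["higher_in"] = labels[0] if med_diff > 0 else labels[1] if med_diff < 0 else "tie"
        results.append(res)
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results
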