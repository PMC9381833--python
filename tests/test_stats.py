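"""Cohort statistics against independent oracles: Fisher exact vs full
hypergeometric enumeration, BH vs a step-up oracle, exact Mann–Whitney vs
permutation enumeration, Spearman vs rank-then-Pearson, Welch t vs the
textbook formula."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from clonarch.datasets import (
    EXAMPLE_PREDOMINANCE_COUNTS,
    example_group_labels,
    expand_example_cohort,
)
from clonarch.stats import (
    alteration_frequency_table,
    bh_adjust,
    fisher_exact_2x2,
    mann_whitney,
    predominance_percentages,
    spearman,
    t_test_one_sided,
)

from conftest import make_mutation


# ---------------------------------------------------------------- oracles
def fisher_oracle(a, b, c, d):
    """Two-sided p by full hypergeometric enumeration at fixed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    pmf = {k: sps.hypergeom.pmf(k, n, c1, r1) for k in range(lo, hi + 1)}
    obs = pmf[a]
    return sum(p for p in pmf.values() if p <= obs * (1 + 1e-7))


def bh_oracle(pvals):
    """Independent step-up: q_(i) = min_{j>=i} (m * p_(j) / j), capped at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        q[i] = min(running, 1.0)
    return q


def mwu_exact_oracle(x, y):
    """Two-sided exact p by enumerating rank-label permutations."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    mean_u = n1 * len(y) / 2.0
    obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2
        total += 1
        hits += abs(u - mean_u) >= abs(obs - mean_u) - 1e-12
    return hits / total


def welch_oracle(x, y, direction):
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    t = (np.mean(x) - np.mean(y)) / math.sqrt(vx / nx + vy / ny)
    df = (vx / nx + vy / ny) ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return sps.t.sf(t, df) if direction == "greater" else sps.t.cdf(t, df)


# ---------------------------------------------------------------- tests
class TestAlterationFrequency:
    def test_example_cohort_row_counts(self):
        muts, focal = expand_example_cohort()
        rows = alteration_frequency_table(muts, focal, example_group_labels())
        mut_rows = [r for r in rows if r.alteration_type == "Mutation"]
        cnv_rows = [r for r in rows if r.alteration_type != "Mutation"]
        assert len(mut_rows) == 9 and len(cnv_rows) == 5

    def test_sample_counted_once_per_gene(self):
        muts = [make_mutation(pos=p, gene="RYR2", sample_id="L01") for p in (1, 2, 3)]
        rows = alteration_frequency_table(muts, [], {"L01": "LEP", "M01": "MIP"})
        assert rows[0].n_altered_lep == 1 and rows[0].n_mutations_lep == 3

    def test_group_sizes_come_from_label_map(self):
        muts = [make_mutation(gene="A", sample_id="L01")]
        labels = {f"L{i:02d}": "LEP" for i in range(1, 6)}
        labels.update({f"M{i:02d}": "MIP" for i in range(1, 7)})
        row = alteration_frequency_table(muts, [], labels)[0]
        assert (row.n_lep, row.n_mip) == (5, 6)

    def test_unlabeled_sample_rejected(self):
        with pytest.raises(ValueError, match="no group label"):
            alteration_frequency_table([make_mutation(sample_id="ZZ")], [], {"L01": "LEP"})

    def test_empty_cohort(self):
        assert alteration_frequency_table([], [], {"L01": "LEP"}) == []


class TestFisher:
    def test_degenerate_margins(self):
        assert fisher_exact_2x2(0, 5, 0, 7).p == pytest.approx(1.0)

    def test_hand_enumerated_values(self):
        assert fisher_exact_2x2(3, 1, 1, 3).p == pytest.approx(34 / 70, rel=1e-7)
        assert fisher_exact_2x2(5, 0, 0, 5).p == pytest.approx(2 / 252, rel=1e-7)

    def test_all_zero_convention(self):
        assert fisher_exact_2x2(0, 0, 0, 0).p == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 1, 1, 1)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 9, size=4)
            assert fisher_exact_2x2(a, b, c, d).p == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-7
            ), (a, b, c, d)

    def test_row_and_column_swap_invariance(self):
        p1 = fisher_exact_2x2(2, 7, 5, 1).p
        p2 = fisher_exact_2x2(1, 5, 7, 2).p  # swap rows then columns
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestBh:
    def test_hand_computed_vector(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            p = rng.uniform(size=rng.integers(1, 30))
            assert bh_adjust(p) == pytest.approx(bh_oracle(list(p)), rel=1e-12)

    def test_q_dominates_p_and_order_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=15)
        q = bh_adjust(p)
        assert np.all(q >= p)
        perm = rng.permutation(15)
        assert bh_adjust(p[perm]) == pytest.approx(q[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)  # 2 of 20 arrangements as extreme
        assert res.extra["method"] == "exact-permutation"

    def test_identical_multisets_p_one(self):
        assert mann_whitney([1, 2, 2, 3], [1, 2, 2, 3]).p == pytest.approx(1.0)

    def test_matches_permutation_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n1, n2 = rng.integers(2, 6, size=2)
            x = rng.integers(0, 5, size=n1).astype(float)  # heavy ties
            y = rng.integers(0, 5, size=n2).astype(float)
            assert mann_whitney(x, y).p == pytest.approx(mwu_exact_oracle(x, y))

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            expected = sps.mannwhitneyu(x, y, method="exact").pvalue
            assert mann_whitney(x, y).p == pytest.approx(expected)

    def test_monotone_transform_invariance(self):
        x, y = [1.0, 2.0, 5.0], [3.0, 8.0, 9.0, 10.0]
        p1 = mann_whitney(x, y).p
        p2 = mann_whitney(np.exp(x), np.exp(y)).p
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [40, 30, 20, 10]) == pytest.approx(-1.0)

    def test_constant_vector_is_missing_not_zero(self):
        assert math.isnan(spearman([1, 1, 1], [1, 2, 3]))

    def test_ties_match_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = rng.integers(4, 25)
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            expected = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
            assert spearman(x, y) == pytest.approx(expected, rel=1e-12)


class TestWelchT:
    def test_extreme_shift(self):
        rng = np.random.default_rng(6)
        y = rng.normal(0, 1, size=20)
        x = y + 5.0
        assert t_test_one_sided(x, y, "greater").p < 1e-4

    def test_identical_groups_half(self):
        assert t_test_one_sided([1.0, 1.0], [1.0, 1.0], "greater").p == 0.5

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            x = rng.normal(size=rng.integers(3, 15))
            y = rng.normal(0.3, 1.2, size=rng.integers(3, 15))
            for direction in ("greater", "less"):
                assert t_test_one_sided(x, y, direction).p == pytest.approx(
                    welch_oracle(x, y, direction), rel=1e-9
                )


def test_predominance_percentages():
    pct = predominance_percentages(EXAMPLE_PREDOMINANCE_COUNTS)
    assert pct["LEP"] == 17.8 and pct["MIP"] == 10.1
    assert sum(EXAMPLE_PREDOMINANCE_COUNTS.values()) == 286
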