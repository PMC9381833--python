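"""CCF estimation with Clopper–Pearson uncertainty, the clonal/subclonal
rule, MATH, and per-sample mutation ITH metrics."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.optimize import brentq

from clonarch.clonality import (
    classify_clonality,
    clopper_pearson,
    estimate_ccf,
    math_score,
    mutation_ith_metrics,
)
from clonarch.models import ClonalityCall, ComponentSample

from conftest import make_mutation, make_sample


def cp_oracle(alt: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Independent Clopper–Pearson: bisection on binomial tail conditions."""
    lo = 0.0 if alt == 0 else brentq(
        lambda p: sps.binom.sf(alt - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-12
    )
    hi = 1.0 if alt == n else brentq(
        lambda p: sps.binom.cdf(alt, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-12
    )
    return lo, hi


class TestEstimateCcf:
    def test_half_purity_diploid_gives_ccf_one(self, diploid_segment):
        rec = make_mutation(alt_count=25, ref_count=75)  # VAF 0.25
        call = estimate_ccf(rec, make_sample(purity=0.5), diploid_segment)
        assert call.ccf == pytest.approx(1.0)
        assert call.multiplicity == 1

    def test_pure_tumor_limit(self, diploid_segment, sample_pure):
        rec = make_mutation(alt_count=50, ref_count=50)  # VAF 0.5
        call = estimate_ccf(rec, sample_pure, diploid_segment)
        assert call.ccf == pytest.approx(1.0)

    def test_ci_matches_independent_binomial_oracle(self, diploid_segment):
        """alt=50/ref=450 at purity 0.5: CCF 0.4, CI pinned by the oracle."""
        rec = make_mutation(alt_count=50, ref_count=450)
        call = estimate_ccf(rec, make_sample(purity=0.5), diploid_segment)
        lo, hi = cp_oracle(50, 500)
        factor = 4.0  # (0.5*2 + 2*0.5) / (0.5*1)
        assert call.ccf == pytest.approx(0.4)
        assert call.ccf_ci_low == pytest.approx(lo * factor, rel=1e-9)
        assert call.ccf_ci_high == pytest.approx(hi * factor, rel=1e-9)
        assert call.ccf_ci_low == pytest.approx(0.30054326, abs=1e-6)
        assert call.ccf_ci_high == pytest.approx(0.51883634, abs=1e-6)

    @pytest.mark.parametrize("alt,n", [(0, 50), (50, 50), (7, 200), (120, 300)])
    def test_clopper_pearson_vs_oracle(self, alt, n):
        assert clopper_pearson(alt, n) == pytest.approx(cp_oracle(alt, n), abs=1e-9)

    def test_ci_upper_may_exceed_one(self, diploid_segment):
        rec = make_mutation(alt_count=30, ref_count=30)
        call = estimate_ccf(rec, make_sample(purity=0.5), diploid_segment)
        assert call.ccf_ci_high > 1.0  # untruncated, required by the clonality rule

    def test_ccf_monotone_in_vaf(self, diploid_segment):
        sample = make_sample(purity=0.6)
        ccfs = [
            estimate_ccf(make_mutation(alt_count=a, ref_count=100 - a), sample, diploid_segment).ccf
            for a in range(5, 35, 5)
        ]
        assert all(a < b for a, b in zip(ccfs, ccfs[1:]))

    def test_zero_depth_rejected(self, diploid_segment):
        rec = make_mutation(alt_count=0, ref_count=0)
        with pytest.raises(ValueError, match="zero depth"):
            estimate_ccf(rec, make_sample(), diploid_segment)

    def test_uncovered_mutation_named(self, diploid_segment):
        rec = make_mutation(chrom="2")
        with pytest.raises(ValueError, match="not covered"):
            estimate_ccf(rec, make_sample(), diploid_segment)


class TestClassify:
    def _call(self, ccf, ci_high, prob, ci_low=0.0):
        return ClonalityCall(sample_id="S1", key=("1", 1, "A", "T"), vaf=0.3,
                             multiplicity=1, ccf=ccf, ccf_ci_low=ci_low,
                             ccf_ci_high=ci_high, clonal_probability=prob)

    def test_clonal_needs_both_conjuncts(self):
        assert classify_clonality(self._call(1.0, 1.2, 0.95)).label == "clonal"
        assert classify_clonality(self._call(0.3, 0.45, 0.95)).label == "subclonal"
        assert classify_clonality(self._call(1.0, 1.2, 0.3)).label == "subclonal"

    def test_boundary_ci_exactly_one_is_clonal_by_default(self):
        assert classify_clonality(self._call(0.9, 1.0, 0.8)).label == "clonal"
        assert classify_clonality(self._call(0.9, 1.0, 0.8), strict_ci=True).label == "subclonal"


class TestMath:
    def test_constant_vafs_score_zero(self):
        assert math_score([0.3, 0.3, 0.3]) == 0.0

    def test_hand_computed_value(self):
        # median 0.3, MAD 0.1 -> 100 * 1.4826 * 0.1 / 0.3
        assert math_score([0.1, 0.2, 0.3, 0.4, 0.5]) == pytest.approx(49.42)

    def test_scale_invariance(self):
        v = [0.12, 0.31, 0.08, 0.44, 0.25]
        assert math_score(v) == pytest.approx(math_score([x * 0.5 for x in v]))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            v = rng.uniform(0.01, 0.99, size=rng.integers(2, 40))
            med = sorted(v)[len(v) // 2] if len(v) % 2 else sum(sorted(v)[len(v) // 2 - 1:len(v) // 2 + 1]) / 2
            mad = sorted(abs(x - med) for x in v)
            mad = mad[len(v) // 2] if len(v) % 2 else (mad[len(v) // 2 - 1] + mad[len(v) // 2]) / 2
            assert math_score(v) == pytest.approx(100 * 1.4826 * mad / med)

    @pytest.mark.parametrize("bad", [[0.3], [0.0, 0.0, 0.0]])
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            math_score(bad)


class TestIthMetrics:
    def _calls(self, n_clonal, n_subclonal):
        out = []
        for i in range(n_clonal + n_subclonal):
            c = ClonalityCall(sample_id="S1", key=("1", i + 1, "A", "T"), vaf=0.25,
                              multiplicity=1, ccf=1.0, ccf_ci_low=0.8, ccf_ci_high=1.2,
                              clonal_probability=0.9)
            c.label = "clonal" if i < n_clonal else "subclonal"
            out.append(c)
        return out

    def test_ctmb_per_mb(self):
        m = mutation_ith_metrics(self._calls(53, 0), make_sample())
        assert m.ctmb == pytest.approx(1.0)

    def test_subclonal_proportion(self):
        m = mutation_ith_metrics(self._calls(4, 6), make_sample())
        assert m.subclonal_mut_proportion == pytest.approx(0.6)

    def test_conservation(self):
        sample = make_sample()
        calls = self._calls(7, 5)
        m = mutation_ith_metrics(calls, sample)
        n_sub = round(m.subclonal_mut_proportion * len(calls))
        assert m.ctmb * sample.capture_size_mb + n_sub == len(calls)

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError):
            mutation_ith_metrics([], make_sample())
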