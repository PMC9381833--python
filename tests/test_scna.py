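"""CNLOH flagging, focal SCNA calling against a normal baseline, gene-level
copy number, and SCNA-level ITH metrics."""

import numpy as np
import pytest

from clonarch.experiments import focal_null_false_call_rate, focal_recovery
from clonarch.models import CopySegment, GeneModel
from clonarch.scna import call_focal_scna, flag_cnloh, gene_level_cn, scna_ith_metrics
from clonarch.stats import spearman


def seg(start, end, major, minor, ccf=1.0, chrom="1", sample="S1", log2=0.0):
    return CopySegment(sample_id=sample, chrom=chrom, start=start, end=end,
                       log2_ratio=log2, major_cn=major, minor_cn=minor, segment_ccf=ccf)


class TestCnloh:
    @pytest.mark.parametrize("major,minor,expected", [
        (2, 0, True),   # copy-neutral LOH
        (1, 1, False),  # balanced diploid
        (3, 0, False),  # total 3, plain loss of one allele with gain
        (1, 0, False),  # deletion
    ])
    def test_definition(self, major, minor, expected):
        keep, cnloh = flag_cnloh([seg(1, 100, major, minor)])
        assert (len(cnloh) == 1) is expected
        assert len(keep) + len(cnloh) == 1


class TestFocal:
    def test_null_gene_neutral(self):
        calls = call_focal_scna({"A": 0.0}, {"A": (0.0, 0.1)})
        assert calls[0].direction == "neutral"

    def test_extreme_amplification_called(self):
        calls = call_focal_scna({"A": 1.0}, {"A": (0.0, 0.1)})
        assert calls[0].direction == "amplified"
        assert calls[0].statistic == pytest.approx(10.0)

    def test_significant_but_small_effect_suppressed(self):
        # z = 6 but |log2| below the 0.2 effect floor
        calls = call_focal_scna({"A": 0.12}, {"A": (0.0, 0.02)})
        assert calls[0].direction == "neutral"

    def test_gene_missing_from_baseline_excluded(self):
        calls = call_focal_scna({"A": 1.0, "B": 1.0}, {"A": (0.0, 0.1)})
        assert [c.gene for c in calls] == ["A"]

    def test_zero_baseline_sd_rejected(self):
        with pytest.raises(ValueError):
            call_focal_scna({"A": 0.1}, {"A": (0.0, 0.0)})

    def test_planted_effects_recovered(self):
        """log2 +-0.8 at sd 0.15: all planted genes recovered in >=95% of reps;
        false calls stay at the level FDR control admits (mean well below 1)."""
        res = focal_recovery(n_reps=100, seed=2)
        rng = np.random.default_rng(2)
        genes = [f"G{i:04d}" for i in range(1, 101)]
        base = {g: (0.0, 0.15) for g in genes}
        recovered = 0
        false_counts = []
        for _ in range(100):
            planted = list(rng.choice(genes, 10, replace=False))
            signs = rng.choice([-1.0, 1.0], 10)
            log2 = {g: float(rng.normal(0, 0.15)) for g in genes}
            for g, s in zip(planted, signs):
                log2[g] = float(s * 0.8 + rng.normal(0, 0.15))
            calls = {c.gene: c.direction for c in call_focal_scna(log2, base)}
            expected = {g: ("amplified" if s > 0 else "deleted") for g, s in zip(planted, signs)}
            recovered += all(calls[g] == d for g, d in expected.items())
            false_counts.append(sum(1 for g, d in calls.items() if g not in expected and d != "neutral"))
        assert recovered / 100 >= 0.95
        assert np.mean(false_counts) <= 1.0
        assert res["n_reps"] == 100

    def test_null_false_call_rate_bounded(self):
        res = focal_null_false_call_rate(n_reps=500, q_threshold=0.05, seed=3)
        assert res["false_call_rate"] <= 0.05 + 0.02


class TestGeneLevelCn:
    genes = [GeneModel("A", "1", 100, 200), GeneModel("B", "1", 950, 1150),
             GeneModel("C", "2", 100, 200)]

    def test_midpoint_rule(self):
        segs = [seg(1, 1000, 3, 1), seg(1001, 2000, 1, 1)]
        cn = gene_level_cn(segs, self.genes)
        assert cn["A"] == 4
        assert cn["B"] == 2  # midpoint 1050 sits in the second, diploid segment

    def test_breakpoint_gene_decided_by_midpoint(self):
        segs = [seg(1, 1040, 3, 1), seg(1041, 2000, 1, 1)]
        cn = gene_level_cn(segs, self.genes)
        assert cn["B"] == 2  # midpoint 1050 falls in the second segment

    def test_uncovered_gene_missing(self):
        cn = gene_level_cn([seg(1, 1000, 1, 1)], self.genes)
        assert cn["C"] is None

    def test_co_amplified_genes_correlate_perfectly(self):
        """Three genes on one segment: their CN across a cohort co-varies, so
        pairwise Spearman is exactly 1 (the co-amplification signature)."""
        genes = [GeneModel(g, "1", s, s + 99) for g, s in [("X", 100), ("Y", 300), ("Z", 500)]]
        cn_rows = {g.gene: [] for g in genes}
        for k in range(6):  # cohort of 6 samples with growing amplification
            segs = [seg(1, 1000, 1 + k, 1, sample=f"S{k}")]
            cn = gene_level_cn(segs, genes)
            for g in genes:
                cn_rows[g.gene].append(cn[g.gene])
        assert spearman(cn_rows["X"], cn_rows["Y"]) == pytest.approx(1.0)
        assert spearman(cn_rows["Y"], cn_rows["Z"]) == pytest.approx(1.0)


class TestScnaIth:
    def test_all_clonal_gives_zero(self):
        segs = [seg(1, 100, 2, 1, ccf=1.0), seg(101, 200, 1, 0, ccf=1.0)]
        m = scna_ith_metrics(segs, ploidy=2.0)
        assert m.subclonal_scna_proportion == 0.0
        assert m.subclonal_genome_fraction == 0.0

    def test_half_subclonal_equal_lengths(self):
        segs = [
            seg(1, 100, 2, 1, ccf=1.0), seg(101, 200, 2, 1, ccf=0.5),
            seg(201, 300, 1, 0, ccf=1.0), seg(301, 400, 1, 0, ccf=0.4),
            seg(401, 500, 1, 1, ccf=1.0),
        ]
        m = scna_ith_metrics(segs, ploidy=2.0)
        assert m.subclonal_scna_proportion == pytest.approx(0.5)
        assert m.subclonal_genome_fraction == pytest.approx(200 / 500)

    def test_no_altered_segments_reports_missing_not_zero(self):
        m = scna_ith_metrics([seg(1, 100, 1, 1)], ploidy=2.0)
        assert m.subclonal_scna_proportion is None

    def test_fraction_denominator_is_total_segmented_length(self):
        segs = [seg(1, 100, 3, 1, ccf=0.5), seg(101, 1000, 1, 1)]
        m = scna_ith_metrics(segs, ploidy=2.0)
        assert m.subclonal_genome_fraction == pytest.approx(100 / 1000)

    def test_chrom_burden(self):
        segs = [seg(1, 100, 3, 1), seg(101, 200, 1, 1), seg(1, 100, 1, 1, chrom="2")]
        m = scna_ith_metrics(segs, ploidy=2.0)
        assert m.chrom_burden["1"] == pytest.approx(0.5)
        assert m.chrom_burden["2"] == 0.0
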