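"""Two-leaf pair trees: trunk/branch set algebra, clonality transitions,
and newick serialization."""

import pytest

from clonarch.models import ClonalityCall, FocalCall
from clonarch.phylogeny import (
    build_pair_tree,
    clonality_transitions,
    parse_pair_newick,
    serialize_tree,
    transition_counts,
)


def call(pos, label, sample="S", chrom="1"):
    c = ClonalityCall(sample_id=sample, key=(chrom, pos, "A", "T"), vaf=0.3,
                      multiplicity=1, ccf=1.0, ccf_ci_low=0.8, ccf_ci_high=1.2,
                      clonal_probability=0.9)
    c.label = label
    return c


def focal(gene, direction, sample="S"):
    return FocalCall(sample_id=sample, gene=gene, direction=direction,
                     statistic=5.0, p=1e-4, q=1e-3)


class TestBuildPairTree:
    def test_set_algebra(self):
        lep = [call(p, "clonal") for p in (1, 2, 3)] + [call(p, "clonal") for p in (10, 11)]
        mip = [call(p, "clonal") for p in (1, 2, 3)] + [call(p, "subclonal") for p in (20, 21)]
        tree = build_pair_tree("P1", lep, mip)
        assert len(tree.trunk_mutations) == 3
        assert len(tree.branch_lep) == 2 and len(tree.branch_mip) == 2
        assert tree.shared_subclonal == frozenset()

    def test_identical_all_clonal_components(self):
        lep = [call(p, "clonal") for p in range(1, 6)]
        mip = [call(p, "clonal") for p in range(1, 6)]
        tree = build_pair_tree("P1", lep, mip)
        assert len(tree.trunk_mutations) == 5
        assert not tree.branch_lep and not tree.branch_mip

    def test_shared_but_not_biclonal_goes_to_shared_subclonal(self):
        lep = [call(1, "clonal"), call(2, "clonal")]
        mip = [call(1, "clonal"), call(2, "subclonal")]
        tree = build_pair_tree("P1", lep, mip)
        assert tree.trunk_mutations == frozenset({("1", 1, "A", "T")})
        assert tree.shared_subclonal == frozenset({("1", 2, "A", "T")})
        assert not tree.branch_lep and not tree.branch_mip

    def test_partition_invariant(self):
        lep = [call(p, "clonal") for p in (1, 2, 5, 6)]
        mip = [call(p, "subclonal") for p in (1, 2, 7)]
        tree = build_pair_tree("P1", lep, mip)
        union = {c.key for c in lep} | {c.key for c in mip}
        assert (len(tree.shared_mutations) + len(tree.branch_lep)
                + len(tree.branch_mip)) == len(union)

    def test_component_swap_only_swaps_labels(self):
        lep = [call(p, "clonal") for p in (1, 2, 5)]
        mip = [call(p, "clonal") for p in (1, 2, 7)]
        t1 = build_pair_tree("P1", lep, mip)
        t2 = build_pair_tree("P1", mip, lep)
        assert t1.trunk_mutations == t2.trunk_mutations
        assert t1.branch_lep == t2.branch_mip and t1.branch_mip == t2.branch_lep

    def test_trunk_scna_requires_same_gene_and_direction(self):
        lep = [call(1, "clonal")]
        mip = [call(1, "clonal")]
        tree = build_pair_tree(
            "P1", lep, mip,
            focal_lep=[focal("A", "amplified"), focal("B", "deleted")],
            focal_mip=[focal("A", "amplified"), focal("B", "amplified")],
        )
        assert tree.trunk_scna == frozenset({("A", "amplified")})
        assert ("B", "deleted") in tree.branch_scna_lep

    def test_trunk_drivers_from_cancer_gene_list(self):
        lep = [call(1, "clonal"), call(2, "clonal")]
        mip = [call(1, "clonal"), call(2, "clonal")]
        gene_of = {("1", 1, "A", "T"): "EGFR", ("1", 2, "A", "T"): "G0001"}
        tree = build_pair_tree("P1", lep, mip, gene_of=gene_of, cancer_genes=["EGFR"])
        assert tree.trunk_drivers == frozenset({"EGFR"})

    def test_missing_component_rejected(self):
        with pytest.raises(ValueError, match="both components"):
            build_pair_tree("P1", [call(1, "clonal")], [])

    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_pair_tree("P1", [call(1, "clonal"), call(1, "clonal")], [call(1, "clonal")])


class TestTransitions:
    def test_labels(self):
        lep = [call(1, "clonal"), call(2, "clonal"), call(3, "subclonal"), call(4, "subclonal")]
        mip = [call(1, "subclonal"), call(2, "clonal"), call(3, "clonal"), call(4, "subclonal")]
        recs = {t.key[1]: t.label for t in clonality_transitions(lep, mip)}
        assert recs[1] == "clonal→subclonal (LEP→MIP)"
        assert recs[2] == "stable-clonal"
        assert recs[3] == "subclonal→clonal (LEP→MIP)"
        assert recs[4] == "stable-subclonal"

    def test_only_shared_mutations_labeled(self):
        lep = [call(1, "clonal"), call(9, "clonal")]
        mip = [call(1, "clonal")]
        assert len(clonality_transitions(lep, mip)) == 1

    def test_counts_cover_all_labels(self):
        counts = transition_counts(clonality_transitions([call(1, "clonal")], [call(1, "clonal")]))
        assert counts["stable-clonal"] == 1
        assert sum(counts.values()) == 1


class TestSerialize:
    def test_newick_format(self):
        lep = [call(p, "clonal") for p in (1, 2, 3, 10, 11)]
        mip = [call(p, "clonal") for p in (1, 2, 3, 20, 21)]
        newick, summary = serialize_tree(build_pair_tree("P1", lep, mip))
        assert newick == "(LEP:2,MIP:2):3;"
        assert summary["n_trunk"] == 3

    def test_empty_branches(self):
        lep = [call(p, "clonal") for p in (1, 2)]
        newick, _ = serialize_tree(build_pair_tree("P1", lep, lep))
        assert newick == "(LEP:0,MIP:0):2;"

    def test_round_trip_recovers_counts(self):
        lep = [call(p, "clonal") for p in (1, 2, 3, 4, 10)]
        mip = [call(p, "clonal") for p in (1, 2, 3, 4, 20, 21)]
        newick, _ = serialize_tree(build_pair_tree("P1", lep, mip))
        assert parse_pair_newick(newick) == (4, 1, 2)
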