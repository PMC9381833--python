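"""Two-leaf trunk/branch phylogenies for matched LEP/MIP component pairs.

The trunk holds mutations shared by both components AND clonal in both;
mutations shared but not bi-clonal form a separate annotated class rather
than being forced onto the trunk or a branch. Private mutations form the
two branches. Focal SCNA calls identical in both components (same gene,
same direction) decorate the trunk. Mutation identity is the genomic key
(chrom, pos, ref, alt), never the gene symbol.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Optional, Sequence

from .models import ClonalityCall, FocalCall, MutationKey, PairTree, TransitionRecord

TRANSITION_LABELS = (
    "stable-clonal",
    "stable-subclonal",
    "clonal→subclonal (LEP→MIP)",
    "subclonal→clonal (LEP→MIP)",
)


def _index_calls(calls: Sequence[ClonalityCall], component: str) -> dict[MutationKey, ClonalityCall]:
    idx: dict[MutationKey, ClonalityCall] = {}
    for c in calls:
        if c.label is None:
            raise ValueError(f"{component}: call {c.key} is unlabeled")
        if c.key in idx:
            raise ValueError(f"{component}: duplicate mutation key {c.key}")
        idx[c.key] = c
    return idx


def build_pair_tree(
    patient_id: str,
    calls_lep: Sequence[ClonalityCall],
    calls_mip: Sequence[ClonalityCall],
    focal_lep: Sequence[FocalCall] = (),
    focal_mip: Sequence[FocalCall] = (),
    gene_of: Optional[Mapping[MutationKey, str]] = None,
    cancer_genes: Iterable[str] = (),
) -> PairTree:
    """Assemble the pair phylogeny from per-component clonality calls.

    ``gene_of`` maps mutation keys to gene symbols (needed only for
    trunk-driver annotation against ``cancer_genes``).
    """
    if not calls_lep or not calls_mip:
        raise ValueError(f"{patient_id}: both components must be present")
    lep = _index_calls(calls_lep, "LEP")
    mip = _index_calls(calls_mip, "MIP")
    shared = set(lep) & set(mip)
    trunk = frozenset(
        k for k in shared if lep[k].label == "clonal" and mip[k].label == "clonal"
    )
    shared_subclonal = frozenset(shared - trunk)
    branch_lep = frozenset(set(lep) - shared)
    branch_mip = frozenset(set(mip) - shared)

    def _dir_sets(calls: Sequence[FocalCall]) -> frozenset[tuple[str, str]]:
        return frozenset((c.gene, c.direction) for c in calls if c.direction != "neutral")

    scna_lep = _dir_sets(focal_lep)
    scna_mip = _dir_sets(focal_mip)
    trunk_scna = scna_lep & scna_mip

    drivers: frozenset[str] = frozenset()
    if gene_of is not None:
        cancer = set(cancer_genes)
        drivers = frozenset(
            gene_of[k] for k in trunk if k in gene_of and gene_of[k] in cancer
        )
    return PairTree(
        patient_id=patient_id,
        trunk_mutations=trunk,
        branch_lep=branch_lep,
        branch_mip=branch_mip,
        shared_subclonal=shared_subclonal,
        trunk_scna=trunk_scna,
        branch_scna_lep=frozenset(scna_lep - trunk_scna),
        branch_scna_mip=frozenset(scna_mip - trunk_scna),
        trunk_drivers=drivers,
    )


def clonality_transitions(
    calls_lep: Sequence[ClonalityCall], calls_mip: Sequence[ClonalityCall]
) -> list[TransitionRecord]:
    """Label every shared mutation by its LEP→MIP clonality pattern."""
    lep = _index_calls(calls_lep, "LEP")
    mip = _index_calls(calls_mip, "MIP")
    records = []
    for key in sorted(set(lep) & set(mip)):
        a, b = lep[key].label, mip[key].label
        if a == b:
            label = f"stable-{a}"
        elif a == "clonal":
            label = "clonal→subclonal (LEP→MIP)"
        else:
            label = "subclonal→clonal (LEP→MIP)"
        records.append(TransitionRecord(key=key, label=label))
    return records


def transition_counts(transitions: Sequence[TransitionRecord]) -> dict[str, int]:
    counts = Counter(t.label for t in transitions)
    return {label: counts.get(label, 0) for label in TRANSITION_LABELS}


def serialize_tree(tree: PairTree) -> tuple[str, dict]:
    """Newick text plus a flat summary row for one pair tree.

    Branch lengths are private mutation counts; the root-to-split length
    is the trunk mutation count.
    """
    newick = (
        f"(LEP:{len(tree.branch_lep)},MIP:{len(tree.branch_mip)}):{len(tree.trunk_mutations)};"
    )
    summary = {
        "patient_id": tree.patient_id,
        "n_trunk": len(tree.trunk_mutations),
        "n_shared": len(tree.shared_mutations),
        "n_shared_subclonal": len(tree.shared_subclonal),
        "n_branch_LEP": len(tree.branch_lep),
        "n_branch_MIP": len(tree.branch_mip),
        "n_trunk_scna": len(tree.trunk_scna),
        "n_branch_scna_LEP": len(tree.branch_scna_lep),
        "n_branch_scna_MIP": len(tree.branch_scna_mip),
        "trunk_drivers": ",".join(sorted(tree.trunk_drivers)),
    }
    return newick, summary


def parse_pair_newick(text: str) -> tuple[int, int, int]:
    """Recover (trunk, branch_LEP, branch_MIP) counts from serialized newick."""
    body = text.strip().rstrip(";")
    inner, _, trunk = body.rpartition(":")
    inner = inner.strip("()")
    parts = dict(p.split(":") for p in inner.split(","))
    return int(trunk), int(parts["LEP"]), int(parts["MIP"])
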