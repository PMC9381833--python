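"""Build the two-leaf trunk/branch tree for every patient pair, annotate
clonality transitions, and check the planted driver sits on every trunk.

Reads results/cohort/ and results/clonality/; writes results/trees/.
"""

from pathlib import Path

import pandas as pd

from clonarch import io_formats
from clonarch.clonality import call_sample_clonality
from clonarch.phylogeny import (
    build_pair_tree,
    clonality_transitions,
    serialize_tree,
    transition_counts,
)

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    out = ROOT / "trees"
    out.mkdir(parents=True, exist_ok=True)
    samples = io_formats.read_metadata(ROOT / "cohort" / "metadata.tsv")
    by_patient: dict[str, dict] = {}
    for s in samples:
        by_patient.setdefault(s.patient_id, {})[s.component.value] = s
    rows = []
    for patient, comps in sorted(by_patient.items()):
        calls, gene_of = {}, {}
        for comp, sample in comps.items():
            recs = io_formats.read_mutation_table(ROOT / "filtered" / f"{sample.sample_id}.muts.tsv")
            segs = io_formats.read_seg(ROOT / "cohort" / f"{sample.sample_id}.seg.tsv")
            calls[comp] = call_sample_clonality(recs, sample, segs)
            gene_of.update({r.key: r.gene for r in recs})
        tree = build_pair_tree(patient, calls["LEP"], calls["MIP"],
                               gene_of=gene_of, cancer_genes=["EGFR"])
        newick, summary = serialize_tree(tree)
        (out / f"{patient}.nwk").write_text(newick + "\n")
        counts = transition_counts(clonality_transitions(calls["LEP"], calls["MIP"]))
        summary.update({f"transitions[{k}]": v for k, v in counts.items()})
        rows.append(summary)
        print(f"{patient}: {newick}  trunk drivers: {sorted(tree.trunk_drivers) or '-'}  "
              f"transitions: {counts}")
    pd.DataFrame(rows).to_csv(out / "pair_trees.tsv", sep="\t", index=False)
    print(f"wrote newick trees and summary to {out}")
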