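"""Estimate CCFs, label clonality, and compute mutation-level ITH metrics
(MATH, clonal TMB, subclonal mutation proportion) per sample.

Reads results/cohort/ and results/filtered/; writes results/clonality/.
"""

from pathlib import Path

import pandas as pd

from clonarch import io_formats
from clonarch.clonality import call_sample_clonality, mutation_ith_metrics
from clonarch.synthetic import key_str

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    out = ROOT / "clonality"
    out.mkdir(parents=True, exist_ok=True)
    samples = {s.sample_id: s for s in io_formats.read_metadata(ROOT / "cohort" / "metadata.tsv")}
    call_rows, metric_rows = [], []
    for sid, sample in sorted(samples.items()):
        records = io_formats.read_mutation_table(ROOT / "filtered" / f"{sid}.muts.tsv")
        segments = io_formats.read_seg(ROOT / "cohort" / f"{sid}.seg.tsv")
        calls = call_sample_clonality(records, sample, segments)
        for c in calls:
            call_rows.append({"sample_id": sid, "key": key_str(c.key), "vaf": c.vaf,
                              "ccf": c.ccf, "ccf_ci_high": c.ccf_ci_high,
                              "clonal_probability": c.clonal_probability, "label": c.label})
        m = mutation_ith_metrics(calls, sample)
        metric_rows.append({"sample_id": sid, "math": m.math, "ctmb": m.ctmb,
                            "subclonal_mut_proportion": m.subclonal_mut_proportion})
        print(f"{sid}: {sum(c.label == 'clonal' for c in calls)} clonal / {len(calls)} calls, "
              f"MATH {m.math:.1f}, cTMB {m.ctmb:.3f}/Mb")
    pd.DataFrame(call_rows).to_csv(out / "calls.tsv", sep="\t", index=False)
    pd.DataFrame(metric_rows).to_csv(out / "mutation_ith.tsv", sep="\t", index=False)
    print(f"wrote {out}/calls.tsv and mutation_ith.tsv")
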