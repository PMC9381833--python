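"""Apply the four-rule somatic quality filter to every sample of the
simulated cohort and report the per-rule survivor chain.

Reads results/cohort/ (run 01 first); writes results/filtered/.
"""

import json
from pathlib import Path

from clonarch import io_formats
from clonarch.variant_filter import apply_quality_filters

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    out = ROOT / "filtered"
    out.mkdir(parents=True, exist_ok=True)
    reports = {}
    for path in sorted((ROOT / "cohort").glob("*.muts.tsv")):
        records = io_formats.read_mutation_table(path)
        kept, report = apply_quality_filters(records)
        sample = path.name.removesuffix(".muts.tsv")
        io_formats.write_mutation_table(kept, out / path.name)
        reports[sample] = report.counts_after_each_rule
        chain = " -> ".join(str(v) for v in report.counts_after_each_rule.values())
        print(f"{sample}: {report.counts_in} -> {chain}")
    with open(out / "filter_report.json", "w") as fh:
        json.dump(reports, fh, indent=1, sort_keys=True)
    print(f"wrote filtered tables and report to {out}")
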