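"""Simulate the study cohort: five patients, each a matched LEP/MIP pair.

Writes per-sample mutation and segment tables, metadata, the synthetic
gene model and the truth JSON under results/cohort/.
"""

from pathlib import Path

from clonarch.synthetic import SimulationConfig, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"

if __name__ == "__main__":
    cfg = SimulationConfig(seed=1)
    pairs = simulate_cohort(cfg, OUT, overwrite=True)
    n_trunc = [len(p.truth.truncal) for p in pairs]
    print(f"wrote {2 * len(pairs)} samples for {len(pairs)} pairs to {OUT}")
    print(f"truncal mutations per pair: {n_trunc}")
    print(f"purities: "
          + ", ".join(f"{s}={v:.2f}" for p in pairs for s, v in p.truth.purity.items()))
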