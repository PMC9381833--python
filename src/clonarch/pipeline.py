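"""End-to-end orchestration of the paired-component analysis.

Stages: simulate (or load) -> variant filter -> clonality/ITH -> SCNA ->
pair phylogenies -> cohort comparisons -> immune-cycle scoring. Every
threshold the analysis depends on is surfaced in :class:`PipelineConfig`;
a run writes versioned TSVs, newick trees and a JSON manifest, and is
byte-identical under a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import clonality as clonality_mod
from . import datasets, immunity, io_formats, phylogeny, scna, stats, synthetic, variant_filter
from .models import Component
from .synthetic import PairData, SimulationConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "clonality", "scna", "phylo", "compare", "immune")


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    input_dir: Optional[str] = None  # load a simulated cohort instead of simulating

    # variant filter
    pop_freq_max: float = 0.01
    min_alt_reads_exclusive: int = 3
    vaf_min: float = 0.01
    functional_only: bool = True
    cancer_genes: tuple[str, ...] = ("EGFR",)

    # clonality
    ci_alpha: float = 0.05
    ccf_clonal_threshold: float = 0.9
    clonal_prob_cutoff: float = 0.5

    # scna
    focal_q_threshold: float = 0.05
    focal_effect_min: float = 0.2
    focal_baseline_sd: float = 0.1
    subclonal_seg_ccf_cutoff: float = 0.9

    # immune-cycle stage (expression is simulated with a planted shift)
    immune_n_genes: int = 200
    immune_n_per_group: int = 20
    immune_shift_step: str = datasets.IMMUNE_CYCLE_STEP_NAMES[-1]
    immune_shift_group: str = "MIP"
    immune_shift: float = 2.0
    ssgsea_alpha: float = 0.25

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**{
            **raw.pop("sim", {}),
        })
        for key in ("purity_range", "subclonal_ccf_range"):
            setattr(sim, key, tuple(getattr(sim, key)))
        cfg = cls(sim=sim, **raw)
        cfg.cancer_genes = tuple(cfg.cancer_genes)
        return cfg


def _load_cohort(input_dir: Path) -> list[PairData]:
    samples = io_formats.read_metadata(input_dir / "metadata.tsv")
    with open(input_dir / "truth.json") as fh:
        truth_raw = json.load(fh)
    pairs: list[PairData] = []
    by_patient: dict[str, list] = {}
    for s in samples:
        by_patient.setdefault(s.patient_id, []).append(s)
    for patient, pair_samples in sorted(by_patient.items()):
        data = PairData(samples={}, mutations={}, segments={}, truth=None)
        for s in pair_samples:
            comp = s.component.value
            data.samples[comp] = s
            data.mutations[comp] = io_formats.read_mutation_table(
                input_dir / f"{s.sample_id}.muts.tsv"
            )
            data.segments[comp] = io_formats.read_seg(input_dir / f"{s.sample_id}.seg.tsv")
        t = truth_raw.get(patient, {})
        data.truth = t  # raw dict is enough downstream
        pairs.append(data)
    return pairs


def run_pipeline(config: PipelineConfig, out_dir: str | Path, overwrite: bool = False) -> dict:
    """Run every stage; returns the manifest (also written as JSON)."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out} is not empty (use overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)
    if config.input_dir is not None and not Path(config.input_dir).exists():
        raise FileNotFoundError(f"input_dir does not exist: {config.input_dir}")

    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            k: v for k, v in asdict(config).items() if k not in ("sim", "input_dir")
        },
        "sim": asdict(config.sim),
        "stages_completed": [],
        "outputs": [],
    }

    def _done(stage: str, *files: Path) -> None:
        manifest["stages_completed"].append(stage)
        manifest["outputs"].extend(str(f.relative_to(out)) for f in files)
        logger.info("stage %s complete", stage)

    def _stage_error(stage: str, exc: Exception) -> RuntimeError:
        manifest["failed_stage"] = stage
        return RuntimeError(f"stage {stage!r} failed: {exc}")

    # ---- simulate / load
    try:
        if config.input_dir is not None:
            pairs = _load_cohort(Path(config.input_dir))
        else:
            sim_dir = out / "cohort"
            pairs = synthetic.simulate_cohort(config.sim, sim_dir, overwrite=overwrite)
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise _stage_error("simulate", exc)
    _done("simulate")

    gene_model = synthetic.build_gene_model(config.sim.n_genes)

    # ---- filter
    try:
        filtered: dict[str, dict[str, list]] = {}
        reports: dict[str, dict] = {}
        for pair in pairs:
            patient = pair.samples["LEP"].patient_id
            filtered[patient] = {}
            for comp, recs in pair.mutations.items():
                kept, report = variant_filter.apply_quality_filters(
                    recs,
                    pop_freq_max=config.pop_freq_max,
                    min_alt_reads_exclusive=config.min_alt_reads_exclusive,
                    vaf_min=config.vaf_min,
                    functional_only=config.functional_only,
                )
                filtered[patient][comp] = kept
                reports[f"{patient}_{comp}"] = {
                    "counts_in": report.counts_in,
                    "counts_after_each_rule": report.counts_after_each_rule,
                    "counts_out": report.counts_out,
                }
        report_path = out / "filter_report.json"
        with open(report_path, "w") as fh:
            json.dump(reports, fh, indent=1, sort_keys=True)
    except Exception as exc:
        raise _stage_error("filter", exc)
    _done("filter", report_path)

    # ---- clonality
    try:
        all_calls: dict[str, dict[str, list]] = {}
        call_rows, ith_rows = [], []
        for pair in pairs:
            patient = pair.samples["LEP"].patient_id
            all_calls[patient] = {}
            for comp, recs in filtered[patient].items():
                sample = pair.samples[comp]
                calls = clonality_mod.call_sample_clonality(
                    recs, sample, pair.segments[comp],
                    alpha=config.ci_alpha,
                    ccf_clonal_threshold=config.ccf_clonal_threshold,
                    prob_cutoff=config.clonal_prob_cutoff,
                )
                all_calls[patient][comp] = calls
                for c in calls:
                    call_rows.append(
                        {
                            "sample_id": c.sample_id,
                            "key": synthetic.key_str(c.key),
                            "vaf": round(c.vaf, 6),
                            "multiplicity": c.multiplicity,
                            "ccf": round(c.ccf, 6),
                            "ccf_ci_low": round(c.ccf_ci_low, 6),
                            "ccf_ci_high": round(c.ccf_ci_high, 6),
                            "clonal_probability": round(c.clonal_probability, 6),
                            "label": c.label,
                        }
                    )
                if calls:
                    m = clonality_mod.mutation_ith_metrics(calls, sample)
                    ith_rows.append(
                        {
                            "sample_id": m.sample_id,
                            "math": round(m.math, 4),
                            "ctmb": round(m.ctmb, 6),
                            "subclonal_mut_proportion": round(m.subclonal_mut_proportion, 6),
                        }
                    )
        calls_path = out / "clonality_calls.tsv"
        pd.DataFrame(call_rows).to_csv(calls_path, sep="\t", index=False)
        mut_ith_path = out / "mutation_ith.tsv"
        pd.DataFrame(ith_rows).to_csv(mut_ith_path, sep="\t", index=False)
    except Exception as exc:
        raise _stage_error("clonality", exc)
    _done("clonality", calls_path, mut_ith_path)

    # ---- scna
    try:
        baseline = {g.gene: (0.0, config.focal_baseline_sd) for g in gene_model}
        focal_by_sample: dict[str, list] = {}
        scna_rows = []
        for pair in pairs:
            for comp, segs in pair.segments.items():
                sample = pair.samples[comp]
                non_cnloh, _ = scna.flag_cnloh(segs)
                gene_log2 = {}
                for g in gene_model:
                    seg = next((s for s in segs if s.covers(g.chrom, g.midpoint)), None)
                    if seg is not None:
                        gene_log2[g.gene] = seg.log2_ratio
                focal_by_sample[sample.sample_id] = scna.call_focal_scna(
                    gene_log2, baseline, sample_id=sample.sample_id,
                    q_threshold=config.focal_q_threshold, effect_min=config.focal_effect_min,
                )
                m = scna.scna_ith_metrics(
                    non_cnloh, sample.ploidy, sample_id=sample.sample_id,
                    subclonal_ccf_cutoff=config.subclonal_seg_ccf_cutoff,
                    gene_model=gene_model,
                )
                scna_rows.append(
                    {
                        "sample_id": m.sample_id,
                        "subclonal_scna_proportion": (
                            "" if m.subclonal_scna_proportion is None
                            else round(m.subclonal_scna_proportion, 6)
                        ),
                        "subclonal_genome_fraction": round(m.subclonal_genome_fraction, 6),
                    }
                )
        scna_path = out / "scna_ith.tsv"
        pd.DataFrame(scna_rows).to_csv(scna_path, sep="\t", index=False)
        focal_path = out / "focal_calls.tsv"
        pd.DataFrame(
            [
                {
                    "sample_id": c.sample_id, "gene": c.gene, "direction": c.direction,
                    "statistic": round(c.statistic, 4), "p": c.p, "q": c.q,
                }
                for calls in focal_by_sample.values() for c in calls if c.direction != "neutral"
            ]
        ).to_csv(focal_path, sep="\t", index=False)
    except Exception as exc:
        raise _stage_error("scna", exc)
    _done("scna", scna_path, focal_path)

    # ---- phylo
    try:
        tree_dir = out / "trees"
        tree_dir.mkdir(exist_ok=True)
        summary_rows, tree_files = [], []
        gene_of_all: dict = {}
        for pair in pairs:
            for recs in pair.mutations.values():
                gene_of_all.update({r.key: r.gene for r in recs})
        for pair in pairs:
            patient = pair.samples["LEP"].patient_id
            tree = phylogeny.build_pair_tree(
                patient,
                all_calls[patient]["LEP"],
                all_calls[patient]["MIP"],
                focal_by_sample.get(pair.samples["LEP"].sample_id, ()),
                focal_by_sample.get(pair.samples["MIP"].sample_id, ()),
                gene_of=gene_of_all,
                cancer_genes=config.cancer_genes,
            )
            newick, summary = phylogeny.serialize_tree(tree)
            nwk_path = tree_dir / f"{patient}.nwk"
            nwk_path.write_text(newick + "\n")
            tree_files.append(nwk_path)
            transitions = phylogeny.clonality_transitions(
                all_calls[patient]["LEP"], all_calls[patient]["MIP"]
            )
            summary.update(
                {f"transitions[{k}]": v for k, v in phylogeny.transition_counts(transitions).items()}
            )
            summary_rows.append(summary)
        trees_path = out / "pair_trees.tsv"
        pd.DataFrame(summary_rows).to_csv(trees_path, sep="\t", index=False)
    except Exception as exc:
        raise _stage_error("phylo", exc)
    _done("phylo", trees_path, *tree_files)

    # ---- compare
    try:
        group_of = {
            s.sample_id: s.component.value for pair in pairs for s in pair.samples.values()
        }
        all_filtered = [r for p in filtered.values() for recs in p.values() for r in recs]
        all_focal = [c for calls in focal_by_sample.values() for c in calls]
        freq_rows = stats.alteration_frequency_table(all_filtered, all_focal, group_of)
        freq_path = out / "alteration_frequency.tsv"
        pd.DataFrame([vars(r) for r in freq_rows]).to_csv(freq_path, sep="\t", index=False)

        scna_df = pd.DataFrame(scna_rows).replace("", float("nan"))
        by_group = {
            g: scna_df[scna_df.sample_id.map(group_of) == g]["subclonal_scna_proportion"]
            .dropna().astype(float).to_numpy()
            for g in ("LEP", "MIP")
        }
        test_rows = []
        if len(by_group["LEP"]) and len(by_group["MIP"]):
            res = stats.mann_whitney(by_group["MIP"], by_group["LEP"], sided="two-sided")
            test_rows.append(
                {"name": "subclonal_scna_proportion_MIP_vs_LEP",
                 "statistic": res.statistic, "p": res.p, "sidedness": res.sidedness}
            )
        tests_path = out / "group_tests.tsv"
        pd.DataFrame(test_rows).to_csv(tests_path, sep="\t", index=False)
    except Exception as exc:
        raise _stage_error("compare", exc)
    _done("compare", freq_path, tests_path)

    # ---- immune
    try:
        n = config.immune_n_per_group
        groups_list = ["LEP"] * n + ["MIP"] * n
        gene_sets = datasets.example_immune_cycle_sets(config.immune_n_genes)
        expr = synthetic.simulate_expression(
            config.immune_n_genes,
            groups_list,
            gene_sets,
            shifts={config.immune_shift_step: {config.immune_shift_group: config.immune_shift}},
            seed=config.seed + 10_007,
        )
        activity = immunity.ssgsea_scores(expr, gene_sets, alpha=config.ssgsea_alpha)
        group_map = dict(zip(expr.columns, groups_list))
        results = immunity.compare_step_activity(activity, group_map)
        activity_path = out / "immune_activity.tsv"
        activity.round(6).to_csv(activity_path, sep="\t", index_label="step")
        immune_tests_path = out / "immune_tests.tsv"
        pd.DataFrame(
            [
                {"step": r.name, "U": r.statistic, "p": r.p, "q": r.q,
                 "higher_in": r.extra.get("higher_in", "")}
                for r in results
            ]
        ).to_csv(immune_tests_path, sep="\t", index=False)
    except Exception as exc:
        raise _stage_error("immune", exc)
    _done("immune", activity_path, immune_tests_path)

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
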