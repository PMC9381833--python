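"""Synthetic matched LEP/MIP component pairs with known clonal truth.

The generator emulates the study design the pipeline targets: two
histological components micro-dissected from one tumor share a truncal
clone (true CCF = 1 in both), on top of which each component carries
private clonal and private subclonal mutations. Read counts are binomial
draws at Poisson depth; the expected variant allele frequency at a site is

    E[VAF] = purity * m * CCF / (purity * CN_t + 2 * (1 - purity))

with m the mutation multiplicity and CN_t the local total copy number.
Copy segments come in clonal and subclonal flavours plus copy-neutral LOH
(major 2 / minor 0), and an expression simulator plants gene-set shifts
between groups for immune-cycle scoring tests.

Everything is deterministic given (seed, pair_index).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io_formats
from .models import (
    Component,
    ComponentSample,
    CopySegment,
    GeneModel,
    GeneSet,
    MutationKey,
    MutationRecord,
)

N_CHROMS = 22
GENE_LENGTH = 10_000
GENE_SPACING = 50_000
MIN_DEPTH = 30  # depth floor; avoids degenerate CIs at FFPE-like coverage dips
DRIVER_GENE = "EGFR"
DRIVER_CHROM = "7"


@dataclass
class SimulationConfig:
    """Study conditions for a simulated paired-component cohort.

    Defaults mirror a five-patient paired lepidic/micropapillary design
    sequenced deep on a custom exon capture: a shared truncal clone, a
    handful of private clonal mutations and a private subclone per
    component, and a stronger subclonal-SCNA load in MIP than in LEP.
    """

    n_pairs: int = 5
    depth_mean: float = 500.0
    purity_range: tuple[float, float] = (0.2, 0.9)
    n_truncal: int = 30
    n_private_clonal: int = 10
    n_private_subclonal: int = 20
    subclonal_ccf_range: tuple[float, float] = (0.1, 0.4)
    n_segments: int = 40
    frac_altered_seg: float = 0.5
    frac_subclonal_seg_lep: float = 0.2
    frac_subclonal_seg_mip: float = 0.6
    frac_cnloh: float = 0.1
    n_genes: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_altered_seg", "frac_subclonal_seg_lep", "frac_subclonal_seg_mip", "frac_cnloh"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0,1]: {v}")
        for name in ("purity_range", "subclonal_ccf_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} not ordered: ({lo}, {hi})")
        if not 0.0 < self.purity_range[0] and self.purity_range[1] <= 1.0:
            raise ValueError("purity_range must lie in (0,1]")
        if not (0.0 < self.subclonal_ccf_range[0] and self.subclonal_ccf_range[1] < 1.0):
            raise ValueError("subclonal_ccf_range must lie in (0,1)")


@dataclass
class TruthSet:
    """Ground truth for one simulated pair (the oracle for recovery tests)."""

    patient_id: str
    truncal: list[MutationKey]
    private_clonal: dict[str, list[MutationKey]] = field(default_factory=dict)  # component -> keys
    private_subclonal: dict[str, list[MutationKey]] = field(default_factory=dict)
    true_ccf: dict[str, dict[str, float]] = field(default_factory=dict)  # component -> key-str -> ccf
    purity: dict[str, float] = field(default_factory=dict)  # sample_id -> purity
    segment_clonal: dict[str, list[bool]] = field(default_factory=dict)  # sample_id -> flags
    segment_cnloh: dict[str, list[bool]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


@dataclass
class PairData:
    samples: dict[str, ComponentSample]  # component value -> sample
    mutations: dict[str, list[MutationRecord]]  # component value -> records
    segments: dict[str, list[CopySegment]]
    truth: TruthSet


def key_str(key: MutationKey) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}>{key[3]}"


def build_gene_model(n_genes: int = 400) -> list[GeneModel]:
    """Deterministic synthetic exome: genes G0001.. laid out round-robin on
    22 chromosomes, plus a reserved EGFR-like driver locus on chromosome 7."""
    genes: list[GeneModel] = []
    per_chrom_count: dict[int, int] = {c: 0 for c in range(1, N_CHROMS + 1)}
    names = [f"G{i:04d}" for i in range(1, n_genes)]
    # slot the driver where a chr7 gene would fall
    layout: list[str] = []
    driver_placed = False
    idx = 0
    for i in range(n_genes):
        chrom = (i % N_CHROMS) + 1
        if chrom == 7 and not driver_placed:
            layout.append(DRIVER_GENE)
            driver_placed = True
        else:
            layout.append(names[idx])
            idx += 1
    if not driver_placed:  # fewer than 7 genes requested
        layout[-1] = DRIVER_GENE
    for i, name in enumerate(layout):
        chrom = (i % N_CHROMS) + 1
        k = per_chrom_count[chrom]
        per_chrom_count[chrom] += 1
        start = 1 + k * (GENE_LENGTH + GENE_SPACING)
        arm = "p" if k < max(1, (n_genes // N_CHROMS + 1) // 2) else "q"
        genes.append(
            GeneModel(gene=name, chrom=str(chrom), start=start, end=start + GENE_LENGTH - 1, arm=arm)
        )
    return genes


def _chrom_extents(gene_model: Sequence[GeneModel]) -> dict[str, int]:
    extents: dict[str, int] = {}
    for g in gene_model:
        extents[g.chrom] = max(extents.get(g.chrom, 0), g.end + GENE_SPACING)
    return extents


def _partition_segments(gene_model: Sequence[GeneModel], n_segments: int) -> list[tuple[str, int, int]]:
    """Split each chromosome's extent into contiguous blocks, n_segments total."""
    extents = _chrom_extents(gene_model)
    chroms = sorted(extents, key=lambda c: int(c) if c.isdigit() else 99)
    per = max(1, n_segments // len(chroms))
    bounds: list[tuple[str, int, int]] = []
    for chrom in chroms:
        length = extents[chrom]
        edges = np.linspace(1, length + 1, per + 1).astype(int)
        for a, b in zip(edges[:-1], edges[1:]):
            bounds.append((chrom, int(a), int(b - 1)))
    return bounds


def _assign_segment_states(
    rng: np.random.Generator,
    bounds: Sequence[tuple[str, int, int]],
    sample_id: str,
    purity: float,
    frac_altered: float,
    frac_subclonal: float,
    frac_cnloh: float,
    protect: Optional[tuple[str, int]] = None,
) -> tuple[list[CopySegment], list[bool], list[bool]]:
    n = len(bounds)
    roll = rng.random(n)
    segs: list[CopySegment] = []
    clonal_flags: list[bool] = []
    cnloh_flags: list[bool] = []
    for i, (chrom, start, end) in enumerate(bounds):
        protected = protect is not None and chrom == protect[0] and start <= protect[1] <= end
        if not protected and roll[i] < frac_cnloh:
            major, minor = 2, 0
            clonal = True
            cnloh = True
            ccf = 1.0
        elif not protected and roll[i] < frac_cnloh + frac_altered:
            if rng.random() < 0.5:
                major, minor = int(rng.integers(2, 4)), 1  # gain
            else:
                major, minor = 1, 0  # loss
            clonal = bool(rng.random() >= frac_subclonal)
            cnloh = False
            ccf = 1.0 if clonal else float(rng.uniform(0.3, 0.7))
        else:
            major, minor = 1, 1
            clonal = True
            cnloh = False
            ccf = 1.0
        cnt = major + minor
        # mixture copy ratio of tumor at this segment CCF vs diploid normal
        eff = purity * (ccf * cnt + (1 - ccf) * 2) + 2 * (1 - purity)
        segs.append(
            CopySegment(
                sample_id=sample_id,
                chrom=chrom,
                start=start,
                end=end,
                log2_ratio=float(np.log2(eff / 2.0)),
                major_cn=major,
                minor_cn=minor,
                segment_ccf=ccf,
            )
        )
        clonal_flags.append(clonal)
        cnloh_flags.append(cnloh)
    return segs, clonal_flags, cnloh_flags


def _covering_segment(segments: Sequence[CopySegment], chrom: str, pos: int) -> CopySegment:
    for s in segments:
        if s.covers(chrom, pos):
            return s
    raise LookupError(f"no segment covers {chrom}:{pos}")


_BASES = np.array(["A", "C", "G", "T"])


def simulate_pair(config: SimulationConfig, pair_index: int) -> PairData:
    """Simulate one matched LEP/MIP pair; deterministic in (seed, pair_index)."""
    rng = np.random.default_rng((config.seed + pair_index) % 2**31)
    patient = f"P{pair_index + 1:02d}"
    gene_model = build_gene_model(config.n_genes)
    gene_by_name = {g.gene: g for g in gene_model}
    bounds = _partition_segments(gene_model, config.n_segments)

    truth = TruthSet(patient_id=patient, truncal=[])
    if config.n_truncal == 0:
        truth.warnings.append(
            f"{patient}: n_truncal=0 — components share no ancestry in this simulation"
        )

    samples: dict[str, ComponentSample] = {}
    segments: dict[str, list[CopySegment]] = {}
    seg_clonal: dict[str, list[bool]] = {}
    driver_gene = gene_by_name[DRIVER_GENE]
    protect = (driver_gene.chrom, driver_gene.midpoint)
    for comp, frac_sub in (
        (Component.LEP, config.frac_subclonal_seg_lep),
        (Component.MIP, config.frac_subclonal_seg_mip),
    ):
        sid = f"{patient}_{comp.value}"
        purity = float(rng.uniform(*config.purity_range))
        samples[comp.value] = ComponentSample(
            sample_id=sid, patient_id=patient, component=comp, purity=purity
        )
        segs, clonal, cnloh = _assign_segment_states(
            rng, bounds, sid, purity,
            config.frac_altered_seg, frac_sub, config.frac_cnloh, protect=protect,
        )
        segments[comp.value] = segs
        seg_clonal[comp.value] = clonal
        truth.purity[sid] = purity
        truth.segment_clonal[sid] = clonal
        truth.segment_cnloh[sid] = cnloh

    # --- draw mutation sites without replacement over the synthetic exome
    n_sites = config.n_truncal + 2 * (config.n_private_clonal + config.n_private_subclonal)
    usable = [g for g in gene_model if g.gene != DRIVER_GENE]
    gene_idx = rng.choice(len(usable), size=n_sites, replace=True)
    taken: set[tuple[str, int]] = set()
    sites: list[tuple[GeneModel, int]] = []
    for gi in gene_idx:
        g = usable[int(gi)]
        while True:
            pos = int(rng.integers(g.start, g.end + 1))
            if (g.chrom, pos) not in taken:
                taken.add((g.chrom, pos))
                sites.append((g, pos))
                break

    def _make_keys(n: int) -> list[tuple[GeneModel, int, str, str]]:
        out = []
        for _ in range(n):
            g, pos = sites.pop()
            ref, alt = rng.choice(4, size=2, replace=False)
            out.append((g, pos, str(_BASES[ref]), str(_BASES[alt])))
        return out

    truncal_sites = _make_keys(max(0, config.n_truncal - 1))
    if config.n_truncal > 0:
        dpos = int(rng.integers(driver_gene.start, driver_gene.end + 1))
        ref, alt = rng.choice(4, size=2, replace=False)
        truncal_sites.insert(0, (driver_gene, dpos, str(_BASES[ref]), str(_BASES[alt])))
    private_clonal = {c: _make_keys(config.n_private_clonal) for c in ("LEP", "MIP")}
    private_subclonal = {c: _make_keys(config.n_private_subclonal) for c in ("LEP", "MIP")}

    truth.truncal = [(g.chrom, pos, r, a) for g, pos, r, a in truncal_sites]
    mutations: dict[str, list[MutationRecord]] = {}
    for comp in ("LEP", "MIP"):
        sample = samples[comp]
        segs = segments[comp]
        truth.private_clonal[comp] = [(g.chrom, p, r, a) for g, p, r, a in private_clonal[comp]]
        truth.private_subclonal[comp] = [(g.chrom, p, r, a) for g, p, r, a in private_subclonal[comp]]
        truth.true_ccf[comp] = {}
        recs: list[MutationRecord] = []
        plan = (
            [(s, 1.0) for s in truncal_sites]
            + [(s, 1.0) for s in private_clonal[comp]]
            + [(s, float(rng.uniform(*config.subclonal_ccf_range))) for s in private_subclonal[comp]]
        )
        for (g, pos, ref, alt), ccf in plan:
            seg = _covering_segment(segs, g.chrom, pos)
            cnt = seg.total_cn
            if cnt == 2:
                m = 1
            else:
                m = int(rng.integers(1, max(seg.major_cn, 1) + 1))
            evaf = sample.purity * m * ccf / (sample.purity * cnt + 2 * (1 - sample.purity))
            depth = max(int(rng.poisson(config.depth_mean)), MIN_DEPTH)
            alt_count = int(rng.binomial(depth, min(evaf, 1.0)))
            recs.append(
                MutationRecord(
                    sample_id=sample.sample_id,
                    patient_id=patient,
                    component=sample.component,
                    chrom=g.chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=g.gene,
                    variant_class="missense",
                    alt_count=alt_count,
                    ref_count=depth - alt_count,
                    population_freq=None,
                    is_cancer_gene=(g.gene == DRIVER_GENE),
                )
            )
            truth.true_ccf[comp][key_str((g.chrom, pos, ref, alt))] = ccf
        recs.sort(key=lambda r: (int(r.chrom), r.pos))
        mutations[comp] = recs

    return PairData(samples=samples, mutations=mutations, segments=segments, truth=truth)


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path, overwrite: bool = False
) -> list[PairData]:
    """Simulate ``n_pairs`` independent pairs and write all pipeline inputs.

    Writes one mutation TSV and one SEG TSV per sample, a cohort metadata
    TSV, the synthetic gene model, and a truth JSON.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out} is not empty (use overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)

    pairs = [simulate_pair(config, i) for i in range(config.n_pairs)]
    all_samples: list[ComponentSample] = []
    truth_json: dict = {}
    for pair in pairs:
        for comp, sample in pair.samples.items():
            all_samples.append(sample)
            io_formats.write_mutation_table(
                pair.mutations[comp], out / f"{sample.sample_id}.muts.tsv"
            )
            io_formats.write_seg(pair.segments[comp], out / f"{sample.sample_id}.seg.tsv")
        t = asdict(pair.truth)
        t["truncal"] = [key_str(k) for k in pair.truth.truncal]
        t["private_clonal"] = {c: [key_str(k) for k in v] for c, v in pair.truth.private_clonal.items()}
        t["private_subclonal"] = {
            c: [key_str(k) for k in v] for c, v in pair.truth.private_subclonal.items()
        }
        truth_json[pair.truth.patient_id] = t
    io_formats.write_metadata(all_samples, out / "metadata.tsv")
    io_formats.write_gene_model(build_gene_model(config.n_genes), out / "genes.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)
    return pairs


def simulate_expression(
    n_genes: int,
    groups: Sequence[str],
    gene_sets: Sequence[GeneSet],
    shifts: Optional[Mapping[str, Mapping[str, float]]] = None,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Genes x samples expression matrix with planted gene-set shifts.

    Baseline log2 expression is gene-wise Gaussian around a log-normal
    landscape; for each entry of ``shifts`` (set name -> group label ->
    shift), genes of that set have their mean raised by ``shift`` log2
    units in samples of that group.
    """
    universe = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    uni_set = set(universe)
    for gs in gene_sets:
        missing = gs.genes - uni_set
        if missing:
            raise ValueError(f"gene set {gs.name!r} has genes outside the universe: {sorted(missing)[:3]}")
    set_names = {gs.name for gs in gene_sets}
    shifts = shifts or {}
    for name in shifts:
        if name not in set_names:
            raise ValueError(f"shift specified for unknown gene set {name!r}")

    rng = np.random.default_rng(seed % 2**31)
    base = rng.normal(5.0, 1.5, size=n_genes)  # gene-level baseline, log2 scale
    mat = base[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, len(groups)))
    gindex = {g: i for i, g in enumerate(universe)}
    for gs in gene_sets:
        per_group = shifts.get(gs.name, {})
        for group, shift in per_group.items():
            cols = [j for j, lab in enumerate(groups) if lab == group]
            rows = [gindex[g] for g in sorted(gs.genes)]
            for j in cols:
                mat[rows, j] += shift
    columns = [f"{lab}_{j:02d}" for j, lab in enumerate(groups)]
    return pd.DataFrame(mat, index=universe, columns=columns)
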