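"""Bundled example data for a paired LEP/MIP lung adenocarcinoma study.

Two small published-style summaries ship with the package so the tally and
comparison machinery can be exercised without any download:

* the per-gene subtype-specific alteration summary of a five-LEP /
  six-MIP micro-dissected component cohort (mutation and focal-CNV rows);
* the histological-predominance composition of a 286-patient LUAD
  resection cohort.

``expand_example_cohort`` turns the per-gene counts back into per-sample
mutation records and focal calls (with synthetic coordinates and read
counts, since the summary carries none), so that re-tallying them with
:func:`clonarch.stats.alteration_frequency_table` reproduces the summary.
The immune-cycle gene sets here are synthetic stand-ins for signature
sets of the cancer-immunity-cycle steps, sized for testing only.
"""

from __future__ import annotations

from .models import Component, FocalCall, GeneSet, MutationRecord

N_LEP_SAMPLES = 5
N_MIP_SAMPLES = 6

#: (gene, n_samples_altered_LEP, n_samples_altered_MIP, n_mutations_LEP, n_mutations_MIP)
EXAMPLE_MUTATION_SUMMARY: tuple[tuple[str, int, int, int, int], ...] = (
    ("C10orf71", 1, 0, 3, 0),
    ("SLC32A1", 1, 0, 4, 0),
    ("DISC1", 1, 0, 5, 0),
    ("AHCTF1", 0, 1, 0, 3),
    ("PHRF1", 1, 2, 1, 3),
    ("PLEC", 0, 1, 0, 3),
    ("RYR2", 1, 3, 1, 3),
    ("SI", 1, 3, 0, 3),
    ("SYNE2", 1, 2, 1, 4),
)

#: (gene, alteration type, n_samples_altered_LEP, n_samples_altered_MIP)
EXAMPLE_CNV_SUMMARY: tuple[tuple[str, str, int, int], ...] = (
    ("RCSD1", "Duplication", 3, 0),
    ("PTP4A3", "Duplication", 1, 5),
    ("EZR", "Deletion", 2, 5),
    ("NAPRT", "Duplication", 2, 5),
    ("RECQL4", "Duplication", 2, 5),
)

#: patients per predominant histological growth pattern, 286-patient cohort
EXAMPLE_PREDOMINANCE_COUNTS: dict[str, int] = {
    "LEP": 51,
    "ACI": 178,
    "PAP": 16,
    "MIP": 29,
    "SOL": 12,
}

LEP_SAMPLE_IDS = tuple(f"L{i:02d}" for i in range(1, N_LEP_SAMPLES + 1))
MIP_SAMPLE_IDS = tuple(f"M{i:02d}" for i in range(1, N_MIP_SAMPLES + 1))


def example_group_labels() -> dict[str, str]:
    labels = {s: "LEP" for s in LEP_SAMPLE_IDS}
    labels.update({s: "MIP" for s in MIP_SAMPLE_IDS})
    return labels


def expand_example_cohort() -> tuple[list[MutationRecord], list[FocalCall]]:
    """Per-sample records consistent with the bundled per-gene summary.

    Altered samples are assigned deterministically (the first ``n`` of
    each group); every altered sample carries at least one mutation and
    surplus mutations go to the group's first altered sample. Coordinates
    and read counts are synthetic placeholders — only the tallies are
    data.
    """
    mutations: list[MutationRecord] = []
    pos = 10_000
    for gi, (gene, n_lep, n_mip, m_lep, m_mip) in enumerate(EXAMPLE_MUTATION_SUMMARY):
        for group, n_samples, n_muts, sample_ids, comp in (
            ("LEP", n_lep, m_lep, LEP_SAMPLE_IDS, Component.LEP),
            ("MIP", n_mip, m_mip, MIP_SAMPLE_IDS, Component.MIP),
        ):
            n_muts = max(n_muts, n_samples)  # every altered sample needs >= 1 record
            carriers = list(sample_ids[:n_samples])
            per_sample = {s: 1 for s in carriers}
            if carriers:
                per_sample[carriers[0]] += n_muts - n_samples
            for sid in carriers:
                for _ in range(per_sample[sid]):
                    pos += 101
                    mutations.append(
                        MutationRecord(
                            sample_id=sid,
                            patient_id=sid,
                            component=comp,
                            chrom=str(gi % 22 + 1),
                            pos=pos,
                            ref="A",
                            alt="G",
                            gene=gene,
                            variant_class="missense",
                            alt_count=30,
                            ref_count=70,
                        )
                    )
    focal: list[FocalCall] = []
    for gene, alt_type, n_lep, n_mip in EXAMPLE_CNV_SUMMARY:
        direction = "amplified" if alt_type == "Duplication" else "deleted"
        for sample_ids, n in ((LEP_SAMPLE_IDS, n_lep), (MIP_SAMPLE_IDS, n_mip)):
            for sid in sample_ids[:n]:
                focal.append(
                    FocalCall(
                        sample_id=sid, gene=gene, direction=direction,
                        statistic=5.0 if direction == "amplified" else -5.0,
                        p=1e-4, q=1e-3,
                    )
                )
    return mutations, focal


IMMUNE_CYCLE_STEP_NAMES = (
    "Step1_release_of_cancer_cell_antigens",
    "Step4_CD8_T_cell_recruiting",
    "Step4_dendritic_cell_recruiting",
    "Step4_macrophage_recruiting",
    "Step4_Th17_cell_recruiting",
    "Step5_infiltration_of_T_cells_into_tumors",
    "Step7_killing_of_cancer_cells",
)


def example_immune_cycle_sets(n_genes: int = 200, set_size: int = 15) -> list[GeneSet]:
    """Synthetic immune-cycle step signatures over the simulated gene
    universe (disjoint deterministic blocks of ``set_size`` genes each)."""
    if len(IMMUNE_CYCLE_STEP_NAMES) * set_size > n_genes:
        raise ValueError("gene universe too small for the requested set size")
    sets = []
    for i, name in enumerate(IMMUNE_CYCLE_STEP_NAMES):
        start = i * set_size + 1
        genes = frozenset(f"G{j:04d}" for j in range(start, start + set_size))
        sets.append(GeneSet(name=name, genes=genes))
    return sets
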