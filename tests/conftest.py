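import pytest

from clonarch.models import Component, ComponentSample, CopySegment, MutationRecord


def make_mutation(
    sample_id="S1",
    patient_id="P1",
    component=Component.LEP,
    chrom="1",
    pos=1000,
    ref="A",
    alt="T",
    gene="G0001",
    variant_class="missense",
    alt_count=30,
    ref_count=70,
    population_freq=None,
    is_cancer_gene=False,
):
    return MutationRecord(
        sample_id=sample_id,
        patient_id=patient_id,
        component=component,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        variant_class=variant_class,
        alt_count=alt_count,
        ref_count=ref_count,
        population_freq=population_freq,
        is_cancer_gene=is_cancer_gene,
    )


@pytest.fixture
def diploid_segment():
    return CopySegment(
        sample_id="S1", chrom="1", start=1, end=10_000_000,
        log2_ratio=0.0, major_cn=1, minor_cn=1, segment_ccf=1.0,
    )


@pytest.fixture
def sample_pure():
    return ComponentSample(
        sample_id="S1", patient_id="P1", component=Component.LEP, purity=1.0
    )


def make_sample(purity=0.5, sample_id="S1", component=Component.LEP):
    return ComponentSample(
        sample_id=sample_id, patient_id="P1", component=component, purity=purity
    )
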