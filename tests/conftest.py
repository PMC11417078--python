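import pytest

from ctdnamon.calling import CandidateVariant
from ctdnamon.pipeline import run_pipeline
from ctdnamon.simulate import SimConfig, generate_cohort, generate_site_counts
from ctdnamon.variant_io import SiteCounts


def make_counts(
    alt_reads,
    ref_reads,
    library_id="lib",
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    gene="APC",
    consequence="missense",
):
    return SiteCounts(
        library_id=library_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        ref_reads=ref_reads,
        alt_reads=alt_reads,
        gene=gene,
        consequence=consequence,
    )


def make_candidate(
    vaf_t0,
    vaf_t1,
    patient_id="P1",
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    gene="APC",
    consequence="missense",
    depth=10_000,
):
    def sc(vaf, lib):
        alt_n = int(round(vaf * depth))
        return make_counts(
            alt_n, depth - alt_n, library_id=lib, chrom=chrom, pos=pos,
            ref=ref, alt=alt, gene=gene, consequence=consequence,
        )

    return CandidateVariant(
        patient_id=patient_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        t0_libraries=(sc(vaf_t0, "t0a"), sc(vaf_t0, "t0b")),
        t1_libraries=(sc(vaf_t1, "t1a"), sc(vaf_t1, "t1b")),
        buffycoat=sc(0.0, "bc"),
        vaf_t0=vaf_t0,
        vaf_t1=vaf_t1,
    )


@pytest.fixture(scope="session")
def sim_truth():
    return generate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_counts(sim_truth):
    return generate_site_counts(sim_truth)


@pytest.fixture(scope="session")
def pipeline_result(sim_truth, sim_counts):
    return run_pipeline(
        sim_counts,
        sim_truth.samples,
        sim_truth.buffycoat_libraries,
        clinical=list(sim_truth.patients),
    )
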