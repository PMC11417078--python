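"""Truth-labelled cohort generation: determinism, label structure, noise model."""

import dataclasses
import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from ctdnamon.pipeline import load_cohort_dir
from ctdnamon.simulate import (
    CohortTruth,
    ConfigError,
    PanelDesign,
    SimConfig,
    expected_vaf,
    generate_cohort,
    generate_site_counts,
    read_truth,
    write_fixture,
)


class TestGenerateCohort:
    def test_protocol_allocation_matches_cohort_proportions(self):
        """17 patients at 6:6:5 proportions come out exactly 6 RAPIDO, 6 fRCT, 5 SCRT."""
        truth = generate_cohort(SimConfig(seed=3))
        counts = Counter(p.protocol for p in truth.patients)
        assert counts == {"RAPIDO": 6, "fRCT": 6, "SCRT": 5}

    def test_fixed_seed_reproducibility(self):
        cfg = SimConfig(seed=42)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert a.patients == b.patients
        assert a.true_variants == b.true_variants
        assert a.samples == b.samples
        pd.testing.assert_frame_equal(a.sites, b.sites)
        ca, cb = generate_site_counts(a), generate_site_counts(b)
        assert ca.keys() == cb.keys()
        for lib in ca:
            pd.testing.assert_frame_equal(ca[lib], cb[lib])

    def test_no_tumor_variants_when_positive_fraction_zero(self):
        truth = generate_cohort(SimConfig(seed=5, ctdna_positive_fraction=0.0))
        assert all(v.origin != "tumor" for v in truth.true_variants)

    def test_library_plan_structure(self, sim_truth):
        """Two duplicate plasma libraries per timepoint, one buffycoat per patient."""
        per_patient = Counter(s.patient_id for s in sim_truth.samples)
        assert all(n == 2 for n in per_patient.values())
        assert set(per_patient) == set(sim_truth.buffycoat_libraries)
        assert all(len(s.library_ids) == 2 for s in sim_truth.samples)

    def test_variant_compartment_invariants(self, sim_truth):
        for v in sim_truth.true_variants:
            if v.origin == "germline":
                assert v.vaf_t0 == v.vaf_t1 == 0.5
            if v.origin == "chip":
                assert v.vaf_t0 == v.vaf_t1

    def test_staging_consistent_with_downstaging_flag(self, sim_truth):
        from ctdnamon.response import downstaging

        for p in sim_truth.patients:
            assert downstaging(p.cT, p.cN, p.ypT, p.ypN) == p.downstaging

    def test_invalid_mix_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(protocol_mix={"SCRT": 0.5, "RAPIDO": 0.2, "fRCT": 0.2})

    def test_tumor_sites_absent_from_buffycoat_expectation(self, sim_truth):
        """Leukocyte DNA carries no tumor signal beyond the error model."""
        for p in sim_truth.patients:
            exp = expected_vaf(sim_truth, p.patient_id, "buffycoat", "t0")
            idx = {
                (r.chrom, int(r.pos), r.ref, r.alt): i
                for i, r in enumerate(sim_truth.sites.itertuples(index=False))
            }
            for v in sim_truth.variants_of(p.patient_id):
                if v.origin == "tumor":
                    assert exp[idx[v.site]] == 0.0


class TestGenerateSiteCounts:
    def test_zero_probability_draws_zero_alt(self):
        """No expected VAF and no error rate can only give alt = 0."""
        cfg = SimConfig(
            seed=1,
            n_patients=2,
            ctdna_positive_fraction=0.0,
            n_chip_variants_per_patient=0,
            germline_het_count=0,
            error_rate_mean=0.0,
            panel=PanelDesign(n_genes=4, positions_per_gene=1),
        )
        truth = generate_cohort(cfg)
        counts = generate_site_counts(truth)
        for df in counts.values():
            assert (df["alt_reads"] == 0).all()

    def test_binomial_sampling_unbiased_at_known_vaf(self):
        """200 libraries at expected VAF 0.05, depth 10,000: the mean observed
        VAF lands within 3 binomial standard errors of truth."""
        cfg = SimConfig(
            seed=2,
            n_patients=50,
            ctdna_positive_fraction=0.0,
            n_chip_variants_per_patient=1,
            chip_vaf_range=(0.05, 0.05),
            germline_het_count=0,
            error_rate_mean=0.0,
            panel=PanelDesign(n_genes=4, positions_per_gene=1),
        )
        truth = generate_cohort(cfg)
        counts = generate_site_counts(truth)
        chip_site = next(v.site for v in truth.true_variants if v.origin == "chip")
        vafs = []
        for s in truth.samples:  # 50 patients x 2 timepoints x 2 replicates
            for lib in s.library_ids:
                df = counts[lib].set_index(["chrom", "pos", "ref", "alt"])
                row = df.loc[chip_site]
                vafs.append(row["alt_reads"] / (row["alt_reads"] + row["ref_reads"]))
        assert len(vafs) == 200
        se = math.sqrt(0.05 * 0.95 / 10_000)
        assert abs(np.mean(vafs) - 0.05) < 3 * se

    def test_germline_buffycoat_vaf_concentrates_at_half(self, sim_truth, sim_counts):
        """At depth >= 1,000 a heterozygous site stays within (0.4, 0.6);
        the binomial tail bound puts the failure probability below 1e-3."""
        # oracle: brute-force binomial CDF at the loosest covered depth
        assert binom.cdf(599, 1000, 0.5) - binom.cdf(400, 1000, 0.5) > 0.999
        for pid, lib in sim_truth.buffycoat_libraries.items():
            df = sim_counts[lib].set_index(["chrom", "pos", "ref", "alt"])
            for v in sim_truth.variants_of(pid):
                if v.origin != "germline":
                    continue
                row = df.loc[v.site]
                depth = row["alt_reads"] + row["ref_reads"]
                assert depth >= 1000
                assert 0.4 < row["alt_reads"] / depth < 0.6

    def test_pooled_duplicates_unbiased_over_seeds(self):
        """Pooling the two duplicates estimates the true VAF without bias."""
        diffs = []
        cfg_base = SimConfig(
            n_patients=4,
            ctdna_positive_fraction=0.0,
            n_chip_variants_per_patient=1,
            chip_vaf_range=(0.02, 0.02),
            germline_het_count=0,
            error_rate_mean=0.0,
            panel=PanelDesign(n_genes=4, positions_per_gene=1),
        )
        for seed in range(100):
            cfg = dataclasses.replace(cfg_base, seed=seed)
            truth = generate_cohort(cfg)
            counts = generate_site_counts(truth)
            site = next(v.site for v in truth.true_variants if v.origin == "chip")
            for s in truth.samples:
                a = counts[s.library_ids[0]].set_index(["chrom", "pos", "ref", "alt"]).loc[site]
                b = counts[s.library_ids[1]].set_index(["chrom", "pos", "ref", "alt"]).loc[site]
                alt = a["alt_reads"] + b["alt_reads"]
                depth = alt + a["ref_reads"] + b["ref_reads"]
                diffs.append(alt / depth - 0.02)
        se = math.sqrt(0.02 * 0.98 / 20_000)
        assert abs(np.mean(diffs)) < 3 * se


class TestWriteFixture:
    def test_round_trip(self, tmp_path, sim_truth, sim_counts):
        write_fixture(sim_truth, sim_counts, tmp_path)
        counts, samples, bc_map, clinical = load_cohort_dir(tmp_path)
        assert tuple(samples) == sim_truth.samples
        assert bc_map == sim_truth.buffycoat_libraries
        assert tuple(clinical) == sim_truth.patients
        assert set(counts) == set(sim_counts)
        lib = next(iter(sim_counts))
        pd.testing.assert_frame_equal(counts[lib], sim_counts[lib])
        assert tuple(read_truth(tmp_path / "cohort_truth.tsv")) == sim_truth.true_variants

    def test_empty_cohort_writes_valid_headers(self, tmp_path):
        truth = CohortTruth(
            config=SimConfig(),
            sites=pd.DataFrame(
                columns=["chrom", "pos", "ref", "alt", "gene", "consequence", "error_rate"]
            ),
            patients=(),
            true_variants=(),
            samples=(),
            buffycoat_libraries={},
        )
        write_fixture(truth, {}, tmp_path)
        manifest = pd.read_csv(tmp_path / "manifest.tsv", sep="\t")
        assert len(manifest) == 0
        assert list(manifest.columns) == [
            "patient_id", "timepoint", "library_id", "replicate", "compartment", "cfdna_ng",
        ]
        assert len(pd.read_csv(tmp_path / "cohort_truth.tsv", sep="\t")) == 0
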