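"""Cohort container, CSV/VCF readers, genotype counting, MAF orientation."""

import numpy as np
import pandas as pd
import pytest

from snpcc.cohort import (
    CohortTable,
    DataError,
    GenotypeCounts,
    SchemaError,
    SnpInfo,
    genotype_counts,
    merge_vcf_cohort,
    minor_allele,
    normalize_genotype,
    read_cohort,
    write_cohort,
)
from snpcc.config import schema_for
from snpcc.simulate import SimSnp, SimulationConfig, simulate_cohort


class TestReadCohort:
    def test_reads_tiny_fixture(self, tiny_cohort_csv, tiny_schema):
        cohort = read_cohort(tiny_cohort_csv, tiny_schema)
        assert len(cohort.data) == 3
        assert cohort.n_cases == 2 and cohort.n_controls == 1
        cc = genotype_counts(cohort, "rs0001", "case")
        assert cc.as_tuple() == (0, 1, 0) and cc.n_missing == 1

    def test_na_genotype_counted_missing_but_subject_kept(self, tiny_cohort_csv, tiny_schema):
        cohort = read_cohort(tiny_cohort_csv, tiny_schema)
        assert cohort.data.loc[cohort.data.subject_id == "P2", "age_years"].iloc[0] == 7.0
        assert pd.isna(cohort.data.loc[cohort.data.subject_id == "P2", "rs0001"]).all()

    def test_missing_status_column_is_schema_error(self, tmp_path, tiny_schema):
        path = tmp_path / "bad.csv"
        path.write_text("subject_id,rs0001\nP1,A/A\n")
        with pytest.raises(SchemaError, match="status"):
            read_cohort(path, tiny_schema)

    def test_unknown_allele_names_subject_and_snp(self, tmp_path, tiny_schema):
        path = tmp_path / "bad.csv"
        path.write_text(
            "subject_id,status,rs0001\nP1,case,A/C\nP2,control,G/T\n"
        )
        with pytest.raises(DataError, match="P2.*rs0001"):
            read_cohort(path, tiny_schema)

    def test_duplicate_subject_id_fatal(self, tmp_path, tiny_schema):
        path = tmp_path / "dup.csv"
        path.write_text(
            "subject_id,status,rs0001\nP1,case,A/A\nP1,control,A/C\n"
        )
        with pytest.raises(DataError, match="duplicate"):
            read_cohort(path, tiny_schema)

    def test_simulated_cohort_round_trips(self, tmp_path):
        cohort = simulate_cohort(SimulationConfig(n_cases=60, n_controls=80, seed=11))
        path = tmp_path / "sim.csv"
        write_cohort(cohort, path)
        back = read_cohort(path, schema_for(cohort))
        pd.testing.assert_frame_equal(
            back.data.reset_index(drop=True),
            cohort.data.reset_index(drop=True),
            check_dtype=False,
        )


class TestGenotypeParsing:
    @pytest.mark.parametrize("raw,expected", [
        ("A/C", "A/C"), ("C/A", "A/C"), ("C|A", "A/C"), (" A / C ", "A/C"),
    ])
    def test_allele_pairs_are_unordered(self, raw, expected):
        assert normalize_genotype(raw) == expected

    @pytest.mark.parametrize("raw", ["", "NA", ".", "./."])
    def test_missing_tokens(self, raw):
        assert np.isnan(normalize_genotype(raw))

    def test_malformed_pair_raises(self):
        with pytest.raises(DataError):
            normalize_genotype("ACG")


class TestGenotypeCounts:
    def test_control_counts_match_bundled_study(self, study_cohort):
        ct = genotype_counts(study_cohort, "rs285207", "control")
        assert ct.as_tuple() == (656, 292, 21)

    def test_missing_inferred_from_group_size(self, study_cohort):
        ct = genotype_counts(study_cohort, "rs285162", "control")
        assert ct.as_tuple() == (796, 152, 7)
        assert ct.n_missing == 16
        assert ct.n_total == 971

    def test_empty_group_all_zero(self):
        info = SnpInfo("rs1", "A", "C")
        df = pd.DataFrame({
            "subject_id": ["P1"], "status": ["case"], "rs1": ["A/A"],
        })
        cohort = CohortTable(data=df, snps={"rs1": info})
        assert genotype_counts(cohort, "rs1", "control").as_tuple() == (0, 0, 0)

    def test_unregistered_snp_errors(self, study_cohort):
        with pytest.raises(KeyError):
            genotype_counts(study_cohort, "rs999", "case")

    def test_counts_invariant_to_subject_order(self, study_cohort):
        shuffled = study_cohort.subset(
            pd.Series(True, index=study_cohort.data.index)
        )
        shuffled.data = shuffled.data.sample(frac=1.0, random_state=3).reset_index(drop=True)
        for group in ("case", "control"):
            assert (
                genotype_counts(shuffled, "rs285207", group).as_tuple()
                == genotype_counts(study_cohort, "rs285207", group).as_tuple()
            )

    def test_conservation_over_simulated_cohort(self):
        cohort = simulate_cohort(SimulationConfig(n_cases=120, n_controls=150, seed=5))
        for snp in cohort.snps:
            for group, n in (("case", 120), ("control", 150)):
                counts = genotype_counts(cohort, snp, group)
                assert counts.n_total == n


class TestMinorAllele:
    def test_maf_from_control_counts(self):
        counts = GenotypeCounts("rs285207", "control", 656, 292, 21)
        info = SnpInfo("rs285207", "A", "C")
        allele, maf = minor_allele(counts, info)
        assert allele == "C"
        assert maf == pytest.approx(334 / 1938, abs=1e-9)
        assert maf == pytest.approx(0.172, abs=5e-4)

    def test_monomorphic_swap_with_warning(self, caplog):
        counts = GenotypeCounts("rs1", "control", 0, 0, 10)
        info = SnpInfo("rs1", "A", "C")
        with caplog.at_level("WARNING"):
            allele, maf = minor_allele(counts, info)
        assert allele == "A" and maf == 0.0
        assert any("swap" in rec.message for rec in caplog.records)

    def test_half_boundary_no_swap(self):
        counts = GenotypeCounts("rs1", "control", 50, 0, 50)
        allele, maf = minor_allele(counts, SnpInfo("rs1", "A", "C"))
        assert allele == "C" and maf == 0.5

    def test_all_missing_errors(self):
        counts = GenotypeCounts("rs1", "control", 0, 0, 0, n_missing=4)
        with pytest.raises(ValueError, match="missing"):
            minor_allele(counts, SnpInfo("rs1", "A", "C"))


class TestVcfIngest:
    def test_vcf_merge_with_covariates(self, tmp_path):
        pytest.importorskip("pysam")
        vcf = tmp_path / "geno.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=20>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\tP3\n"
            "20\t42295379\trs0001\tA\tC\t.\tPASS\t.\tGT\t0/1\t1|1\t./.\n"
        )
        covars = tmp_path / "covars.csv"
        covars.write_text(
            "subject_id,status,age_years,sex\n"
            "P1,case,3.5,female\nP2,control,5.0,male\nP3,case,2.0,male\n"
        )
        cohort = merge_vcf_cohort(vcf, covars, {"snps": []})
        got = dict(zip(cohort.data.subject_id, cohort.data.rs0001))
        assert got["P1"] == "A/C"          # unphased het
        assert got["P2"] == "C/C"          # phased separator accepted
        assert pd.isna(got["P3"])           # missing call
        assert cohort.snps["rs0001"].allele_major == "A"
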