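import pytest

from snpcc.datasets import load_all_study_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """Pseudo-individual expansion of the bundled childhood-ALL study counts."""
    return load_all_study_cohort()


@pytest.fixture()
def tiny_cohort_csv(tmp_path):
    """4-line cohort CSV: 2 cases, 1 control, one SNP, one NA genotype."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "subject_id,status,age_years,sex,rs0001\n"
        "P1,case,4.5,female,A/C\n"
        "P2,case,7.0,male,NA\n"
        "P3,control,6.2,male,A/A\n"
    )
    return path


@pytest.fixture()
def tiny_schema():
    return {
        "snps": [{"snp_id": "rs0001", "allele_major": "A", "allele_minor": "C"}],
    }
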