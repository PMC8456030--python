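"""Bundled example dataset: published summary counts from a childhood
acute-lymphoblastic-leukemia (ALL) case-control study of three candidate
SNPs in the MYBL2 promoter/coding region (687 cases, 971 cancer-free
controls, Han Chinese).

Only group-level counts are bundled — per-SNP genotype tallies by status,
demographic margins, and subgroup splits of the rs285207 dominant contrast.
:func:`load_all_study_cohort` expands them into a pseudo-individual cohort
(via :func:`snpcc.simulate.cohort_from_counts`) whose margins reproduce the
published cells exactly, so the count-level results can be recomputed
through the individual-level pipeline. Individual ages and the joint
distribution of clinical attributes were never published; the pseudo cohort
carries a banded ``age_band`` attribute instead of continuous age, and its
cross-variable joints are arbitrary.
"""

from __future__ import annotations

from .cohort import CohortTable, SnpInfo
from .simulate import cohort_from_counts

N_CASES = 687
N_CONTROLS = 971

SNP_REGISTRY = {
    "rs285162": SnpInfo(
        snp_id="rs285162", allele_major="C", allele_minor="T",
        chromosome="20", position=42328639,
        functional_flags=frozenset({"SRS"}),
        population_maf={"CHB": 0.113},
    ),
    "rs285207": SnpInfo(
        snp_id="rs285207", allele_major="A", allele_minor="C",
        chromosome="20", position=42295379,
        functional_flags=frozenset({"TFBS"}),
        population_maf={"CHB": 0.226},
    ),
    "rs2070235": SnpInfo(
        snp_id="rs2070235", allele_major="A", allele_minor="G",
        chromosome="20", position=42328639,
        functional_flags=frozenset({"nsSNP"}),
        population_maf={"CHB": 0.108},
    ),
}

#: (major hom, het, minor hom) per SNP per group; shortfalls vs the group
#: size are untyped subjects
GENOTYPE_COUNTS = {
    "rs285162": {"case": (553, 111, 7), "control": (796, 152, 7)},
    "rs285207": {"case": (502, 165, 19), "control": (656, 292, 21)},
    "rs2070235": {"case": (577, 99, 5), "control": (798, 170, 3)},
}

# Subgroup margins for the rs285207 dominant contrast (AA vs AC/CC carriers).
# Tuples are (level, n in AA block, n in carrier block[, n untyped]); control
# margins exist only for variables recorded on both groups (age band, sex) —
# the published untyped subjects are placed to match the whole-group
# demographic margins (1 untyped case: male, <10; 2 untyped controls: male,
# <10).
ATTRIBUTE_MARGINS = {
    "age_band": {
        "case": [("<10", 444, 164, 1), (">=10", 58, 20)],
        "control": [("<10", 588, 281, 2), (">=10", 68, 32)],
    },
    "immunophenotype": {
        "case": [("Pro B", 166, 61), ("Common B", 135, 64), ("Pre B", 131, 35),
                 ("Mature B", 3, 0), ("T ALL", 45, 16)],
        "control": None,
    },
    "fusion_type": {
        "case": [("BCR-ABL", 11, 7), ("ETV6-RUNX1", 101, 24), ("E2A-PBX1", 15, 6),
                 ("SIL-TAL", 6, 1), ("MLL", 8, 3), ("Other", 10, 4),
                 ("Normal", 347, 135)],
        "control": None,
    },
    "risk_level": {
        "case": [("Low", 183, 57), ("Medium", 225, 93), ("High", 47, 15)],
        "control": None,
    },
    "karyotype": {
        "case": [("Normal diploid", 327, 113), ("Abnormal diploid", 27, 12),
                 ("Hypo-diploid", 11, 8), ("Low hyper-diploid", 12, 6),
                 ("High hyper-diploid", 38, 18)],
        "control": None,
    },
    "wbc_category": {
        "case": [("Lower", 166, 48), ("Higher", 181, 75), ("Normal", 102, 45)],
        "control": None,
    },
    "hemoglobin_category": {
        "case": [("Lower", 384, 149), ("Higher", 2, 0), ("Normal", 60, 17)],
        "control": None,
    },
    "platelet_category": {
        "case": [("Lower", 366, 131), ("Higher", 5, 6), ("Normal", 79, 30)],
        "control": None,
    },
    "relapse": {
        "case": [("-", 340, 125), ("+", 13, 6)],
        "control": None,
    },
}

#: sex within the rs285207 blocks (recorded on both groups)
SEX_MARGINS = {
    "case": [("female", 212, 66), ("male", 290, 118, 1)],
    "control": [("female", 243, 112), ("male", 413, 201, 2)],
}

#: whole-group demographic margins (age band and sex)
DEMOGRAPHICS = {
    "age_band": {"case": {"<10": 609, ">=10": 78}, "control": {"<10": 871, ">=10": 100}},
    "sex": {"case": {"female": 278, "male": 409}, "control": {"female": 355, "male": 616}},
}

#: published HWE p-values in controls, as reference metadata
PUBLISHED_HWE_CONTROLS = {"rs285162": 0.7301, "rs285207": 0.0797, "rs2070235": 0.0527}


def load_all_study_cohort() -> CohortTable:
    """Pseudo-individual cohort reproducing the published count margins.

    Subjects are ordered by rs285207 genotype block within each group; every
    attribute column and every SNP's genotype column independently matches
    its published margin. Sex is materialized into the core ``sex`` column;
    continuous age is unavailable (``age_years`` is all-missing) — use the
    ``age_band`` attribute, with ``age_band`` as the adjusted-model covariate
    where one is wanted.
    """
    margins = {k: v for k, v in ATTRIBUTE_MARGINS.items() if v is not None}
    margins["sex_attr"] = SEX_MARGINS
    cohort = cohort_from_counts(
        genotype_counts=GENOTYPE_COUNTS,
        group_sizes={"case": N_CASES, "control": N_CONTROLS},
        snp_registry=SNP_REGISTRY,
        anchor_snp="rs285207",
        attribute_margins=margins,
    )
    cohort.data["sex"] = cohort.data.pop("sex_attr")
    cohort.attribute_columns = [c for c in cohort.attribute_columns if c != "sex_attr"]
    cohort.provenance["source"] = "bundled childhood-ALL MYBL2 study counts"
    return cohort


__all__ = [
    "N_CASES", "N_CONTROLS", "SNP_REGISTRY", "GENOTYPE_COUNTS",
    "ATTRIBUTE_MARGINS", "SEX_MARGINS", "DEMOGRAPHICS",
    "PUBLISHED_HWE_CONTROLS", "load_all_study_cohort",
]
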