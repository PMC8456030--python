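"""Synthetic case-control cohorts and count-expansion pseudo-cohorts.

``simulate_cohort`` draws a cohort with the structure the analysis assumes:
control genotypes in Hardy-Weinberg proportions at a configured minor-allele
frequency, case genotypes from the control distribution reweighted by the
genetic model's odds multiplier (exact for retrospective case-control
sampling under a logistic risk model), independent age/sex covariates, a
case-only subtype mixture, and status-independent genotype missingness.

``cohort_from_counts`` goes the other way: it expands published genotype and
subgroup counts into a pseudo-individual cohort whose per-SNP and per-stratum
margins exactly reproduce the input cells, so count-level results from the
literature can be recomputed through the same individual-level pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CASE, CONTROL, CohortTable, SnpInfo
from .stats import MODEL_CODING


@dataclass(frozen=True)
class SimSnp:
    """Generative spec for one SNP: control MAF plus a model/OR effect."""

    snp_id: str
    maf: float
    model: str = "dominant"
    odds_ratio: float = 1.0
    allele_major: str = "A"
    allele_minor: str = "C"

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: control MAF must be in (0, 0.5]")
        if self.odds_ratio <= 0:
            raise ValueError(f"{self.snp_id}: effect OR must be positive")
        if self.model not in MODEL_CODING or self.model.startswith("codominant"):
            raise ValueError(
                f"{self.snp_id}: effect model must be additive/dominant/recessive"
            )


# Default study conditions: a pediatric ALL case-control design with three
# candidate SNPs at Han-Chinese reference MAFs and modest per-model effects.
DEFAULT_SNPS = (
    SimSnp("rs285162", maf=0.113, model="additive", odds_ratio=1.08,
           allele_major="C", allele_minor="T"),
    SimSnp("rs285207", maf=0.226, model="dominant", odds_ratio=0.77,
           allele_major="A", allele_minor="C"),
    SimSnp("rs2070235", maf=0.108, model="dominant", odds_ratio=0.83,
           allele_major="A", allele_minor="G"),
)

# "Unclassified" stands in for cases published without an immunophenotype
# call; a literal "NA" label would collide with the missing-value token.
DEFAULT_SUBTYPES = {
    "Pro B": 0.3304, "Common B": 0.2911, "Pre B": 0.2416, "Mature B": 0.0044,
    "T ALL": 0.0888, "Unclassified": 0.0437,
}


@dataclass
class SimulationConfig:
    """Full generative specification of a synthetic cohort."""

    n_cases: int = 687
    n_controls: int = 971
    snps: tuple = DEFAULT_SNPS
    age_mean: float = 5.2
    age_sd: float = 2.9
    age_range: tuple = (0.5, 18.0)
    sex_male_fraction: float = 0.60
    subtype_mixture: dict = field(default_factory=lambda: dict(DEFAULT_SUBTYPES))
    covariate_effects: dict = field(default_factory=lambda: {"age": 0.0, "sex": 0.0})
    missing_rate: float = 0.015
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("group sizes must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.sex_male_fraction <= 1.0:
            raise ValueError("sex_male_fraction must be in [0, 1]")
        if self.age_sd <= 0 or self.age_range[0] >= self.age_range[1]:
            raise ValueError("invalid age distribution")
        if self.subtype_mixture:
            total = sum(self.subtype_mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"subtype probabilities sum to {total}, expected 1")
        for snp in self.snps:
            if not isinstance(snp, SimSnp):
                raise ValueError("snps must be SimSnp instances")


def control_genotype_probs(maf: float) -> np.ndarray:
    """HWE genotype probabilities (major hom, het, minor hom)."""
    p, q = 1.0 - maf, maf
    return np.array([p * p, 2 * p * q, q * q])


def case_genotype_probs(maf: float, model: str, odds_ratio: float) -> np.ndarray:
    """Control HWE probabilities reweighted by the model's odds multiplier.

    Under a logistic risk model with rare-or-common disease sampled
    retrospectively, case genotype frequencies are proportional to
    P(g) * OR^encoding(g); the normalization absorbs the intercept.
    """
    base = control_genotype_probs(maf)
    enc = np.array([MODEL_CODING[model][g] for g in (0, 1, 2)], dtype=float)
    weighted = base * odds_ratio ** enc
    return weighted / weighted.sum()


def _truncated_normal(rng, mean, sd, lo, hi, size):
    from scipy import stats as sps

    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(config: SimulationConfig) -> CohortTable:
    """Draw a synthetic cohort; fully reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_case, n_ctrl = config.n_cases, config.n_controls
    n = n_case + n_ctrl
    status = np.array([CASE] * n_case + [CONTROL] * n_ctrl)

    df = pd.DataFrame({
        "subject_id": [f"SIM{i:06d}" for i in range(n)],
        "status": status,
    })

    # covariates: independent of genotype; optional log-odds tilt for cases
    age = _truncated_normal(rng, config.age_mean, config.age_sd,
                            *config.age_range, size=n)
    beta_age = config.covariate_effects.get("age", 0.0)
    if beta_age != 0.0:
        # importance-resample case ages so P(age | case) tilts by exp(beta*age)
        pool = _truncated_normal(rng, config.age_mean, config.age_sd,
                                 *config.age_range, size=max(10 * n_case, 1000))
        w = np.exp(beta_age * pool)
        age[:n_case] = rng.choice(pool, size=n_case, p=w / w.sum())
    df["age_years"] = np.round(age, 2)

    p_male = np.full(n, config.sex_male_fraction)
    beta_sex = config.covariate_effects.get("sex", 0.0)
    if beta_sex != 0.0:
        pm = config.sex_male_fraction
        tilted = pm * np.exp(beta_sex) / (pm * np.exp(beta_sex) + (1 - pm))
        p_male[:n_case] = tilted
    df["sex"] = np.where(rng.random(n) < p_male, "male", "female")

    registry: dict[str, SnpInfo] = {}
    for snp in config.snps:
        registry[snp.snp_id] = SnpInfo(
            snp_id=snp.snp_id,
            allele_major=snp.allele_major,
            allele_minor=snp.allele_minor,
        )
        probs_ctrl = control_genotype_probs(snp.maf)
        probs_case = case_genotype_probs(snp.maf, snp.model, snp.odds_ratio)
        codes = np.empty(n, dtype=int)
        codes[:n_case] = rng.choice(3, size=n_case, p=probs_case)
        codes[n_case:] = rng.choice(3, size=n_ctrl, p=probs_ctrl)
        strings = np.array([registry[snp.snp_id].genotype_string(k) for k in (0, 1, 2)])
        column = strings[codes].astype(object)
        if config.missing_rate > 0:
            column[rng.random(n) < config.missing_rate] = np.nan
        df[snp.snp_id] = column

    attribute_columns = []
    if config.subtype_mixture:
        labels = list(config.subtype_mixture)
        probs = np.array([config.subtype_mixture[k] for k in labels])
        subtype = np.full(n, np.nan, dtype=object)
        subtype[:n_case] = rng.choice(labels, size=n_case, p=probs / probs.sum())
        df["immunophenotype"] = subtype
        attribute_columns.append("immunophenotype")

    return CohortTable(
        data=df,
        snps=registry,
        attribute_columns=attribute_columns,
        provenance={"source": "simulate_cohort", "seed": config.seed},
    )


class MarginError(ValueError):
    """Published margins are mutually inconsistent."""


def cohort_from_counts(
    genotype_counts: dict,
    group_sizes: dict,
    snp_registry: dict[str, SnpInfo],
    anchor_snp: str | None = None,
    attribute_margins: dict | None = None,
) -> CohortTable:
    """Expand published genotype (and subgroup) counts into a pseudo cohort.

    Parameters
    ----------
    genotype_counts:
        ``{snp_id: {"case": (n_major_hom, n_het, n_minor_hom), "control": ...}}``;
        any shortfall against the group size becomes missing genotypes.
    group_sizes:
        ``{"case": N, "control": M}``.
    snp_registry:
        ``{snp_id: SnpInfo}`` fixing allele orientation.
    anchor_snp:
        the SNP whose genotype blocks order the subjects; subgroup margins are
        expressed against this SNP's reference-homozygote vs carrier split.
    attribute_margins:
        ``{variable: {"case": [(level, n_ref_hom, n_carrier)], "control": ...}}``
        allocating attribute levels within the anchor SNP's genotype blocks
        (``None`` for a group leaves that group's column missing); unallocated
        subjects get a missing value.

    The resulting cohort's per-SNP genotype counts and per-stratum contrast
    cells exactly equal the input margins. The joint distribution across
    variables (and across SNPs) is otherwise arbitrary — only the margins the
    count-level analyses consume are meaningful.
    """
    if not genotype_counts:
        return CohortTable(
            data=pd.DataFrame(columns=["subject_id", "status", "age_years", "sex"]),
            snps=dict(snp_registry),
        )
    n_by_group = {g: int(group_sizes[g]) for g in (CASE, CONTROL)}
    frames = {}
    for group in (CASE, CONTROL):
        n = n_by_group[group]
        frames[group] = pd.DataFrame({
            "subject_id": [f"{group[:4]}{i:05d}" for i in range(n)],
            "status": group,
            "age_years": np.nan,
            "sex": pd.Series([np.nan] * n, dtype=object),
        })

    anchor = anchor_snp or next(iter(genotype_counts))
    block_order: dict[str, np.ndarray] = {}
    for snp_id, per_group in genotype_counts.items():
        info = snp_registry[snp_id]
        for group, tup in per_group.items():
            n = n_by_group[group]
            typed = sum(tup)
            if typed > n:
                raise MarginError(
                    f"{snp_id} {group}: genotype cells sum to {typed} > group size {n}"
                )
            strings = [info.genotype_string(k) for k in (0, 1, 2)]
            col = np.array(
                [strings[0]] * tup[0] + [strings[1]] * tup[1]
                + [strings[2]] * tup[2] + [np.nan] * (n - typed),
                dtype=object,
            )
            frames[group][snp_id] = col
            if snp_id == anchor:
                block_order[group] = np.array(tup + (n - typed,))

    attribute_columns: list[str] = []
    for variable, per_group in (attribute_margins or {}).items():
        attribute_columns.append(variable)
        for group in (CASE, CONTROL):
            n = n_by_group[group]
            allocations = (per_group or {}).get(group)
            if allocations is None:
                frames[group][variable] = pd.Series([np.nan] * n, dtype=object)
                continue
            blocks = block_order.get(group)
            if blocks is None:
                raise MarginError(
                    f"attribute margins for {variable!r} need anchor SNP "
                    f"{anchor!r} counts for group {group!r}"
                )
            n_ref_hom = int(blocks[0])
            n_carrier = int(blocks[1] + blocks[2])
            n_untyped = int(blocks[3])
            ref_labels: list = []
            carrier_labels: list = []
            untyped_labels: list = []
            for alloc in allocations:
                level, n_ref, n_car = alloc[0], alloc[1], alloc[2]
                n_unt = alloc[3] if len(alloc) > 3 else 0
                ref_labels.extend([level] * int(n_ref))
                carrier_labels.extend([level] * int(n_car))
                untyped_labels.extend([level] * int(n_unt))
            if (len(ref_labels) > n_ref_hom or len(carrier_labels) > n_carrier
                    or len(untyped_labels) > n_untyped):
                raise MarginError(
                    f"{variable!r} {group}: allocations ({len(ref_labels)} ref, "
                    f"{len(carrier_labels)} carrier, {len(untyped_labels)} untyped) "
                    f"exceed anchor blocks ({n_ref_hom} ref, {n_carrier} carrier, "
                    f"{n_untyped} untyped)"
                )
            ref_labels += [np.nan] * (n_ref_hom - len(ref_labels))
            carrier_labels += [np.nan] * (n_carrier - len(carrier_labels))
            untyped_labels += [np.nan] * (n_untyped - len(untyped_labels))
            frames[group][variable] = pd.Series(
                ref_labels + carrier_labels + untyped_labels, dtype=object
            )

    df = pd.concat([frames[CASE], frames[CONTROL]], ignore_index=True)
    return CohortTable(
        data=df,
        snps=dict(snp_registry),
        attribute_columns=attribute_columns,
        provenance={"source": "cohort_from_counts", "anchor_snp": anchor},
    )


__all__ = [
    "SimSnp", "SimulationConfig", "simulate_cohort",
    "control_genotype_probs", "case_genotype_probs", "cohort_from_counts",
    "MarginError", "DEFAULT_SNPS", "DEFAULT_SUBTYPES",
]
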