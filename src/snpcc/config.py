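"""Structured configuration: cohort column schemas and run configs (YAML)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import DEFAULT_MISSING_TOKENS, SnpInfo

DEFAULT_STATUS_LABELS = {"case": "case", "control": "control", "1": "case", "0": "control"}
DEFAULT_SEX_LABELS = {"female": "female", "male": "male", "F": "female", "M": "male"}


@dataclass(frozen=True)
class SnpColumn:
    """One genotype column: the SNP it holds and its allele orientation."""

    snp_id: str
    allele_major: str
    allele_minor: str
    column: str | None = None
    chromosome: str = ""
    position: int | None = None
    functional_flags: frozenset = frozenset()
    population_maf: dict = field(default_factory=dict)

    @property
    def info(self) -> SnpInfo:
        return SnpInfo(
            snp_id=self.snp_id,
            allele_major=self.allele_major,
            allele_minor=self.allele_minor,
            chromosome=self.chromosome,
            position=self.position,
            functional_flags=frozenset(self.functional_flags),
            population_maf=dict(self.population_maf),
        )


@dataclass
class CohortSchema:
    """Column mapping for :func:`snpcc.cohort.read_cohort`."""

    snps: list[SnpColumn]
    status_column: str = "status"
    status_labels: dict = field(default_factory=lambda: dict(DEFAULT_STATUS_LABELS))
    id_column: str | None = "subject_id"
    age_column: str | None = "age_years"
    sex_column: str | None = "sex"
    sex_labels: dict = field(default_factory=lambda: dict(DEFAULT_SEX_LABELS))
    attribute_columns: list[str] = field(default_factory=list)
    missing_tokens: tuple = DEFAULT_MISSING_TOKENS
    delimiter: str = ","

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSchema":
        snps = []
        for s in d.get("snps", []):
            snps.append(
                SnpColumn(
                    snp_id=s["snp_id"],
                    allele_major=s["allele_major"],
                    allele_minor=s["allele_minor"],
                    column=s.get("column"),
                    chromosome=str(s.get("chromosome", "")),
                    position=s.get("position"),
                    functional_flags=frozenset(s.get("functional_flags", [])),
                    population_maf=dict(s.get("population_maf", {})),
                )
            )
        return cls(
            snps=snps,
            status_column=d.get("status_column", "status"),
            status_labels=dict(d.get("status_labels", DEFAULT_STATUS_LABELS)),
            id_column=d.get("id_column", "subject_id"),
            age_column=d.get("age_column", "age_years"),
            sex_column=d.get("sex_column", "sex"),
            sex_labels=dict(d.get("sex_labels", DEFAULT_SEX_LABELS)),
            attribute_columns=list(d.get("attribute_columns", [])),
            missing_tokens=tuple(d.get("missing_tokens", DEFAULT_MISSING_TOKENS)),
            delimiter=d.get("delimiter", ","),
        )

    @classmethod
    def from_yaml(cls, path) -> "CohortSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def schema_for(cohort) -> CohortSchema:
    """Schema that re-reads a CSV written by :func:`snpcc.cohort.write_cohort`."""
    snps = [
        SnpColumn(
            snp_id=info.snp_id,
            allele_major=info.allele_major,
            allele_minor=info.allele_minor,
            chromosome=info.chromosome,
            position=info.position,
            functional_flags=info.functional_flags,
            population_maf=info.population_maf,
        )
        for info in cohort.snps.values()
    ]
    return CohortSchema(snps=snps, attribute_columns=list(cohort.attribute_columns))


@dataclass
class FprpSettings:
    priors: tuple = (0.25, 0.1, 0.01, 0.001, 0.0001)
    or0: float = 0.67
    threshold: float = 0.2
    significance_gate: float = 0.05


@dataclass
class RunConfig:
    """Full analysis run: input, models, strata, FPRP settings, output."""

    input_path: str | None
    schema: CohortSchema | None
    snp_ids: list[str]
    models: list[str]
    covariates: list[str] = field(default_factory=lambda: ["age", "sex"])
    stratum_specs: list[dict] = field(default_factory=list)
    fprp: FprpSettings = field(default_factory=FprpSettings)
    output_dir: str = "results"
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        base = Path(path).parent
        input_path = d.get("input")
        if input_path is not None and not Path(input_path).is_absolute():
            input_path = str(base / input_path)
        schema = CohortSchema.from_dict(d["schema"]) if "schema" in d else None
        fp = d.get("fprp", {})
        cfg = cls(
            input_path=input_path,
            schema=schema,
            snp_ids=list(d.get("snps", [])),
            models=list(d.get("models", ["codominant_het", "codominant_hom",
                                         "additive", "dominant", "recessive"])),
            covariates=list(d.get("covariates", ["age", "sex"])),
            stratum_specs=list(d.get("strata", [])),
            fprp=FprpSettings(
                priors=tuple(fp.get("priors", (0.25, 0.1, 0.01, 0.001, 0.0001))),
                or0=float(fp.get("or0", 0.67)),
                threshold=float(fp.get("threshold", 0.2)),
                significance_gate=float(fp.get("significance_gate", 0.05)),
            ),
            output_dir=d.get("output_dir", "results"),
            seed=int(d.get("seed", 0)),
            verbosity=d.get("verbosity", "INFO"),
        )
        if not cfg.snp_ids and schema is not None:
            cfg.snp_ids = [s.snp_id for s in schema.snps]
        if not cfg.models:
            raise ValueError("run config must name at least one genetic model")
        return cfg


__all__ = ["SnpColumn", "CohortSchema", "schema_for", "FprpSettings", "RunConfig"]
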