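"""Cohort data model: subjects, SNP metadata, genotype counting, CSV I/O.

A cohort is a flat per-subject table: case/control status, optional age and
sex, one genotype column per SNP (unordered allele pairs like ``"A/C"``), and
free-form categorical clinical attributes (immunophenotype, risk level, ...).
Genotypes are biallelic; each SNP carries a registry entry naming its major
and minor allele so downstream model encodings are unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: tokens treated as missing on input (configurable per schema)
DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan", ".", "./.")

RESERVED_COLUMNS = ("subject_id", "status", "age_years", "sex")

CASE, CONTROL = "case", "control"


class SchemaError(ValueError):
    """The input file does not match the declared column schema."""


class DataError(ValueError):
    """A cell value violates the cohort contract (bad allele, duplicate id)."""


@dataclass(frozen=True)
class SnpInfo:
    """Registry entry for one biallelic SNP.

    ``allele_major``/``allele_minor`` fix the orientation used by the genetic
    model encodings; ``population_maf`` is optional reference metadata (e.g.
    a HapMap population frequency), not used in computation.
    """

    snp_id: str
    allele_major: str
    allele_minor: str
    chromosome: str = ""
    position: int | None = None
    functional_flags: frozenset[str] = frozenset()
    population_maf: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.allele_major == self.allele_minor:
            raise ValueError(f"{self.snp_id}: major and minor allele must differ")
        for pop, maf in self.population_maf.items():
            if not 0.0 < maf <= 0.5:
                raise ValueError(f"{self.snp_id}: MAF for {pop} must be in (0, 0.5]")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_major, self.allele_minor)

    def genotype_string(self, n_minor: int) -> str:
        """Canonical unordered genotype string for a minor-allele count 0/1/2."""
        pair = sorted(
            [self.allele_major] * (2 - n_minor) + [self.allele_minor] * n_minor
        )
        return f"{pair[0]}/{pair[1]}"


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-SNP 3-genotype counts for one group (cases or controls)."""

    snp_id: str
    group: str
    n_major_hom: int
    n_het: int
    n_minor_hom: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n_major_hom, self.n_het, self.n_minor_hom, self.n_missing) < 0:
            raise ValueError("genotype counts must be nonnegative")

    @property
    def n_typed(self) -> int:
        return self.n_major_hom + self.n_het + self.n_minor_hom

    @property
    def n_total(self) -> int:
        return self.n_typed + self.n_missing

    @property
    def n_major_allele(self) -> int:
        return 2 * self.n_major_hom + self.n_het

    @property
    def n_minor_allele(self) -> int:
        return self.n_het + 2 * self.n_minor_hom

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_major_hom, self.n_het, self.n_minor_hom)


@dataclass
class CohortTable:
    """A case-control cohort: subject table + SNP registry + provenance.

    ``data`` columns: ``subject_id``, ``status`` ("case"/"control"),
    ``age_years`` (float, NaN allowed), ``sex`` ("female"/"male", NaN allowed),
    one column per registered SNP id holding genotype strings or NaN, and the
    attribute columns listed in ``attribute_columns``.
    """

    data: pd.DataFrame
    snps: dict[str, SnpInfo]
    attribute_columns: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        for col in ("subject_id", "status"):
            if col not in df.columns:
                raise SchemaError(f"cohort table lacks required column {col!r}")
        if df["subject_id"].duplicated().any():
            dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise DataError(f"duplicate subject_id values: {dups[:5]}")
        bad_status = set(df["status"].dropna()) - {CASE, CONTROL}
        if bad_status:
            raise DataError(f"unrecognized status labels: {sorted(bad_status)}")
        if df["status"].isna().any():
            raise DataError("status must be present for every subject")
        for snp_id, info in self.snps.items():
            if snp_id not in df.columns:
                continue
            valid = _valid_genotype_strings(info)
            observed = set(df[snp_id].dropna().unique())
            bad = observed - valid
            if bad:
                row = df.loc[df[snp_id].isin(bad)].iloc[0]
                raise DataError(
                    f"subject {row['subject_id']!r}, SNP {snp_id}: genotype "
                    f"{row[snp_id]!r} uses alleles outside "
                    f"{{{info.allele_major}, {info.allele_minor}}}"
                )
        for snp_col in set(df.columns) - set(RESERVED_COLUMNS) - set(self.attribute_columns):
            if snp_col not in self.snps:
                raise SchemaError(
                    f"column {snp_col!r} is neither a registered SNP nor a "
                    "declared attribute"
                )

    @property
    def n_cases(self) -> int:
        return int((self.data["status"] == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.data["status"] == CONTROL).sum())

    def group(self, group: str) -> pd.DataFrame:
        if group not in (CASE, CONTROL):
            raise ValueError(f"group must be 'case' or 'control', got {group!r}")
        return self.data[self.data["status"] == group]

    def subset(self, mask: pd.Series) -> "CohortTable":
        """A new CohortTable restricted to the masked subjects (shared registry)."""
        sub = CohortTable.__new__(CohortTable)
        sub.data = self.data[mask].reset_index(drop=True)
        sub.snps = self.snps
        sub.attribute_columns = self.attribute_columns
        sub.provenance = {**self.provenance, "subset": True}
        return sub


def _valid_genotype_strings(info: SnpInfo) -> set[str]:
    return {info.genotype_string(k) for k in (0, 1, 2)}


def normalize_genotype(value: str, missing_tokens=DEFAULT_MISSING_TOKENS) -> str | float:
    """Canonicalize an ``"X/Y"`` (or ``"X|Y"``) allele pair; NaN for missing.

    Pairs are unordered: ``"C/A"`` and ``"A/C"`` normalize identically.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip()
    if s in missing_tokens:
        return np.nan
    s = s.replace("|", "/")
    parts = s.split("/")
    if len(parts) != 2 or not all(parts):
        raise DataError(f"cannot parse genotype {value!r}: expected 'X/Y'")
    a, b = sorted(p.strip() for p in parts)
    return f"{a}/{b}"


def read_cohort(path, schema) -> CohortTable:
    """Load a delimited per-subject table into a validated :class:`CohortTable`.

    ``schema`` is a :class:`snpcc.config.CohortSchema` (or plain dict with the
    same keys) mapping file columns to roles and declaring each SNP's alleles.
    """
    from .config import CohortSchema

    if isinstance(schema, dict):
        schema = CohortSchema.from_dict(schema)
    raw = pd.read_csv(path, sep=schema.delimiter, dtype=str, keep_default_na=False)
    if schema.status_column not in raw.columns:
        raise SchemaError(
            f"status column {schema.status_column!r} not found in {path} "
            f"(columns: {list(raw.columns)})"
        )
    missing = tuple(schema.missing_tokens)

    df = pd.DataFrame()
    if schema.id_column and schema.id_column in raw.columns:
        df["subject_id"] = raw[schema.id_column]
    else:
        df["subject_id"] = [f"S{i:05d}" for i in range(len(raw))]
    df["status"] = raw[schema.status_column].map(
        lambda s: schema.status_labels.get(str(s).strip(), np.nan)
    )
    if schema.age_column and schema.age_column in raw.columns:
        df["age_years"] = pd.to_numeric(
            raw[schema.age_column].replace(list(missing), np.nan), errors="coerce"
        )
    else:
        df["age_years"] = np.nan
    if schema.sex_column and schema.sex_column in raw.columns:
        df["sex"] = raw[schema.sex_column].map(
            lambda s: schema.sex_labels.get(str(s).strip(), np.nan)
        )
    else:
        df["sex"] = np.nan

    registry: dict[str, SnpInfo] = {}
    for snp in schema.snps:
        col = snp.column or snp.snp_id
        if col not in raw.columns:
            raise SchemaError(f"genotype column {col!r} for {snp.snp_id} not in file")
        registry[snp.snp_id] = snp.info
        df[snp.snp_id] = raw[col].map(lambda v: normalize_genotype(v, missing))

    for attr in schema.attribute_columns:
        if attr in raw.columns:
            df[attr] = raw[attr].replace(list(missing), np.nan)
        else:
            df[attr] = np.nan

    report = {
        "source": str(path),
        "n_rows": len(df),
        "missing_per_column": {
            c: int(df[c].isna().sum()) for c in df.columns if c != "subject_id"
        },
    }
    cohort = CohortTable(
        data=df,
        snps=registry,
        attribute_columns=list(schema.attribute_columns),
        provenance=report,
    )
    log.info("read cohort %s: %d subjects, %d SNPs", path, len(df), len(registry))
    return cohort


def write_cohort(cohort: CohortTable, path) -> None:
    """Write the canonical cohort CSV (the format :func:`read_cohort` expects
    with the default schema produced by :func:`snpcc.config.schema_for`)."""
    cohort.data.to_csv(path, index=False, na_rep="NA")


def genotype_counts(cohort: CohortTable, snp_id: str, group: str) -> GenotypeCounts:
    """Tally the 3 genotype classes for one SNP in one group.

    Missing genotypes go to ``n_missing`` (per-SNP complete-case analysis);
    the three class counts plus ``n_missing`` always sum to the group size.
    """
    if snp_id not in cohort.snps:
        raise KeyError(f"SNP {snp_id!r} not registered in cohort")
    info = cohort.snps[snp_id]
    sub = cohort.group(group)
    geno = sub[snp_id]
    counts = geno.value_counts()
    return GenotypeCounts(
        snp_id=snp_id,
        group=group,
        n_major_hom=int(counts.get(info.genotype_string(0), 0)),
        n_het=int(counts.get(info.genotype_string(1), 0)),
        n_minor_hom=int(counts.get(info.genotype_string(2), 0)),
        n_missing=int(geno.isna().sum()),
    )


def minor_allele(counts: GenotypeCounts, info: SnpInfo) -> tuple[str, float]:
    """Observed minor allele and its frequency from (control) genotype counts.

    If the registry's nominal minor allele has frequency > 0.5 in the data,
    the labels are swapped (a warning is logged) and the swapped frequency is
    returned, so the result is always the actually-less-common allele.
    """
    if counts.n_typed == 0:
        raise ValueError(f"{counts.snp_id}: all genotypes missing, MAF undefined")
    maf = counts.n_minor_allele / (2 * counts.n_typed)
    allele = info.allele_minor
    if maf > 0.5:
        log.warning(
            "%s: nominal minor allele %s has frequency %.3f > 0.5; swapping labels",
            counts.snp_id, allele, maf,
        )
        allele, maf = info.allele_major, 1.0 - maf
    return allele, maf


def genotype_class(cohort: CohortTable, snp_id: str) -> pd.Series:
    """Minor-allele count per subject (0/1/2, NaN for missing) for one SNP."""
    info = cohort.snps[snp_id]
    mapping = {info.genotype_string(k): float(k) for k in (0, 1, 2)}
    return cohort.data[snp_id].map(mapping)


def read_vcf_genotypes(vcf_path, snp_ids=None) -> tuple[pd.DataFrame, dict[str, SnpInfo]]:
    """Extract biallelic GT calls from a VCF into a sample-by-SNP table.

    Phased and unphased separators are both accepted; REF is taken as the
    major allele and ALT as the minor (downstream :func:`minor_allele` will
    flag and swap if the data disagree). Requires :mod:`pysam`.
    """
    import pysam

    want = set(snp_ids) if snp_ids is not None else None
    registry: dict[str, SnpInfo] = {}
    rows: dict[str, dict[str, object]] = {}
    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.id is None or (want is not None and rec.id not in want):
                continue
            if rec.alts is None or len(rec.alts) != 1:
                continue  # biallelic records only
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            registry[rec.id] = SnpInfo(
                snp_id=rec.id,
                allele_major=ref,
                allele_minor=alt,
                chromosome=str(rec.chrom),
                position=int(rec.pos),
            )
            alleles = (ref, alt)
            col = {}
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt) or len(gt) != 2:
                    col[sample] = np.nan
                else:
                    pair = sorted(alleles[a] for a in gt)
                    col[sample] = f"{pair[0]}/{pair[1]}"
            rows[rec.id] = col
    table = pd.DataFrame(rows)
    table.index.name = "subject_id"
    return table, registry


def merge_vcf_cohort(vcf_path, covariates_path, schema) -> CohortTable:
    """Build a cohort from VCF genotypes merged with a covariate CSV by sample id."""
    from .config import CohortSchema

    if isinstance(schema, dict):
        schema = CohortSchema.from_dict(schema)
    geno, registry = read_vcf_genotypes(vcf_path, [s.snp_id for s in schema.snps] or None)
    covars = pd.read_csv(covariates_path, dtype=str, keep_default_na=False)
    id_col = schema.id_column or "subject_id"
    if id_col not in covars.columns:
        raise SchemaError(f"covariate file lacks id column {id_col!r}")
    covars = covars.set_index(id_col)
    merged = covars.join(geno, how="inner").reset_index(names=id_col)

    missing = tuple(schema.missing_tokens)
    df = pd.DataFrame({"subject_id": merged[id_col]})
    df["status"] = merged[schema.status_column].map(
        lambda s: schema.status_labels.get(str(s).strip(), np.nan)
    )
    df["age_years"] = (
        pd.to_numeric(merged[schema.age_column], errors="coerce")
        if schema.age_column and schema.age_column in merged.columns
        else np.nan
    )
    df["sex"] = (
        merged[schema.sex_column].map(lambda s: schema.sex_labels.get(str(s).strip(), np.nan))
        if schema.sex_column and schema.sex_column in merged.columns
        else np.nan
    )
    for snp_id in registry:
        df[snp_id] = merged[snp_id]
    for attr in schema.attribute_columns:
        df[attr] = merged[attr].replace(list(missing), np.nan) if attr in merged.columns else np.nan
    return CohortTable(
        data=df,
        snps=registry,
        attribute_columns=list(schema.attribute_columns),
        provenance={"source": str(vcf_path), "covariates": str(covariates_path)},
    )


__all__ = [
    "SnpInfo", "GenotypeCounts", "CohortTable", "SchemaError", "DataError",
    "read_cohort", "write_cohort", "genotype_counts", "minor_allele",
    "genotype_class", "normalize_genotype", "read_vcf_genotypes",
    "merge_vcf_cohort", "CASE", "CONTROL",
]
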