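"""Subgroup and stratified association scans.

Two stratification designs are supported:

* ``within_stratum`` — both cases and controls are filtered to the stratum
  level (valid for variables defined on everyone: age band, sex);
* ``subtype_cases_vs_all_controls`` — cases are filtered to a case-only
  clinical subtype (immunophenotype, fusion type, risk level, karyotype,
  blood-count category, relapse, MRD level) and compared against the full
  control group, which is therefore identical across the rows of one
  variable.

The default contrast is the dominant model (minor-allele carriers vs
major-allele homozygotes); covariates that are degenerate within a stratum
(e.g. sex inside a sex stratum) are dropped automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CASE, CONTROL, CohortTable, genotype_counts
from .stats import AssociationResult, _adjusted_result, _crude_result

WITHIN = "within_stratum"
SUBTYPE = "subtype_cases_vs_all_controls"


@dataclass(frozen=True)
class StratumSpec:
    """One stratum: a variable, a level, and the comparison design."""

    variable: str
    level: str
    design: str = SUBTYPE
    model: str = "dominant"
    covariates: tuple = ("age", "sex")

    def __post_init__(self) -> None:
        if self.design not in (WITHIN, SUBTYPE):
            raise ValueError(f"unknown stratification design {self.design!r}")

    @property
    def label(self) -> str:
        return f"{self.variable}={self.level}"


@dataclass
class StratumResult:
    spec: StratumSpec
    n_case_ref: int
    n_case_exposed: int
    n_ctrl_ref: int
    n_ctrl_exposed: int
    crude: AssociationResult | None = None
    adjusted: AssociationResult | None = None


def _stratum_column(cohort: CohortTable, variable: str) -> pd.Series:
    df = cohort.data
    if variable == "age_band" and "age_band" not in df.columns:
        # derive <10 / >=10 banding from continuous age
        return df["age_years"].map(
            lambda a: np.nan if pd.isna(a) else ("<10" if a < 10 else ">=10")
        )
    if variable == "sex":
        return df["sex"]
    if variable in df.columns:
        return df[variable]
    available = sorted(set(cohort.attribute_columns) | {"sex", "age_band"})
    raise KeyError(f"unknown stratification variable {variable!r}; available: {available}")


def build_strata(cohort: CohortTable, specs) -> list[tuple[pd.Series, pd.Series, StratumSpec]]:
    """Boolean case/control masks for each stratum spec.

    Subjects with a missing stratum value are excluded from that stratum;
    under the subtype design the control mask is the full control group.
    """
    out = []
    is_case = cohort.data["status"] == CASE
    is_ctrl = cohort.data["status"] == CONTROL
    for spec in specs:
        col = _stratum_column(cohort, spec.variable)
        at_level = col == spec.level
        case_mask = is_case & at_level
        ctrl_mask = (is_ctrl & at_level) if spec.design == WITHIN else is_ctrl
        out.append((case_mask, ctrl_mask, spec))
    return out


def stratified_scan(
    cohort: CohortTable,
    snp_id: str,
    specs,
    covariates=("age", "sex"),
    haldane: bool = False,
) -> list[StratumResult]:
    """Per-stratum crude and adjusted association results for one SNP.

    Each spec yields one row; strata with an empty design cell are kept in
    the output flagged non-estimable so the table shape is preserved.
    """
    results = []
    for case_mask, ctrl_mask, spec in build_strata(cohort, specs):
        sub = cohort.subset(case_mask | ctrl_mask)
        cc = genotype_counts(sub, snp_id, CASE)
        ct = genotype_counts(sub, snp_id, CONTROL)
        crude = _crude_result(sub, snp_id, spec.model, cc, ct, haldane)
        covs = spec.covariates if spec.covariates else covariates
        adjusted = _adjusted_result(sub, snp_id, spec.model, covs, cc, ct) if covs else None
        exposed_case, ref_case = _contrast_cells(cc, spec.model)
        exposed_ctrl, ref_ctrl = _contrast_cells(ct, spec.model)
        results.append(
            StratumResult(
                spec=spec,
                n_case_ref=ref_case, n_case_exposed=exposed_case,
                n_ctrl_ref=ref_ctrl, n_ctrl_exposed=exposed_ctrl,
                crude=crude, adjusted=adjusted,
            )
        )
    return results


def _contrast_cells(counts, model: str) -> tuple[int, int]:
    from .stats import MODEL_CODING

    coding = MODEL_CODING["dominant" if model == "additive" else model]
    tup = counts.as_tuple()
    exposed = sum(tup[k] for k, v in coding.items() if v not in (None, 0))
    ref = sum(tup[k] for k, v in coding.items() if v == 0)
    return exposed, ref


def categorize_lab_value(value: float, low: float, high: float) -> str | float:
    """Map a raw laboratory value to Lower / Normal / Higher against a
    reference range (e.g. WBC 5-12 x10^9/L, platelets 140-440 x10^9/L)."""
    if pd.isna(value):
        return np.nan
    if value < low:
        return "Lower"
    if value > high:
        return "Higher"
    return "Normal"


#: conventional pediatric reference ranges used for blood-count strata
LAB_REFERENCE_RANGES = {
    "wbc": (5.0, 12.0),        # 10^9 cells / L
    "platelet": (140.0, 440.0),  # 10^9 cells / L
}


def specs_for_variable(
    cohort: CohortTable,
    variable: str,
    design: str = SUBTYPE,
    model: str = "dominant",
    covariates: tuple = ("age", "sex"),
) -> list[StratumSpec]:
    """One spec per observed level of a variable, in sorted order."""
    col = _stratum_column(cohort, variable)
    return [
        StratumSpec(variable=variable, level=level, design=design,
                    model=model, covariates=covariates)
        for level in sorted(col.dropna().unique())
    ]


__all__ = [
    "StratumSpec", "StratumResult", "WITHIN", "SUBTYPE", "build_strata",
    "stratified_scan", "categorize_lab_value", "LAB_REFERENCE_RANGES",
    "specs_for_variable",
]
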