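"""Statistical core: HWE goodness of fit, Pearson chi-square, odds ratios
with Wald intervals, genetic-model encodings, and logistic regression for
crude and covariate-adjusted effect estimates.

Conventions fixed across the package:

* No Yates continuity correction in any chi-square test.
* Wald 95% intervals on the log-odds scale with z = 1.959964.
* Crude odds ratios for 2-level contrasts (codominant, dominant, recessive)
  come from the closed-form cross-product; the additive (per-allele trend)
  crude OR is the exponentiated slope of a 0/1/2-coded logistic fit. The two
  routes coincide for binary predictors at these margins.
* Tables with a zero cell are reported as non-estimable rather than patched,
  unless the Haldane-Anscombe +0.5 correction is explicitly requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import CASE, CohortTable, GenotypeCounts, genotype_class

Z95 = 1.959964  # two-sided 95% normal quantile, as conventionally rounded

GENETIC_MODELS = ("codominant_het", "codominant_hom", "additive", "dominant", "recessive")

#: minor-allele-count (0/1/2) -> predictor value; None = excluded from contrast
MODEL_CODING: dict[str, dict[int, float | None]] = {
    "codominant_het": {0: 0, 1: 1, 2: None},
    "codominant_hom": {0: 0, 1: None, 2: 1},
    "additive": {0: 0, 1: 1, 2: 2},
    "dominant": {0: 0, 1: 1, 2: 1},
    "recessive": {0: 0, 1: 0, 2: 1},
}


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str


@dataclass
class AssociationResult:
    """One genetic-model contrast for one SNP: OR, 95% CI, p, provenance."""

    snp_id: str
    model: str
    or_estimate: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_value: float = np.nan
    distribution_p: float | None = None  # Pearson chi-square p of the contrast table
    cells: dict = field(default_factory=dict)
    adjusted: bool = False
    covariates: tuple = ()
    estimable: bool = True
    reason: str = ""

    @property
    def label(self) -> str:
        tag = "adjusted" if self.adjusted else "crude"
        return f"{self.snp_id} {self.model} ({tag})"


def hwe_chisq_test(counts: GenotypeCounts) -> TestResult:
    """Hardy-Weinberg goodness-of-fit chi-square (1 df, no correction).

    Expected genotype counts n*p^2, 2npq, n*q^2 are formed from the observed
    allele frequency; conventionally run on controls, where departure flags
    genotyping error or hidden structure.
    """
    n = counts.n_typed
    if n == 0:
        raise ValueError(f"{counts.snp_id}: no typed genotypes, HWE undefined")
    p = counts.n_major_allele / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        raise ValueError(f"{counts.snp_id}: monomorphic, HWE undefined")
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array(counts.as_tuple(), dtype=float)
    statistic = float(((observed - expected) ** 2 / expected).sum())
    return TestResult(
        statistic=statistic,
        df=1,
        p_value=float(sps.chi2.sf(statistic, 1)),
        method="HWE goodness-of-fit chi-square",
    )


def pearson_chi2(table) -> TestResult:
    """Two-sided Pearson chi-square on an r x k contingency table (no Yates)."""
    arr = np.asarray(table, dtype=float)
    if (arr < 0).any():
        raise ValueError("contingency cells must be nonnegative")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("contingency table has a zero margin")
    res = sps.chi2_contingency(arr, correction=False)
    return TestResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        method="Pearson chi-square",
    )


def odds_ratio_2x2(
    n_case_exposed: int,
    n_case_ref: int,
    n_ctrl_exposed: int,
    n_ctrl_ref: int,
    *,
    snp_id: str = "",
    model: str = "2x2",
    haldane: bool = False,
) -> AssociationResult:
    """Closed-form odds ratio with Wald 95% CI and two-sided Wald p.

    A zero cell makes the cross-product degenerate; the result is then
    flagged non-estimable unless ``haldane=True`` adds 0.5 to every cell.
    """
    cells = dict(
        n_case_exposed=n_case_exposed, n_case_ref=n_case_ref,
        n_ctrl_exposed=n_ctrl_exposed, n_ctrl_ref=n_ctrl_ref,
    )
    if min(cells.values()) < 0:
        raise ValueError("cell counts must be nonnegative")
    a, b, c, d = (float(v) for v in cells.values())
    if min(a, b, c, d) == 0:
        if not haldane:
            return AssociationResult(
                snp_id=snp_id, model=model, cells=cells, estimable=False,
                reason="zero cell in 2x2 table",
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    return AssociationResult(
        snp_id=snp_id, model=model,
        or_estimate=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        p_value=float(2 * sps.norm.sf(abs(z))),
        cells=cells,
    )


def encode_genotypes(
    cohort: CohortTable, snp_id: str, model: str
) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    """Predictor and outcome vectors for one SNP under one genetic model.

    Subjects with a missing genotype — and, for codominant contrasts, the
    excluded genotype class — are dropped. Returns ``(x, y, kept_mask)`` with
    outcome 1 = case, 0 = control.
    """
    if model not in MODEL_CODING:
        raise ValueError(f"unknown genetic model {model!r}; choose from {GENETIC_MODELS}")
    classes = genotype_class(cohort, snp_id)
    coding = MODEL_CODING[model]
    x = classes.map({k: v for k, v in coding.items() if v is not None})
    keep = x.notna()
    y = (cohort.data["status"] == CASE).astype(float)
    return x[keep].to_numpy(float), y[keep].to_numpy(float), keep


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit: coefficients, SEs, Wald inference."""

    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    cov: np.ndarray
    converged: bool
    estimable: bool
    reason: str = ""
    names: tuple = ()

    def or_ci(self, idx: int = 1) -> tuple[float, float, float, float]:
        """(OR, lo, hi, p) for coefficient ``idx`` on the odds-ratio scale."""
        b, se = self.params[idx], self.bse[idx]
        return (
            float(np.exp(b)),
            float(np.exp(b - Z95 * se)),
            float(np.exp(b + Z95 * se)),
            float(self.pvalues[idx]),
        )


# Wald SEs beyond this signal (quasi-)separation: the MLE is drifting to
# infinity and the reported interval would be meaningless.
_SE_SANITY_LIMIT = 50.0


def fit_logistic(X: np.ndarray, y: np.ndarray, names: tuple = ()) -> LogisticFit:
    """Fit a binary logistic model by Newton/IRLS maximum likelihood.

    ``X`` must already contain the intercept column. Non-convergence,
    a singular information matrix, or separation yields ``estimable=False``
    with a diagnostic instead of an exception.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    k = X.shape[1]
    bad = lambda reason: LogisticFit(
        params=np.full(k, np.nan), bse=np.full(k, np.nan),
        pvalues=np.full(k, np.nan), cov=np.full((k, k), np.nan),
        converged=False, estimable=False, reason=reason, names=names,
    )
    if X.shape[0] <= k:
        return bad(f"n={X.shape[0]} too small for {k} parameters")
    variances = X.var(axis=0)
    if (variances[1:] == 0).any() if k > 1 else False:
        return bad("constant predictor column")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
    except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
        return bad(f"fit failed: {exc}")
    bse = np.asarray(res.bse, dtype=float)
    if not res.mle_retvals.get("converged", False):
        return bad("IRLS did not converge in 100 iterations")
    if not np.all(np.isfinite(bse)) or np.nanmax(bse) > _SE_SANITY_LIMIT:
        return bad("separation suspected (unbounded standard error)")
    return LogisticFit(
        params=np.asarray(res.params, dtype=float),
        bse=bse,
        pvalues=np.asarray(res.pvalues, dtype=float),
        cov=np.asarray(res.cov_params(), dtype=float),
        converged=True,
        estimable=True,
        names=names,
    )


def _covariate_matrix(
    cohort: CohortTable, keep: pd.Series, covariates
) -> tuple[np.ndarray, pd.Series, tuple]:
    """Covariate columns for the kept subjects; drops rows with missing values
    and covariates that are degenerate (constant) on the analysis subset."""
    df = cohort.data
    cols: list[pd.Series] = []
    names: list[str] = []
    for cov in covariates:
        if cov == "age":
            col = df["age_years"]
        elif cov == "age_band":
            col = df["age_years"].map(lambda a: np.nan if pd.isna(a) else float(a >= 10))
            if df["age_years"].isna().all() and "age_band" in df.columns:
                col = df["age_band"].map({"<10": 0.0, ">=10": 1.0})
        elif cov == "sex":
            col = df["sex"].map({"female": 0.0, "male": 1.0})
        elif cov in df.columns:
            col = pd.to_numeric(df[cov], errors="coerce")
        else:
            raise KeyError(f"covariate {cov!r} not available on subjects")
        cols.append(col)
        names.append(cov)
    if not cols:
        return np.empty((int(keep.sum()), 0)), keep, ()
    cmat = pd.concat(cols, axis=1)
    keep = keep & cmat.notna().all(axis=1)
    sub = cmat[keep]
    nondegenerate = [i for i in range(sub.shape[1]) if sub.iloc[:, i].nunique() > 1]
    kept_names = tuple(names[i] for i in nondegenerate)
    return sub.iloc[:, nondegenerate].to_numpy(float), keep, kept_names


def _crude_result(cohort, snp_id, model, counts_case, counts_ctrl, haldane=False):
    coding = MODEL_CODING[model]
    exposed = [k for k, v in coding.items() if v not in (None, 0)]
    ref = [k for k, v in coding.items() if v == 0]
    tup_case, tup_ctrl = counts_case.as_tuple(), counts_ctrl.as_tuple()
    cells_table = [
        [sum(tup_case[k] for k in exposed), sum(tup_case[k] for k in ref)],
        [sum(tup_ctrl[k] for k in exposed), sum(tup_ctrl[k] for k in ref)],
    ]
    if model == "additive":
        x, y, _ = encode_genotypes(cohort, snp_id, model)
        if len(x) == 0 or len(np.unique(x)) < 2:
            return AssociationResult(
                snp_id=snp_id, model=model, estimable=False,
                reason="no genotype variation", cells={"case": tup_case, "control": tup_ctrl},
            )
        fit = fit_logistic(sm.add_constant(x), y, names=("const", model))
        result = AssociationResult(
            snp_id=snp_id, model=model,
            cells={"case": tup_case, "control": tup_ctrl},
            estimable=fit.estimable, reason=fit.reason,
        )
        if fit.estimable:
            result.or_estimate, result.ci_low, result.ci_high, result.p_value = fit.or_ci(1)
        return result
    res = odds_ratio_2x2(
        cells_table[0][0], cells_table[0][1], cells_table[1][0], cells_table[1][1],
        snp_id=snp_id, model=model, haldane=haldane,
    )
    if all(min(row) > 0 for row in cells_table):
        res.distribution_p = pearson_chi2(cells_table).p_value
    return res


def association_scan(
    cohort: CohortTable,
    snp_id: str,
    models=GENETIC_MODELS,
    covariates=("age", "sex"),
    haldane: bool = False,
) -> tuple[list[AssociationResult], TestResult | None]:
    """Per-model crude and adjusted association results for one SNP.

    Returns the list of :class:`AssociationResult` (crude then adjusted per
    model) and, when all six genotype cells are positive, the overall 2x3
    genotype-distribution Pearson chi-square.
    """
    from .cohort import genotype_counts

    counts_case = genotype_counts(cohort, snp_id, "case")
    counts_ctrl = genotype_counts(cohort, snp_id, "control")
    genotype_test = None
    table = np.array([counts_case.as_tuple(), counts_ctrl.as_tuple()])
    nonzero_cols = table.sum(axis=0) > 0
    if nonzero_cols.sum() >= 2 and table.sum(axis=1).min() > 0:
        genotype_test = pearson_chi2(table[:, nonzero_cols])

    results: list[AssociationResult] = []
    for model in models:
        crude = _crude_result(cohort, snp_id, model, counts_case, counts_ctrl, haldane)
        results.append(crude)
        if covariates:
            results.append(_adjusted_result(cohort, snp_id, model, covariates,
                                            counts_case, counts_ctrl))
    return results, genotype_test


def _adjusted_result(cohort, snp_id, model, covariates, counts_case, counts_ctrl):
    x, y_all, keep = encode_genotypes(cohort, snp_id, model)
    cmat, keep, used = _covariate_matrix(cohort, keep, covariates)
    x = _reencode(cohort, snp_id, model, keep)
    y = (cohort.data.loc[keep, "status"] == CASE).to_numpy(float)
    result = AssociationResult(
        snp_id=snp_id, model=model, adjusted=True, covariates=used,
        cells={"case": counts_case.as_tuple(), "control": counts_ctrl.as_tuple()},
    )
    if len(x) == 0 or len(np.unique(x)) < 2:
        result.estimable, result.reason = False, "no genotype variation"
        return result
    X = np.column_stack([np.ones(len(x)), x, cmat])
    fit = fit_logistic(X, y, names=("const", model, *used))
    result.estimable, result.reason = fit.estimable, fit.reason
    if fit.estimable:
        result.or_estimate, result.ci_low, result.ci_high, result.p_value = fit.or_ci(1)
    return result


def _reencode(cohort, snp_id, model, keep) -> np.ndarray:
    classes = genotype_class(cohort, snp_id)
    coding = {k: v for k, v in MODEL_CODING[model].items() if v is not None}
    return classes.map(coding)[keep].to_numpy(float)


__all__ = [
    "TestResult", "AssociationResult", "LogisticFit", "GENETIC_MODELS",
    "MODEL_CODING", "Z95", "hwe_chisq_test", "pearson_chi2", "odds_ratio_2x2",
    "encode_genotypes", "fit_logistic", "association_scan",
]
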