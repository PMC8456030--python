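"""Orchestration: run the whole analysis from a config and emit report tables.

Outputs one TSV per analysis table (demographics, per-SNP association scan,
stratified scan, FPRP), a flat machine-readable ``results.txt`` with full
precision, and a plain-text run log. Human tables round to conventional
precisions (OR/CI two decimals, p three, HWE four, FPRP three); the
machine-readable file keeps full precision.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CASE, CONTROL, CohortTable, genotype_counts, read_cohort
from .config import RunConfig
from .fprp import fprp_table
from .stats import TestResult, association_scan, hwe_chisq_test, pearson_chi2
from .stratify import StratumSpec, stratified_scan

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; partial outputs have been removed."""


def summarize_demographics(cohort: CohortTable, variables=None) -> pd.DataFrame:
    """Per-variable case/control level counts, percentages, and a two-sided
    Pearson chi-square p where the variable is recorded in both groups."""
    df = cohort.data
    if variables is None:
        variables = list(dict.fromkeys(["age_band", "sex", *cohort.attribute_columns]))
    rows = []
    for var in variables:
        if var == "age_band" and "age_band" not in df.columns:
            col = df["age_years"].map(
                lambda a: np.nan if pd.isna(a) else ("<10" if a < 10 else ">=10")
            )
        elif var in df.columns:
            col = df[var]
        else:
            continue
        levels = [lv for lv in col.dropna().unique()]
        levels.sort(key=str)
        counts = {
            g: col[df["status"] == g].value_counts() for g in (CASE, CONTROL)
        }
        n_case = int(counts[CASE].sum())
        n_ctrl = int(counts[CONTROL].sum())
        p = np.nan
        if n_case > 0 and n_ctrl > 0 and len(levels) >= 2:
            table = [[int(counts[g].get(lv, 0)) for lv in levels] for g in (CASE, CONTROL)]
            if all(sum(r) > 0 for r in table) and all(sum(c) > 0 for c in zip(*table)):
                p = pearson_chi2(table).p_value
        for lv in levels:
            c, k = int(counts[CASE].get(lv, 0)), int(counts[CONTROL].get(lv, 0))
            rows.append({
                "variable": var, "level": lv,
                "n_cases": c,
                "pct_cases": 100 * c / n_case if n_case else np.nan,
                "n_controls": k,
                "pct_controls": 100 * k / n_ctrl if n_ctrl else np.nan,
                "p_value": p,
            })
    return pd.DataFrame(rows)


def _association_frame(results, genotype_tests) -> pd.DataFrame:
    rows = []
    for res in results:
        rows.append({
            "snp_id": res.snp_id,
            "model": res.model,
            "adjusted": res.adjusted,
            "covariates": "+".join(res.covariates),
            "or": res.or_estimate,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "p_value": res.p_value,
            "distribution_p": res.distribution_p,
            "estimable": res.estimable,
            "reason": res.reason,
            "genotype_p": getattr(genotype_tests.get(res.snp_id), "p_value", np.nan),
        })
    return pd.DataFrame(rows)


def _stratum_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        for which, res in (("crude", r.crude), ("adjusted", r.adjusted)):
            if res is None:
                continue
            rows.append({
                "variable": r.spec.variable, "level": r.spec.level,
                "design": r.spec.design, "model": r.spec.model, "kind": which,
                "case_ref": r.n_case_ref, "case_exposed": r.n_case_exposed,
                "ctrl_ref": r.n_ctrl_ref, "ctrl_exposed": r.n_ctrl_exposed,
                "or": res.or_estimate, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "p_value": res.p_value, "estimable": res.estimable, "reason": res.reason,
            })
    return pd.DataFrame(rows)


def _fprp_frame(rows) -> pd.DataFrame:
    out = []
    for r in rows:
        record = {
            "label": r.label,
            "or": round(r.or_estimate, 2),
            "ci": f"{r.ci_low:.2f}-{r.ci_high:.2f}",
            "p": round(r.alpha, 3),
            "power": round(r.power, 3),
        }
        for pi in r.priors:
            record[f"fprp_{pi:g}"] = round(r.fprp_values[pi], 3)
            record[f"noteworthy_{pi:g}"] = r.noteworthy[pi]
        out.append(record)
    return pd.DataFrame(out)


def run_pipeline(config: RunConfig, cohort: CohortTable | None = None) -> dict:
    """Run demographics, HWE, association, stratification and FPRP stages.

    Returns the report bundle as a dict of DataFrames / objects and writes
    the TSV tables plus ``results.txt`` and ``run.log`` to
    ``config.output_dir``. Any stage failure removes partial outputs and
    raises :class:`PipelineError` tagged with the stage name.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = []
    t0 = time.time()

    def stage(name):
        log_lines.append(f"[{time.time() - t0:8.2f}s] stage {name}")
        log.info("stage %s", name)

    try:
        stage("load")
        if cohort is None:
            if config.input_path is None or config.schema is None:
                raise ValueError("no cohort given and no input/schema configured")
            cohort = read_cohort(config.input_path, config.schema)
        log_lines.append(
            f"  cohort: {cohort.n_cases} cases / {cohort.n_controls} controls, "
            f"{len(cohort.snps)} SNPs"
        )

        stage("demographics")
        demo = summarize_demographics(cohort)
        _write(demo, outdir / "demographics.tsv", written,
               {"pct_cases": 2, "pct_controls": 2, "p_value": 3})

        stage("hwe")
        hwe_rows = []
        for snp_id in config.snp_ids:
            try:
                res = hwe_chisq_test(genotype_counts(cohort, snp_id, CONTROL))
                hwe_rows.append({"snp_id": snp_id, "statistic": res.statistic,
                                 "df": res.df, "p_value": res.p_value})
            except ValueError as exc:
                log_lines.append(f"  HWE {snp_id}: {exc}")
                hwe_rows.append({"snp_id": snp_id, "statistic": np.nan,
                                 "df": 1, "p_value": np.nan})
        hwe = pd.DataFrame(hwe_rows)
        _write(hwe, outdir / "hwe_controls.tsv", written, {"statistic": 4, "p_value": 4})

        stage("association")
        all_results, genotype_tests = [], {}
        for snp_id in config.snp_ids:
            results, gtest = association_scan(
                cohort, snp_id, models=config.models, covariates=config.covariates
            )
            all_results.extend(results)
            genotype_tests[snp_id] = gtest
            for res in results:
                if not res.estimable:
                    log_lines.append(f"  non-estimable: {res.label}: {res.reason}")
        assoc = _association_frame(all_results, genotype_tests)
        _write(assoc, outdir / "association.tsv", written,
               {"or": 2, "ci_low": 2, "ci_high": 2, "p_value": 3,
                "distribution_p": 3, "genotype_p": 3})

        stage("stratification")
        strat_results = []
        if config.stratum_specs:
            specs = [StratumSpec(**{**s, "covariates": tuple(s.get("covariates",
                                 config.covariates))}) for s in config.stratum_specs]
            for snp_id in config.snp_ids:
                per_snp = stratified_scan(cohort, snp_id, specs,
                                          covariates=config.covariates)
                strat_results.extend(per_snp)
        strat = _stratum_frame(strat_results)
        _write(strat, outdir / "stratification.tsv", written,
               {"or": 2, "ci_low": 2, "ci_high": 2, "p_value": 3})

        stage("fprp")
        findings = [
            r for r in all_results
            if not r.adjusted and r.estimable and r.p_value < config.fprp.significance_gate
        ]
        fprp_rows = fprp_table(
            findings, priors=config.fprp.priors, or0=config.fprp.or0,
            threshold=config.fprp.threshold,
            significance_gate=config.fprp.significance_gate,
        )
        fprp_df = _fprp_frame(fprp_rows)
        _write(fprp_df, outdir / "fprp.tsv", written, {})

        stage("write-results")
        _write_flat_results(outdir / "results.txt", written, demo, hwe, assoc,
                            strat, fprp_rows)

        settings = {
            "version": __version__,
            "seed": config.seed,
            "models": ",".join(config.models),
            "covariates": ",".join(config.covariates),
            "fprp_or0": config.fprp.or0,
            "fprp_priors": ",".join(str(p) for p in config.fprp.priors),
            "fprp_threshold": config.fprp.threshold,
            "significance_gate": config.fprp.significance_gate,
            "continuity_correction": "none",
            "zero_cell_policy": "non-estimable (no Haldane correction)",
        }
        log_path = outdir / "run.log"
        with open(log_path, "w") as fh:
            for k, v in settings.items():
                fh.write(f"# {k} = {v}\n")
            fh.write("\n".join(log_lines) + "\n")
            fh.write(f"[{time.time() - t0:8.2f}s] done\n")
        written.append(log_path)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        stage_name = log_lines[-1].split("stage ")[-1] if log_lines else "load"
        raise PipelineError(f"stage {stage_name!r} failed: {exc}") from exc

    return {
        "cohort": cohort, "demographics": demo, "hwe": hwe,
        "association": assoc, "association_results": all_results,
        "genotype_tests": genotype_tests, "stratification": strat,
        "fprp": fprp_df, "fprp_rows": fprp_rows, "outputs": written,
    }


def _write(frame: pd.DataFrame, path: Path, written: list, rounding: dict) -> None:
    out = frame.copy()
    for col, ndig in rounding.items():
        if col in out.columns:
            out[col] = out[col].astype(float).round(ndig)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
    written.append(path)


def _write_flat_results(path: Path, written: list, demo, hwe, assoc, strat, fprp_rows):
    """Flat key=value results at full precision, deterministic ordering."""
    lines = []
    for _, row in hwe.iterrows():
        lines.append(f"hwe.{row['snp_id']}.p = {row['p_value']!r}")
    for _, row in assoc.iterrows():
        tag = "adjusted" if row["adjusted"] else "crude"
        key = f"assoc.{row['snp_id']}.{row['model']}.{tag}"
        lines.append(f"{key}.or = {row['or']!r}")
        lines.append(f"{key}.ci = ({row['ci_low']!r}, {row['ci_high']!r})")
        lines.append(f"{key}.p = {row['p_value']!r}")
    for _, row in demo.iterrows():
        lines.append(
            f"demo.{row['variable']}.{row['level']}.p = {row['p_value']!r}"
        )
    for _, row in strat.iterrows():
        key = f"stratum.{row['variable']}.{row['level']}.{row['kind']}"
        lines.append(f"{key}.or = {row['or']!r}")
        lines.append(f"{key}.p = {row['p_value']!r}")
    for r in fprp_rows:
        key = f"fprp.{r.label.replace(' ', '_')}"
        lines.append(f"{key}.power = {r.power!r}")
        for pi in r.priors:
            lines.append(f"{key}.pi_{pi:g} = {r.fprp_values[pi]!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    written.append(path)


__all__ = ["run_pipeline", "summarize_demographics", "PipelineError"]
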