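"""HWE, Pearson chi-square, odds ratios, model encodings, logistic fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import statsmodels.api as sm

from snpcc.cohort import GenotypeCounts, genotype_counts
from snpcc.stats import (
    MODEL_CODING,
    association_scan,
    encode_genotypes,
    fit_logistic,
    hwe_chisq_test,
    odds_ratio_2x2,
    pearson_chi2,
)


def _counts(c0, c1, c2, group="control", snp="rs"):
    return GenotypeCounts(snp, group, c0, c1, c2)


class TestHwe:
    def test_exact_hwe_proportions_give_zero_statistic(self):
        res = hwe_chisq_test(_counts(25, 50, 25))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    @pytest.mark.parametrize("cells,expected_p", [
        ((656, 292, 21), 0.0797),
        ((798, 170, 3), 0.0527),
    ])
    def test_published_control_counts(self, cells, expected_p):
        assert hwe_chisq_test(_counts(*cells)).p_value == pytest.approx(expected_p, abs=5e-5)

    def test_monomorphic_is_undefined(self):
        with pytest.raises(ValueError, match="monomorphic"):
            hwe_chisq_test(_counts(100, 0, 0))
        with pytest.raises(ValueError, match="undefined"):
            hwe_chisq_test(_counts(0, 0, 0))

    @given(st.tuples(st.integers(1, 500), st.integers(1, 500), st.integers(1, 500)))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_allele_labelling(self, cells):
        forward = hwe_chisq_test(_counts(*cells))
        flipped = hwe_chisq_test(_counts(*cells[::-1]))
        assert forward.statistic == pytest.approx(flipped.statistic, rel=1e-9)


class TestPearson:
    def test_proportional_rows_give_zero_statistic(self):
        res = pearson_chi2([[10, 20, 30], [20, 40, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi2([[0, 0], [5, 5]])

    def test_swapping_groups_leaves_p_unchanged(self):
        a = pearson_chi2([[30, 70], [45, 55]])
        b = pearson_chi2([[45, 55], [30, 70]])
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)


class TestOddsRatio2x2:
    def test_published_het_contrast(self):
        res = odds_ratio_2x2(165, 502, 292, 656)
        assert res.or_estimate == pytest.approx(0.74, abs=5e-3)
        assert res.ci_low == pytest.approx(0.59, abs=5e-3)
        assert res.ci_high == pytest.approx(0.92, abs=5e-3)

    def test_symmetric_table_is_null(self):
        res = odds_ratio_2x2(10, 10, 10, 10)
        assert res.or_estimate == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_zero_cell_not_estimable_by_default(self):
        res = odds_ratio_2x2(0, 10, 5, 5)
        assert not res.estimable and "zero cell" in res.reason

    def test_haldane_correction_recovers_estimate(self):
        res = odds_ratio_2x2(0, 10, 5, 5, haldane=True)
        assert res.estimable
        assert res.or_estimate == pytest.approx((0.5 * 5.5) / (10.5 * 5.5), rel=1e-9)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(-1, 10, 5, 5)

    @given(st.tuples(*(st.integers(5, 300) for _ in range(4))))
    @settings(max_examples=60, deadline=None)
    def test_swapping_case_control_inverts_or(self, cells):
        a, b, c, d = cells
        fwd = odds_ratio_2x2(a, b, c, d)
        rev = odds_ratio_2x2(c, d, a, b)
        assert fwd.or_estimate * rev.or_estimate == pytest.approx(1.0, rel=1e-9)
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-9)

    @given(st.tuples(*(st.integers(5, 100) for _ in range(4))),
           st.integers(2, 8))
    @settings(max_examples=40, deadline=None)
    def test_ci_brackets_estimate_and_shrinks_with_n(self, cells, factor):
        small = odds_ratio_2x2(*cells)
        big = odds_ratio_2x2(*(c * factor for c in cells))
        assert small.ci_low < small.or_estimate < small.ci_high
        assert (np.log(big.ci_high) - np.log(big.ci_low)
                < np.log(small.ci_high) - np.log(small.ci_low))


class TestEncoding:
    @pytest.mark.parametrize("model,coding", [
        ("additive", {0: 0, 1: 1, 2: 2}),
        ("dominant", {0: 0, 1: 1, 2: 1}),
        ("recessive", {0: 0, 1: 0, 2: 1}),
    ])
    def test_coding_definitions(self, model, coding):
        assert {k: v for k, v in MODEL_CODING[model].items()} == coding

    def test_codominant_contrasts_exclude_other_class(self):
        assert MODEL_CODING["codominant_het"][2] is None
        assert MODEL_CODING["codominant_hom"][1] is None

    def test_dominant_encoding_reproduces_carrier_counts(self, study_cohort):
        x, y, _ = encode_genotypes(study_cohort, "rs285207", "dominant")
        assert int(x[y == 1].sum()) == 184   # case carriers
        assert int(x[y == 0].sum()) == 313   # control carriers

    def test_missing_genotypes_excluded(self, study_cohort):
        x, y, keep = encode_genotypes(study_cohort, "rs285207", "additive")
        assert len(x) == 1655  # 686 typed cases + 969 typed controls


def _grid_mle(x, y, span=6.0, steps=121, zooms=6):
    """Independent oracle: coordinate grid refinement of the Bernoulli
    log-likelihood for a 1-predictor logistic model."""
    def loglik(b0, b1):
        eta = b0 + b1 * x
        return float(np.sum(y * eta - np.log1p(np.exp(eta))))

    c0 = c1 = 0.0
    width = span
    for _ in range(zooms):
        b0s = np.linspace(c0 - width, c0 + width, steps)
        b1s = np.linspace(c1 - width, c1 + width, steps)
        values = np.array([[loglik(b0, b1) for b1 in b1s] for b0 in b0s])
        i, j = np.unravel_index(np.argmax(values), values.shape)
        c0, c1 = b0s[i], b1s[j]
        width = width * 2 / (steps - 1) * 4
    return c0, c1


class TestLogistic:
    def test_intercept_only_on_balanced_outcome(self):
        y = np.array([0.0, 1.0] * 25)
        fit = fit_logistic(np.ones((50, 1)), y)
        assert fit.estimable
        assert fit.params[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_brute_force_likelihood_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=20)
        y = (rng.random(20) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        fit = fit_logistic(sm.add_constant(x), y)
        b0, b1 = _grid_mle(x, y)
        assert fit.params[0] == pytest.approx(b0, abs=1e-3)
        assert fit.params[1] == pytest.approx(b1, abs=1e-3)

    def test_dominant_crude_fit_matches_closed_form(self, study_cohort):
        x, y, _ = encode_genotypes(study_cohort, "rs285207", "dominant")
        fit = fit_logistic(sm.add_constant(x), y)
        assert np.exp(fit.params[1]) == pytest.approx(0.77, abs=5e-3)
        closed = odds_ratio_2x2(184, 502, 313, 656)
        assert np.exp(fit.params[1]) == pytest.approx(closed.or_estimate, abs=1e-6)

    def test_separated_data_flagged_not_raised(self):
        x = np.array([0.0] * 10 + [1.0] * 10)
        y = x.copy()
        fit = fit_logistic(sm.add_constant(x), y)
        assert not fit.estimable

    def test_constant_predictor_flagged(self):
        y = np.array([0.0, 1.0] * 10)
        X = np.column_stack([np.ones(20), np.full(20, 3.0)])
        assert not fit_logistic(X, y).estimable

    @given(st.tuples(*(st.integers(5, 150) for _ in range(4))))
    @settings(max_examples=25, deadline=None)
    def test_closed_form_equivalence_on_2x2(self, cells):
        a, b, c, d = cells  # case-exposed, case-ref, ctrl-exposed, ctrl-ref
        x = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
        y = np.concatenate([np.ones(a + b), np.zeros(c + d)])
        fit = fit_logistic(sm.add_constant(x), y)
        closed = odds_ratio_2x2(a, b, c, d)
        assert np.exp(fit.params[1]) == pytest.approx(closed.or_estimate, abs=1e-6)
        se_closed = np.sqrt(sum(1 / v for v in (a, b, c, d)))
        assert fit.bse[1] == pytest.approx(se_closed, abs=1e-6)


class TestAssociationScan:
    def test_crude_scan_reproduces_published_block(self, study_cohort):
        results, gtest = association_scan(
            study_cohort, "rs285207", covariates=()
        )
        crude = {r.model: r for r in results if not r.adjusted}
        assert crude["codominant_het"].or_estimate == pytest.approx(0.74, abs=5e-3)
        assert crude["dominant"].or_estimate == pytest.approx(0.77, abs=5e-3)
        assert crude["dominant"].distribution_p == pytest.approx(0.017, abs=1e-3)
        assert crude["recessive"].or_estimate == pytest.approx(1.29, abs=5e-3)
        assert crude["additive"].or_estimate == pytest.approx(0.83, abs=5e-3)
        assert gtest is not None and gtest.df == 2

    def test_additive_crude_rs285162(self, study_cohort):
        results, _ = association_scan(
            study_cohort, "rs285162", models=("additive",), covariates=()
        )
        assert results[0].or_estimate == pytest.approx(1.08, abs=5e-3)

    def test_identical_genotypes_not_estimable(self, study_cohort):
        import pandas as pd
        from snpcc.cohort import CohortTable, SnpInfo

        df = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(40)],
            "status": ["case"] * 20 + ["control"] * 20,
            "rs1": ["A/A"] * 40,
        })
        cohort = CohortTable(data=df, snps={"rs1": SnpInfo("rs1", "A", "C")})
        results, _ = association_scan(cohort, "rs1", covariates=())
        assert all(not r.estimable for r in results)

    def test_adjusted_results_carry_covariate_labels(self, study_cohort):
        results, _ = association_scan(
            study_cohort, "rs285207", models=("dominant",),
            covariates=("age_band", "sex"),
        )
        adjusted = [r for r in results if r.adjusted][0]
        assert adjusted.estimable
        assert set(adjusted.covariates) == {"age_band", "sex"}
        assert adjusted.or_estimate == pytest.approx(0.78, abs=0.01)
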