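"""Logistic regression tests against closed forms and statsmodels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import macrohier as mh
from macrohier.regression import (SeparationWarning, Z975, fit_logistic,
                                  wald_results)
from macrohier.schema import AnalysisSubset, DesignMatrix, encode
from .conftest import make_toy_cohort


def design_from_arrays(X, y, columns=None):
    X = np.asarray(X, dtype=float)
    columns = columns or ["intercept"] + [f"x{j}" for j in range(1, X.shape[1])]
    colmap = [(c, None) for c in columns]
    return DesignMatrix(X=X, columns=columns, y=np.asarray(y), colmap=colmap,
                        row_index=np.arange(len(y)))


def two_by_two_design(case_exposed, case_unexposed, control_exposed, control_unexposed):
    y = np.concatenate([np.ones(case_exposed + case_unexposed),
                        np.zeros(control_exposed + control_unexposed)])
    x = np.concatenate([np.ones(case_exposed), np.zeros(case_unexposed),
                        np.ones(control_exposed), np.zeros(control_unexposed)])
    return design_from_arrays(np.column_stack([np.ones_like(x), x]), y,
                              ["intercept", "exposed"])


class TestClosedForms:
    def test_two_by_two_slope_is_log_cross_product(self):
        """Exposure counts 13/84 (cases) vs 13/742 (controls): the fitted
        slope equals the closed-form log odds ratio ln(742/84)."""
        design = two_by_two_design(13, 84, 13, 742)
        fit = fit_logistic(design)
        assert fit.converged
        assert fit.beta[1] == pytest.approx(np.log((13 * 742) / (13 * 84)), abs=1e-6)

    def test_two_by_two_wald_interval_woolf(self):
        design = two_by_two_design(13, 84, 13, 742)
        fit = fit_logistic(design)
        [res] = wald_results(fit, design)
        se_woolf = np.sqrt(1 / 13 + 1 / 84 + 1 / 13 + 1 / 742)
        assert res.odds_ratio == pytest.approx(742 / 84, rel=1e-6)
        assert res.se == pytest.approx(se_woolf, abs=1e-6)
        assert res.ci_low == pytest.approx(np.exp(np.log(742 / 84) - Z975 * se_woolf), rel=1e-6)
        assert res.ci_high == pytest.approx(np.exp(np.log(742 / 84) + Z975 * se_woolf), rel=1e-6)
        assert 3.9 < res.ci_low < 4.0 and 19.6 < res.ci_high < 19.8

    def test_intercept_only_is_logit_prevalence(self):
        y = np.concatenate([np.ones(97), np.zeros(755)])
        design = design_from_arrays(np.ones((852, 1)), y, ["intercept"])
        fit = fit_logistic(design)
        assert fit.beta[0] == pytest.approx(np.log(97 / 755), abs=1e-8)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(min_value=1, max_value=60)] * 4))
    def test_random_two_by_two_matches_cross_product(self, counts):
        a, b, c, d = counts
        design = two_by_two_design(a, b, c, d)
        fit = fit_logistic(design)
        assert fit.beta[1] == pytest.approx(np.log((a * d) / (b * c)), abs=1e-6)


class TestFitMechanics:
    def _random_design(self, seed, n=300, p=3):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
        beta = rng.normal(scale=0.8, size=p + 1)
        y = rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))
        return design_from_arrays(X, y.astype(int))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_statsmodels(self, seed):
        import statsmodels.api as sm
        design = self._random_design(seed)
        fit = fit_logistic(design)
        ref = sm.Logit(design.y, design.X).fit(disp=0)
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_loglik_monotone_and_score_satisfied(self):
        design = self._random_design(7)
        fit = fit_logistic(design)
        assert np.all(np.diff(fit.loglik_path) >= -1e-12)
        score = design.X.T @ (design.y - fit.fitted)
        assert np.max(np.abs(score)) <= 1e-8

    def test_covariance_symmetric_psd(self):
        fit = fit_logistic(self._random_design(11))
        np.testing.assert_allclose(fit.cov, fit.cov.T)
        assert np.all(np.linalg.eigvalsh(fit.cov) > 0)

    def test_constant_shift_changes_only_intercept(self):
        design = self._random_design(3)
        shifted = design_from_arrays(design.X.copy(), design.y)
        shifted.X[:, 1] += 5.0
        a, b = fit_logistic(design), fit_logistic(shifted)
        np.testing.assert_allclose(a.beta[1:], b.beta[1:], atol=1e-6)
        assert abs(a.beta[0] - b.beta[0]) > 1e-3

    def test_constant_outcome_raises(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        design = design_from_arrays(X, np.ones(10, dtype=int))
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(design)

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(20), np.arange(20.0), 2 * np.arange(20.0)])
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        design = design_from_arrays(X, y, ["intercept", "a", "a_twice"])
        with pytest.raises(ValueError, match="a_twice"):
            fit_logistic(design)

    def test_separation_flagged_not_silent(self):
        x = np.r_[np.ones(10), np.zeros(10)]
        y = x.astype(int)  # perfectly separated
        design = design_from_arrays(np.column_stack([np.ones(20), x]), y)
        with pytest.warns(SeparationWarning):
            fit = fit_logistic(design)
        assert fit.separation


class TestOddsRatios:
    def test_crude_or_matches_two_by_two(self, cohort912):
        """crude_or on the generated cohort equals the 2x2 closed form for a
        dichotomous predictor."""
        subset = mh.make_subset(cohort912, "macrosomia_vs_2500_4000")
        spec = {s.name: s for s in mh.build_predictor_registry()}["Prior macrosomia"]
        [res] = mh.crude_or(cohort912, subset, spec)
        df = cohort912.df.iloc[subset.index]
        exposed = (df["prior_macrosomia"] == "yes").to_numpy()
        y = subset.y.astype(bool)
        a = int((exposed & y).sum()); b = int((~exposed & y).sum())
        c = int((exposed & ~y).sum()); d = int((~exposed & ~y).sum())
        assert res.odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-5)

    def test_zero_association_gives_unit_or(self):
        table = make_toy_cohort(
            40, prior_macrosomia=np.array((["yes"] * 5 + ["no"] * 15) * 2, dtype=object))
        subset = AnalysisSubset("macrosomia_vs_2500_4000",
                                np.arange(20), np.arange(20, 40))
        spec = {s.name: s for s in mh.build_predictor_registry()}["Prior macrosomia"]
        [res] = mh.crude_or(table, subset, spec)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_rescaling_continuous_predictor(self, cohort912):
        subset = mh.make_subset(cohort912, "macrosomia_vs_2500_4000")
        spec = {s.name: s for s in mh.build_predictor_registry()}["Maternal height (cm)"]
        [res] = mh.crude_or(cohort912, subset, spec)
        df = cohort912.df.copy()
        df["height_cm"] = df["height_cm"] * 10
        df["prepreg_bmi"] = df["prepreg_weight_kg"] / (df["height_cm"] / 100.0) ** 2
        scaled = mh.CohortTable(df)
        [res10] = mh.crude_or(scaled, subset, spec)
        assert res10.beta == pytest.approx(res.beta / 10, rel=1e-4)

    def test_adjusted_recovers_generating_log_odds(self):
        """With GDM confounded by BMI, the BMI-adjusted estimate recovers the
        generating log odds ratio 0.8 while the crude estimate is biased."""
        rng = np.random.default_rng(42)
        spec = {s.name: s for s in mh.build_predictor_registry()}["GDM"]
        adj_betas, crude_betas = [], []
        for _ in range(8):
            n = 4000
            bmi = rng.normal(25, 4, n)
            gdm = rng.random(n) < 1 / (1 + np.exp(-(-1.8 + 0.30 * (bmi - 25))))
            p = 1 / (1 + np.exp(-(-2.0 + 0.18 * (bmi - 25) + 0.8 * gdm)))
            y = rng.random(n) < p
            height = np.full(n, 165.0)
            table = make_toy_cohort(
                n,
                maternal_age_years=rng.normal(33, 4, n),
                parity=rng.integers(0, 3, n),
                prepreg_bmi=bmi,
                prepreg_weight_kg=bmi * (height / 100) ** 2,
                gdm=np.where(gdm, "gdm1", "none").astype(object),
                birthweight_g=np.where(y, 4300.0, 3400.0),
                macrosomia=y.astype(int),
                weight_band=np.where(y, "gt4000", "2500_4000").astype(object),
            )
            subset = mh.make_subset(table, "macrosomia_vs_2500_4000")
            [adj] = mh.adjusted_or(table, subset, spec)
            [crude] = mh.crude_or(table, subset, spec)
            adj_betas.append(adj.beta)
            crude_betas.append(crude.beta)
        assert np.mean(adj_betas) == pytest.approx(0.8, abs=0.12)
        assert np.mean(crude_betas) - 0.8 > 0.2

    def test_orthogonal_noise_aor_near_one(self):
        rng = np.random.default_rng(5)
        n = 2000
        y = rng.random(n) < 0.3
        spec = {s.name: s for s in mh.build_predictor_registry()}["Village"]
        bmi = rng.normal(23, 3, n)
        table = make_toy_cohort(
            n,
            maternal_age_years=rng.normal(33, 4, n),
            parity=rng.integers(0, 3, n),
            prepreg_bmi=bmi,
            prepreg_weight_kg=bmi * 1.65 ** 2,
            residence=np.where(rng.random(n) < 0.5, "village", "large_city").astype(object),
            birthweight_g=np.where(y, 4300.0, 3400.0),
            macrosomia=y.astype(int),
            weight_band=np.where(y, "gt4000", "2500_4000").astype(object),
        )
        subset = mh.make_subset(table, "macrosomia_vs_2500_4000")
        [res] = mh.adjusted_or(table, subset, spec)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.35)
        assert res.ci_low < 1.0 < res.ci_high

    def test_bmi_spec_drops_bmi_adjuster(self, cohort912):
        """Testing a BMI coding must not duplicate BMI among the adjusters."""
        subset = mh.make_subset(cohort912, "macrosomia_vs_2500_4000")
        spec = {s.name: s for s in mh.build_predictor_registry()}["Pre-pregnancy BMI (kg/m2)"]
        results = mh.adjusted_or(cohort912, subset, spec)  # would be rank-deficient
        assert len(results) == 1
        assert results[0].label[0] == "Pre-pregnancy BMI (kg/m2)"
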