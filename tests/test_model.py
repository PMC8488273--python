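import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

from imprintstat.exceptions import InsufficientDataError, UnidentifiableModelError
from imprintstat.model import (
    BatchStandardizer,
    ModelFit,
    PreferenceRegression,
    correlation_from_fit,
    fit_preference_regression,
    fit_with_approach_covariates,
    p_from_correlation,
    predict_at_score,
    standardize_by_batch,
    untrained_summary,
)


def _simulate(seed, tpb=(3, 2, 2, 2, 2, 2, 2, 2, 2, 2), slope=0.004,
              batch_sd=0.12, resid_sd=0.10):
    rng = np.random.default_rng(seed)
    batch, score, y = [], [], []
    for b, k in enumerate(tpb):
        u = rng.normal(0, batch_sd)
        for _ in range(k):
            s = float(np.clip(rng.normal(72, 22), 0, 100))
            batch.append(f"B{b}")
            score.append(s)
            y.append(1 + u + slope * s + rng.normal(0, resid_sd))
    return np.array(score), np.array(y), np.array(batch)


class TestBatchStandardizer:
    def test_single_batch_is_identity(self):
        v = np.array([1.0, 2.0, 5.0])
        assert np.allclose(standardize_by_batch(v, ["b"] * 3), v)

    def test_perfect_batch_effect_removed(self):
        out = standardize_by_batch([1.0, 1.0, 3.0, 3.0], ["a", "a", "b", "b"])
        assert np.allclose(out, 2.0)

    def test_batch_means_collapse_to_overall_mean(self, rng):
        v = rng.normal(0, 1, 12)
        b = np.repeat(["x", "y", "z"], 4)
        out = standardize_by_batch(v, b)
        overall = v.mean()
        for g in "xyz":
            assert out[b == g].mean() == pytest.approx(overall, abs=1e-12)
        assert out.mean() == pytest.approx(overall, abs=1e-12)

    def test_transform_on_unseen_batch_fails(self):
        st = BatchStandardizer().fit([1.0, 2.0], ["a", "a"])
        with pytest.raises(KeyError):
            st.transform([1.0], ["b"])

    def test_sklearn_clone_compatible(self):
        clone(BatchStandardizer())
        clone(PreferenceRegression(reml=False))


class TestPreferenceRegression:
    def test_df_convention_reproduces_study_dfs(self):
        s, y, b = _simulate(0)
        assert fit_preference_regression(y, s, b).df_slope == 10  # 21 chicks, 10 batches
        s, y, b = _simulate(0, tpb=(3, 2, 2, 2, 2, 2, 2, 2, 2))
        assert fit_preference_regression(y, s, b).df_slope == 9  # 19 chicks, 9 batches

    def test_single_batch_equals_ols_closed_form(self, rng):
        s = rng.uniform(40, 100, 12)
        y = 0.8 + 0.003 * s + rng.normal(0, 0.05, 12)
        fit = fit_preference_regression(y, s, ["b1"] * 12)
        sxx = np.sum((s - s.mean()) ** 2)
        slope = np.sum((s - s.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * s.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-8)
        assert fit.intercept == pytest.approx(intercept, abs=1e-8)
        assert fit.var_batch == 0.0

    def test_noiseless_line_recovered_exactly(self):
        s = np.array([50.0, 60.0, 70.0, 90.0])
        y = 2.0 + 0.01 * s
        fit = fit_preference_regression(y, s, ["b"] * 4)
        assert fit.slope == pytest.approx(0.01, abs=1e-12)
        assert fit.residual_variance == 0.0
        assert fit.var_batch == 0.0
        assert fit.se_slope == 0.0

    def test_reml_matches_nlme_lme_frozen_oracle(self):
        """Frozen cross-check against R nlme::lme (REML, random ~1|batch).

        The expected numbers below were computed with nlme 3.1 on exactly
        this dataset; lme also reports denominator DF 10 for the slope,
        matching the n_chicks - n_batches - 1 convention.
        """
        rng = np.random.default_rng(7)
        tpb = [3, 2, 2, 2, 2, 2, 2, 2, 2, 2]
        batch, score, y = [], [], []
        for b in range(10):
            u = rng.normal(0, 0.12)
            for _ in range(tpb[b]):
                s = float(np.clip(rng.normal(72, 22), 0, 100))
                batch.append(f"B{b}")
                score.append(s)
                y.append(1 + u + 0.004 * s + rng.normal(0, 0.1))
        est = PreferenceRegression().fit(np.array(score), np.array(y), groups=np.array(batch))
        assert est.intercept_ == pytest.approx(0.958389092, abs=1e-6)
        assert est.slope_ == pytest.approx(0.004097612, abs=1e-8)
        assert est.se_intercept_ == pytest.approx(0.105610000, abs=1e-6)
        assert est.se_slope_ == pytest.approx(0.001616286, abs=1e-8)
        assert est.residual_variance_ == pytest.approx(0.011534921, abs=1e-7)
        assert est.var_batch_ == pytest.approx(0.008705377, abs=1e-7)
        assert est.df_slope_ == 10

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_reml_matches_statsmodels_mixedlm(self, seed):
        from statsmodels.regression.mixed_linear_model import MixedLM

        s, y, b = _simulate(seed)
        fit = fit_preference_regression(y, s, b)
        X = np.column_stack([np.ones_like(s), s])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = MixedLM(y, X, groups=b).fit(reml=True)
        # tolerances allow for the two optimizers stopping at slightly
        # different points near the var_batch = 0 boundary
        assert fit.intercept == pytest.approx(ref.fe_params[0], abs=5e-4)
        assert fit.slope == pytest.approx(ref.fe_params[1], abs=1e-5)
        assert fit.residual_variance == pytest.approx(float(ref.scale), abs=1e-4)
        assert fit.var_batch == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), abs=1e-4)

    def test_identical_scores_unidentifiable(self):
        with pytest.raises(UnidentifiableModelError):
            fit_preference_regression([1.0, 1.1, 0.9], [70.0] * 3, ["a", "a", "b"])

    def test_too_few_chicks(self):
        with pytest.raises(InsufficientDataError):
            fit_preference_regression([1.0, 1.1], [60.0, 80.0], ["a", "a"])

    def test_replicate_rows_enable_chick_variance_component(self):
        rng = np.random.default_rng(5)
        chicks, batch, score, y = [], [], [], []
        for b in range(6):
            u = rng.normal(0, 0.1)
            for c in range(2):
                cid = f"b{b}c{c}"
                d = rng.normal(0, 0.15)  # chick-level effect
                s = float(np.clip(rng.normal(72, 20), 0, 100))
                for _ in range(3):  # triplicate filters
                    chicks.append(cid)
                    batch.append(f"B{b}")
                    score.append(s)
                    y.append(1 + u + d + 0.003 * s + rng.normal(0, 0.05))
        est = PreferenceRegression().fit(
            np.array(score), np.array(y), groups=np.array(batch),
            chick_ids=np.array(chicks),
        )
        assert est.var_chick_ > 0
        assert est.df_slope_ == 12 - 6 - 1


class TestDerivedStatistics:
    def test_zero_slope_gives_zero_correlation(self):
        fit = ModelFit(intercept=1.0, slope=0.0, se_intercept=0.1, se_slope=0.01,
                       cov_intercept_slope=0.0, df_slope=10, residual_variance=0.01,
                       df_residual=10, var_batch=0.0, var_chick=0.0, n_obs=21,
                       n_batches=10)
        r, df, p = correlation_from_fit(fit)
        assert r == 0.0
        assert p == pytest.approx(1.0)

    def test_printed_correlation_triple_is_consistent(self):
        # r = 0.748 with df 9 corresponds to a two-tailed p printed as 0.008
        assert f"{p_from_correlation(0.748, 9):.1g}" == "0.008"

    def test_correlation_sign_symmetry(self):
        assert p_from_correlation(-0.75, 9) == pytest.approx(p_from_correlation(0.75, 9))

    def test_correlation_p_equals_slope_t_test(self):
        s, y, b = _simulate(4)
        fit = fit_preference_regression(y, s, b)
        r, df, p = correlation_from_fit(fit)
        t = fit.slope / fit.se_slope
        assert p == pytest.approx(float(2 * stats.t.sf(abs(t), fit.df_slope)))
        assert df == fit.df_slope

    def test_prediction_at_zero_is_intercept(self):
        s, y, b = _simulate(6)
        fit = fit_preference_regression(y, s, b)
        pred = predict_at_score(fit, 0.0)
        assert pred.estimate == pytest.approx(fit.intercept)
        assert pred.se == pytest.approx(fit.se_intercept)

    @pytest.mark.parametrize("score", [50.0, 100.0])
    def test_prediction_se_matches_quadratic_form_oracle(self, score):
        s, y, b = _simulate(8)
        fit = fit_preference_regression(y, s, b)
        pred = predict_at_score(fit, score)
        cov = np.array(
            [[fit.se_intercept**2, fit.cov_intercept_slope],
             [fit.cov_intercept_slope, fit.se_slope**2]]
        )
        x = np.array([1.0, score])
        assert pred.se == pytest.approx(float(np.sqrt(x @ cov @ x)), abs=1e-10)
        assert pred.df == fit.df_slope

    def test_untrained_summary(self):
        g = untrained_summary([1.0, 1.0, 1.0])
        assert (g.mean, g.sem, g.df) == (1.0, 0.0, 2)
        vals = np.random.default_rng(1).normal(1, 0.2, 10)
        g = untrained_summary(vals)
        assert g.df == 9
        assert g.variance == pytest.approx(g.n * g.sem**2, abs=1e-12)
        with pytest.raises(InsufficientDataError):
            untrained_summary([1.0])


class TestApproachCovariates:
    def test_constant_covariates_reduce_to_plain_fit(self):
        s, y, b = _simulate(9)
        plain = fit_preference_regression(y, s, b)
        cov = fit_with_approach_covariates(y, s, np.zeros_like(s), np.zeros_like(s), b)
        assert cov.fit.slope == pytest.approx(plain.slope, abs=1e-10)
        assert cov.fit.se_slope == pytest.approx(plain.se_slope, abs=1e-10)
        assert cov.term("approach_training").f == 0.0

    def test_denominator_df_with_three_fixed_terms(self, rng):
        s, y, b = _simulate(10)
        a1 = rng.uniform(10, 100, s.size)
        a2 = rng.uniform(5, 30, s.size)
        cov = fit_with_approach_covariates(y, s, a1, a2, b)
        assert cov.term("preference_score").df_den == 21 - 10 - 3  # the printed F(1,8)
        assert all(t.df_num == 1 for t in cov.terms)

    def test_testing_approach_driven_amounts_detected(self):
        """When testing approach, not learning, drives the protein, its F is
        significant and the preference-score F is not, in >=90% of runs."""
        hits = 0
        n_runs = 200
        for seed in range(n_runs):
            rng = np.random.default_rng(100_000 + seed)
            batch, score, a_tr, a_te, y = [], [], [], [], []
            for b, k in enumerate((3, 2, 2, 2, 2, 2, 2, 2, 2, 2)):
                u = rng.normal(0, 0.1)
                for _ in range(k):
                    s = float(np.clip(rng.normal(72, 22), 0, 100))
                    te = float(rng.lognormal(np.log(11.0), 0.6))
                    batch.append(f"B{b}")
                    score.append(s)
                    a_tr.append(float(rng.lognormal(np.log(45.0), 0.8)))
                    a_te.append(te)
                    y.append(1 + u + 0.03 * te + rng.normal(0, 0.1))
            cov = fit_with_approach_covariates(
                np.array(y), np.array(score), np.array(a_tr), np.array(a_te),
                np.array(batch),
            )
            if cov.term("approach_testing").p < 0.05 and cov.term("preference_score").p >= 0.05:
                hits += 1
        assert hits / n_runs >= 0.90
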