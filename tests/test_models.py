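"""Outcome transforms, scaling, mixed/OLS fits and fit statistics."""
import math
import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from keymood.errors import ContractError, FittingError, UndefinedResultError
from keymood.features import PREDICTORS
from keymood.models import (
    ModelSpec,
    apply_pairwise_deletion,
    fit_mixed_model,
    fit_ols,
    information_criteria,
    likelihood_ratio_test,
    log_transform_ymrs,
    nakagawa_schielzeth_r2,
    prepare_model_frame,
    sample_skewness,
    scale_predictors,
    spearman_total_keys,
    wald_chisq_tests,
)
from keymood.simulate import simulate_cohort


def synthetic_frame(seed=0, n_subjects=6, n_per_subject=12, beta=None, sigma_u=2.0, sigma_e=1.0):
    """Small model-ready frame with known linear structure (synthetic stand-in
    for an extracted feature table; no stream simulation involved)."""
    rng = np.random.default_rng(seed)
    beta = np.zeros(len(PREDICTORS)) if beta is None else np.asarray(beta, dtype=float)
    rows = []
    for i in range(n_subjects):
        u = rng.normal(0, sigma_u)
        for _ in range(n_per_subject):
            x = rng.normal(size=len(PREDICTORS))
            y = 10.0 + x @ beta + u + rng.normal(0, sigma_e)
            rows.append({"subject_id": f"s{i}", "outcome": y, **dict(zip(PREDICTORS, x))})
    return pd.DataFrame(rows)


class TestOutcomeTransform:
    @pytest.mark.parametrize(
        "score,expected", [(0, 0.0), (20, 3.045), (7, math.log(8))]
    )
    def test_values(self, score, expected):
        assert log_transform_ymrs(score) == pytest.approx(expected, abs=5e-4)

    def test_negative_rejected(self):
        with pytest.raises(ContractError):
            log_transform_ymrs(-1)


class TestSkewness:
    def test_symmetric_is_zero(self):
        assert sample_skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_right_tail_positive(self):
        assert sample_skewness([0, 0, 0, 10]) > 0

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        # independent route: scipy's bias-corrected estimator
        assert sample_skewness(x) == pytest.approx(
            scipy.stats.skew(x, bias=False), rel=1e-12
        )

    def test_degenerate_inputs(self):
        with pytest.raises(UndefinedResultError):
            sample_skewness([1.0, 1.0, 1.0])
        with pytest.raises(UndefinedResultError):
            sample_skewness([1.0, 2.0])


class TestScaling:
    def test_scaled_columns_standardized_and_location_invariant(self):
        df = synthetic_frame(seed=3)
        scaled, params = scale_predictors(df)
        for p in PREDICTORS:
            assert scaled[p].mean() == pytest.approx(0.0, abs=1e-12)
            assert scaled[p].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        shifted, _ = scale_predictors(df.assign(**{PREDICTORS[0]: df[PREDICTORS[0]] + 17.0}))
        pd.testing.assert_series_equal(shifted[PREDICTORS[0]], scaled[PREDICTORS[0]])

    def test_matches_two_pass_computation(self):
        df = synthetic_frame(seed=4)
        scaled, params = scale_predictors(df)
        p = PREDICTORS[2]
        col = df[p].to_numpy()
        mean = col.sum() / len(col)
        sd = math.sqrt(((col - mean) ** 2).sum() / (len(col) - 1))
        np.testing.assert_allclose(scaled[p], (col - mean) / sd, rtol=1e-12)

    def test_zero_sd_predictor_named(self):
        df = synthetic_frame(seed=5)
        df[PREDICTORS[3]] = 2.5
        with pytest.raises(UndefinedResultError, match=PREDICTORS[3]):
            scale_predictors(df)

    def test_scaling_equivariance_of_fit(self):
        """Multiplying a raw predictor by a positive constant leaves every
        scaled-model output unchanged."""
        df = synthetic_frame(seed=6, beta=np.arange(7) * 0.3, sigma_u=1.0)
        spec = ModelSpec(outcome="hdrs17_raw")
        df2 = df.assign(**{PREDICTORS[1]: df[PREDICTORS[1]] * 250.0})
        fit1 = fit_mixed_model(scale_predictors(df)[0], spec)
        fit2 = fit_mixed_model(scale_predictors(df2)[0], spec)
        for name in fit1.names:
            assert fit1.params[name] == pytest.approx(fit2.params[name], rel=1e-8)
        assert fit1.llf == pytest.approx(fit2.llf, abs=1e-8)


class TestPairwiseDeletion:
    def test_complete_table_unchanged(self):
        df = synthetic_frame(seed=7)
        out = apply_pairwise_deletion(df, ModelSpec(outcome="hdrs17_raw"))
        assert len(out) == len(df)

    def test_nine_by_eight_with_eight_missing_retains_64(self):
        df = synthetic_frame(seed=8, n_subjects=9, n_per_subject=8)
        idx = np.random.default_rng(0).choice(len(df), size=8, replace=False)
        df.loc[idx[:4], "circadian_similarity"] = np.nan
        df.loc[idx[4:], "outcome"] = np.nan
        out = apply_pairwise_deletion(df, ModelSpec(outcome="hdrs17_raw"))
        assert len(out) == 64

    def test_all_missing_errors(self):
        df = synthetic_frame(seed=9)
        df["outcome"] = np.nan
        with pytest.raises(ContractError):
            apply_pairwise_deletion(df, ModelSpec(outcome="hdrs17_raw"))


class TestMixedModel:
    def test_noiseless_recovery(self):
        beta = np.array([1.5, -2.0, 0.5, 0.0, 3.0, -1.0, 0.25])
        df = synthetic_frame(seed=10, beta=beta, sigma_u=0.0, sigma_e=0.0)
        fit = fit_mixed_model(df, ModelSpec(outcome="hdrs17_raw"))
        got = np.array([fit.params[p] for p in PREDICTORS])
        np.testing.assert_allclose(got, beta, atol=1e-6)
        assert fit.params["const"] == pytest.approx(10.0, abs=1e-6)

    def test_single_subject_rejected(self):
        df = synthetic_frame(seed=11, n_subjects=1)
        with pytest.raises(ContractError):
            fit_mixed_model(df, ModelSpec(outcome="hdrs17_raw"))

    def test_agrees_with_lme4(self, tmp_path):
        """Independent oracle: R/lme4 ML fit on the same frame."""
        df = synthetic_frame(seed=12, beta=np.linspace(-1, 2, 7), sigma_u=1.5)
        frame, _ = (df, None)
        fit = fit_mixed_model(frame, ModelSpec(outcome="hdrs17_raw"))
        csv = tmp_path / "frame.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "f <- lmer(outcome ~ "
            + " + ".join(PREDICTORS)
            + " + (1|subject_id), data=d, REML=FALSE)\n"
            "cat(sprintf('%.8f', as.numeric(logLik(f))), '\\n')\n"
            "vc <- as.data.frame(VarCorr(f))\n"
            "cat(sprintf('%.8f', vc$vcov), '\\n')\n"
            "cat(sprintf('%.8f', fixef(f)), '\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        ).stdout.split("\n")
        r_llf = float(out[0])
        r_vc = [float(v) for v in out[1].split()]
        r_fe = [float(v) for v in out[2].split()]
        assert fit.llf == pytest.approx(r_llf, abs=1e-4)
        assert fit.sigma_u2 == pytest.approx(r_vc[0], abs=1e-3)
        assert fit.sigma_e2 == pytest.approx(r_vc[1], abs=1e-3)
        np.testing.assert_allclose(
            [fit.params[n] for n in fit.names], r_fe, atol=1e-4
        )

    def test_boundary_matches_ols(self):
        """sigma_u = 0 data: when the variance MLE lands on the zero boundary
        (which happens for roughly half of such realizations), the mixed llf
        equals the OLS llf and AIC differs by exactly the extra variance
        parameter."""
        hit_boundary = 0
        for seed in range(40, 52):
            df = synthetic_frame(seed=seed, beta=np.ones(7), sigma_u=0.0,
                                 sigma_e=1.0, n_subjects=8, n_per_subject=10)
            mixed = fit_mixed_model(df, ModelSpec(outcome="hdrs17_raw"))
            ols = fit_ols(df, ModelSpec(outcome="hdrs17_raw", include_random_intercept=False))
            if not mixed.boundary:
                assert mixed.llf >= ols.llf - 1e-8  # interior MLE beats OLS
                continue
            hit_boundary += 1
            assert mixed.sigma_u2 <= 1e-6
            assert mixed.llf == pytest.approx(ols.llf, abs=1e-4)
            assert mixed.aic - ols.aic == pytest.approx(2.0, abs=1e-3)
        assert hit_boundary >= 2


class TestOls:
    def test_exact_linear_r2_one(self):
        df = synthetic_frame(seed=14, beta=np.ones(7), sigma_u=0.0, sigma_e=0.0)
        fit = fit_ols(df, ModelSpec(outcome="hdrs17_raw", include_random_intercept=False))
        assert fit.multiple_r2 == pytest.approx(1.0, abs=1e-10)

    def test_null_r2_near_zero_large_n(self):
        df = synthetic_frame(seed=15, n_subjects=40, n_per_subject=50, sigma_u=0.0)
        fit = fit_ols(df, ModelSpec(outcome="hdrs17_raw", include_random_intercept=False))
        assert fit.multiple_r2 < 0.02

    def test_matches_pseudoinverse_oracle(self):
        df = synthetic_frame(seed=16, beta=np.linspace(1, -1, 7), sigma_e=0.7, sigma_u=0.0)
        fit = fit_ols(df, ModelSpec(outcome="hdrs17_raw", include_random_intercept=False))
        X = np.column_stack([np.ones(len(df))] + [df[p] for p in PREDICTORS])
        beta_hat = np.linalg.pinv(X) @ df["outcome"].to_numpy()
        np.testing.assert_allclose([fit.params[n] for n in fit.names], beta_hat, atol=1e-10)
        resid = df["outcome"].to_numpy() - X @ beta_hat
        assert fit.rmse == pytest.approx(math.sqrt((resid**2).mean()), rel=1e-10)

    def test_rank_deficient_names_predictor(self):
        df = synthetic_frame(seed=17)
        df[PREDICTORS[1]] = 2.0 * df[PREDICTORS[0]]
        with pytest.raises(FittingError):
            fit_ols(df, ModelSpec(outcome="hdrs17_raw", include_random_intercept=False))

    def test_adjusted_r2_and_df_conventions(self):
        df = synthetic_frame(seed=18, n_subjects=8, n_per_subject=8, beta=np.ones(7), sigma_u=0.0)
        fit = fit_ols(df, ModelSpec(outcome="hdrs17_raw", include_random_intercept=False))
        n, p = 64, 7
        assert fit.f_df == (p, n - p - 1)
        assert fit.adjusted_r2 == pytest.approx(
            1 - (1 - fit.multiple_r2) * (n - 1) / (n - p - 1), rel=1e-12
        )


class TestLrt:
    def test_equal_likelihoods_give_zero_and_p_one(self):
        df = synthetic_frame(seed=19, beta=np.ones(7))
        full = fit_mixed_model(df, ModelSpec(outcome="hdrs17_raw"))
        null = fit_mixed_model(df, ModelSpec(outcome="hdrs17_raw", predictors=()))
        null.llf = full.llf
        out = likelihood_ratio_test(null, full)
        assert out.chi_square == 0.0 and out.pvalue == 1.0

    def test_published_arithmetic(self):
        """ll_null = -188.45, ll_full = -179.65, df 7 -> chi2 = 17.6."""
        df = synthetic_frame(seed=20, beta=np.ones(7))
        full_spec = ModelSpec(outcome="hdrs17_raw")
        null_spec = ModelSpec(outcome="hdrs17_raw", predictors=())
        full = fit_mixed_model(df, full_spec)
        null = fit_mixed_model(df, null_spec)
        full.llf, null.llf = -179.65, -188.45
        out = likelihood_ratio_test(null, full)
        assert out.df == 7
        assert out.chi_square == pytest.approx(17.6, abs=1e-10)
        assert out.pvalue == pytest.approx(scipy.stats.chi2.sf(17.6, 7), rel=1e-12)

    def test_null_and_full_must_nest(self):
        df = synthetic_frame(seed=21, beta=np.ones(7))
        full = fit_mixed_model(df, ModelSpec(outcome="hdrs17_raw"))
        null = fit_mixed_model(df, ModelSpec(outcome="hdrs17_raw", predictors=()))
        with pytest.raises(ContractError):
            likelihood_ratio_test(full, null)  # reversed order

    def test_differing_observation_sets_rejected(self):
        df = synthetic_frame(seed=22, beta=np.ones(7))
        full = fit_mixed_model(df, ModelSpec(outcome="hdrs17_raw"))
        null = fit_mixed_model(df.iloc[:-2], ModelSpec(outcome="hdrs17_raw", predictors=()))
        with pytest.raises(ContractError):
            likelihood_ratio_test(null, full)

    def test_statistic_clamped_at_zero(self):
        df = synthetic_frame(seed=23)
        full = fit_mixed_model(df, ModelSpec(outcome="hdrs17_raw"))
        null = fit_mixed_model(df, ModelSpec(outcome="hdrs17_raw", predictors=()))
        null.llf = full.llf + 1e-6  # numerically above the full model
        out = likelihood_ratio_test(null, full)
        assert out.chi_square == 0.0
        assert out.pvalue == 1.0


class TestR2Decomposition:
    def test_direct_formula(self):
        assert nakagawa_schielzeth_r2((2.0, 1.0, 1.0)) == pytest.approx((0.5, 0.75))

    def test_boundary_identity(self):
        m, c = nakagawa_schielzeth_r2((2.0, 0.0, 2.0))
        assert m == c == pytest.approx(0.5)

    def test_zero_fixed_effects(self):
        m, c = nakagawa_schielzeth_r2((0.0, 1.0, 3.0))
        assert m == 0.0 and c == pytest.approx(0.25)

    def test_ordering_on_real_fit(self):
        df = synthetic_frame(seed=24, beta=np.ones(7))
        fit = fit_mixed_model(df, ModelSpec(outcome="hdrs17_raw"))
        assert 0 <= fit.marginal_r2 <= fit.conditional_r2 <= 1

    def test_monotone_in_fixed_effect_variance(self):
        prev = -1.0
        for sf2 in (0.5, 1.0, 2.0, 4.0):
            m, c = nakagawa_schielzeth_r2((sf2, 1.0, 1.0))
            assert m > prev
            prev = m


class TestWald:
    def test_quantile_identity(self):
        df = synthetic_frame(seed=25, beta=np.ones(7))
        fit = fit_mixed_model(df, ModelSpec(outcome="hdrs17_raw"))
        name = PREDICTORS[0]
        fit.params[name] = 1.96 * fit.bse[name]
        table = wald_chisq_tests(fit)
        assert table.loc[name, "pvalue"] == pytest.approx(0.05, abs=1e-3)

    def test_matches_normal_tail_computation(self):
        df = synthetic_frame(seed=26, beta=np.linspace(0, 2, 7))
        fit = fit_mixed_model(df, ModelSpec(outcome="hdrs17_raw"))
        table = wald_chisq_tests(fit)
        for name in fit.names:
            z = fit.params[name] / fit.bse[name]
            assert table.loc[name, "pvalue"] == pytest.approx(
                2 * scipy.stats.norm.sf(abs(z)), rel=1e-9
            )
            assert table.loc[name, "ci_low"] == pytest.approx(
                fit.params[name] - 1.96 * fit.bse[name]
            )


class TestInformationCriteria:
    @pytest.mark.parametrize(
        "ll,k,n,aic,bic",
        [
            (-64.621, 10, 64, 149.24, 170.83),  # mixed-model convention
            (-64.621, 9, 64, 147.24, 166.67),  # OLS convention
            (0.0, 1, 1, 2.0, 0.0),
        ],
    )
    def test_identities(self, ll, k, n, aic, bic):
        got_aic, got_bic = information_criteria(ll, k, n)
        assert got_aic == pytest.approx(aic, abs=5e-3)
        assert got_bic == pytest.approx(bic, abs=5e-3)

    def test_contract(self):
        with pytest.raises(ContractError):
            information_criteria(0.0, 0, 10)


class TestSpearman:
    def test_concordant_and_discordant(self):
        x = np.arange(9, dtype=float)
        got = spearman_total_keys(x, x * 3 + 1)
        assert got.s_statistic == 0.0 and got.rho == pytest.approx(1.0)
        got = spearman_total_keys(x, -x)
        assert got.rho == pytest.approx(-1.0)

    def test_tied_fixture_matches_midrank_oracle(self):
        x = np.array([10.0, 20.0, 20.0, 30.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        got = spearman_total_keys(x, y)
        rx = scipy.stats.rankdata(x)  # midranks: [2, 3.5, 3.5, 5, 1]
        s = float(((rx - scipy.stats.rankdata(y)) ** 2).sum())
        assert got.s_statistic == pytest.approx(s)
        assert got.pvalue == pytest.approx(scipy.stats.spearmanr(x, y).pvalue)

    def test_constant_covariate_undefined(self):
        with pytest.raises(UndefinedResultError):
            spearman_total_keys([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])


def test_prepare_model_frame_log_transform_consistency(light_config):
    sim = simulate_cohort(light_config)
    spec = ModelSpec(outcome="log_ymrs")
    frame, params = prepare_model_frame(sim.truth.features, spec)
    raw = sim.truth.features
    raw = raw[raw["scale"] == "YMRS"].reset_index(drop=True)
    np.testing.assert_allclose(
        frame["outcome"], np.log(raw["score"].astype(float) + 1.0)
    )
    assert params is not None
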