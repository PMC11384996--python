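"""Set-size curve fits, mixed models, and model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from hybridsearch.setsize_stats import (
    aggregate_curves,
    compare_forms_aic,
    fit_random_intercept_lmm,
    fit_random_intercept_logistic,
    likelihood_ratio_test,
    participant_setsize_curves,
)

LEVELS = np.array([1, 2, 4, 8])


def _curve_frame(y_by_level, participant="P0", context=False, axis="vss"):
    other = "mss" if axis == "vss" else "vss"
    rows = []
    for level, ys in y_by_level.items():
        for y in np.atleast_1d(ys):
            rows.append(
                {
                    "participant_id": participant,
                    axis: level,
                    other: 4,
                    "context_present": context,
                    "rt": float(y),
                }
            )
    return pd.DataFrame(rows)


class TestParticipantCurves:
    def test_exact_linear_data_recovered(self):
        """y = 0.13 x + 1.35 reproduced with R^2 = 1 by the linear form."""
        df = _curve_frame({x: 0.13 * x + 1.35 for x in LEVELS})
        fits = participant_setsize_curves(df, axis="vss")
        linear = next(f for f in fits if f.form == "linear")
        assert linear.slope == pytest.approx(0.13, abs=1e-10)
        assert linear.intercept == pytest.approx(1.35, abs=1e-10)
        assert linear.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_exact_log_data_recovered(self):
        """y = 0.40 ln(x) + 1.28 reproduced with R^2 = 1 by the log form."""
        df = _curve_frame({x: 0.40 * np.log(x) + 1.28 for x in LEVELS}, axis="mss")
        fits = participant_setsize_curves(df, axis="mss")
        logf = next(f for f in fits if f.form == "log")
        assert logf.slope == pytest.approx(0.40, abs=1e-10)
        assert logf.intercept == pytest.approx(1.28, abs=1e-10)
        assert logf.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constant_data_gives_zero_slopes(self):
        df = _curve_frame({x: 1.5 for x in LEVELS})
        for f in participant_setsize_curves(df, axis="vss"):
            assert f.slope == pytest.approx(0.0, abs=1e-12)

    def test_normal_equations_hold(self):
        """OLS residuals are orthogonal to the regressor and the intercept."""
        rng = np.random.default_rng(8)
        df = _curve_frame({x: 1 + 0.2 * x + rng.normal(0, 0.1) for x in LEVELS})
        fits = participant_setsize_curves(df, axis="vss")
        means = df.groupby("vss")["rt"].mean()
        for f in fits:
            x = means.index.to_numpy(dtype=float)
            if f.form == "log":
                x = np.log(x)
            resid = means.to_numpy() - (f.slope * x + f.intercept)
            assert abs(resid.sum()) < 1e-10
            assert abs(resid @ x) < 1e-10

    def test_single_level_participant_skipped(self):
        df = _curve_frame({4: [1.0, 1.2, 1.1]})
        assert participant_setsize_curves(df, axis="vss") == []

    def test_fixed_other_restriction_applied(self):
        df = pd.concat(
            [
                _curve_frame({x: 1 + 0.1 * x for x in LEVELS}),
                _curve_frame({x: 50.0 for x in LEVELS}).assign(mss=8),
            ]
        )
        fits = participant_setsize_curves(df, axis="vss", fixed_other=4)
        linear = next(f for f in fits if f.form == "linear")
        assert linear.slope == pytest.approx(0.1, abs=1e-10)


class TestAggregateCurves:
    def test_identical_fits_have_zero_sem(self):
        df = _curve_frame({x: 0.2 * x + 1 for x in LEVELS}, participant="P0")
        df2 = _curve_frame({x: 0.2 * x + 1 for x in LEVELS}, participant="P1")
        fits = participant_setsize_curves(pd.concat([df, df2]), axis="vss")
        agg = aggregate_curves(fits)
        assert np.allclose(agg["slope_sem"], 0.0)

    def test_mean_and_sem_arithmetic(self):
        df = pd.concat(
            [
                _curve_frame({x: 0.1 * x for x in LEVELS}, participant="P0"),
                _curve_frame({x: 0.2 * x for x in LEVELS}, participant="P1"),
            ]
        )
        agg = aggregate_curves(participant_setsize_curves(df, axis="vss"))
        linear = agg[agg["form"] == "linear"].iloc[0]
        assert linear["slope_mean"] == pytest.approx(0.15)
        assert linear["slope_sem"] == pytest.approx(0.05)


def _lmm_data(
    seed,
    n_p=25,
    n_t=40,
    intercept=1.23,
    context=0.49,
    slope=0.12,
    transform=lambda x: x,
    sigma_b=0.25,
    sigma_e=0.6,
):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_p):
        b = rng.normal(0, sigma_b)
        for _ in range(n_t):
            vss = rng.choice(LEVELS)
            ctx = rng.random() < 0.5
            rt = intercept + context * ctx + slope * transform(vss) + b + rng.normal(0, sigma_e)
            rows.append(
                dict(participant_id=f"P{i:02d}", vss=int(vss), context_present=bool(ctx), rt=rt)
            )
    return pd.DataFrame(rows)


class TestRandomInterceptLMM:
    def test_zero_variance_matches_ols(self):
        # at this draw the ML variance ratio lands on the zero boundary,
        # so the mixed fit must collapse to ordinary least squares
        df = _lmm_data(1, sigma_b=0.0)
        res = fit_random_intercept_lmm(df, set_size="vss")
        X = np.column_stack(
            [
                np.ones(len(df)),
                df["context_present"],
                df["vss"],
                df["context_present"] * df["vss"],
            ]
        )
        beta_ols, *_ = np.linalg.lstsq(X, df["rt"].to_numpy(), rcond=None)
        assert res.icc < 0.02
        assert np.allclose(res.fixed_effects["estimate"].to_numpy(), beta_ols, atol=1e-6)

    def test_matches_reference_implementation(self):
        """Log-likelihood agrees with statsmodels MixedLM (ML) to 1e-4."""
        import statsmodels.formula.api as smf

        df = _lmm_data(12)
        res = fit_random_intercept_lmm(df, set_size="vss")
        ref = smf.mixedlm(
            "rt ~ context_present * vss", df, groups=df["participant_id"]
        ).fit(reml=False)
        assert res.log_likelihood == pytest.approx(ref.llf, abs=1e-4)
        assert np.allclose(
            np.sort(res.fixed_effects["estimate"]), np.sort(ref.params.values[:4]), atol=1e-4
        )

    def test_relabeling_invariance_and_location_shift(self):
        df = _lmm_data(2)
        base = fit_random_intercept_lmm(df, set_size="vss")
        relabeled = df.copy()
        mapping = {p: f"Q{j}" for j, p in enumerate(reversed(sorted(df["participant_id"].unique())))}
        relabeled["participant_id"] = relabeled["participant_id"].map(mapping)
        res2 = fit_random_intercept_lmm(relabeled, set_size="vss")
        assert res2.log_likelihood == pytest.approx(base.log_likelihood, abs=1e-8)
        shifted = df.assign(rt=df["rt"] + 5.0)
        res3 = fit_random_intercept_lmm(shifted, set_size="vss")
        est, est3 = base.fixed_effects["estimate"], res3.fixed_effects["estimate"]
        assert est3.iloc[0] == pytest.approx(est.iloc[0] + 5.0, abs=1e-8)
        assert np.allclose(est3.iloc[1:], est.iloc[1:], atol=1e-8)

    def test_singular_design_rejected_with_term_name(self):
        df = _lmm_data(3)
        df["context_present"] = True  # aliased with the intercept
        with pytest.raises(ValueError, match="context"):
            fit_random_intercept_lmm(df, set_size="vss")

    def test_icc_definition(self):
        df = _lmm_data(4, sigma_b=0.4)
        res = fit_random_intercept_lmm(df, set_size="vss")
        expected = res.random_intercept_sd**2 / (
            res.random_intercept_sd**2 + res.residual_sd**2
        )
        assert res.icc == pytest.approx(expected, abs=1e-10)


class TestLikelihoodRatio:
    def test_identical_models_give_zero(self):
        df = _lmm_data(5)
        res = fit_random_intercept_lmm(df, set_size="vss")
        chi2, dof, p = likelihood_ratio_test(res, res)
        assert chi2 == 0.0 and dof == 0 and p == 1.0

    def test_nonnested_rejected(self):
        df = _lmm_data(6)
        full = fit_random_intercept_lmm(df, set_size="vss")
        other = fit_random_intercept_lmm(df.iloc[: len(df) // 2], set_size="vss")
        with pytest.raises(ValueError):
            likelihood_ratio_test(full, other)

    def test_aic_chi2_arithmetic_identity(self):
        """AIC_full <= AIC_null + 4 whenever chi2 >= 8 (2-df nesting)."""
        df = _lmm_data(7)
        null = fit_random_intercept_lmm(df, set_size=None)
        full = fit_random_intercept_lmm(df, set_size="vss")
        chi2, dof, _ = likelihood_ratio_test(null, full)
        if chi2 >= 8:
            assert full.aic <= null.aic + 4


class TestCompareForms:
    def test_no_set_size_effect_keeps_aics_close(self):
        df = _lmm_data(8, slope=0.0)
        comp = compare_forms_aic(df, axis="vss")
        assert abs(comp["delta_aic"]) < 6

    def test_report_fields(self):
        df = _lmm_data(9)
        comp = compare_forms_aic(df, axis="vss")
        assert comp["selected"] in ("linear", "log")
        assert comp["aic_linear"] == pytest.approx(comp["linear"].aic)


def _logistic_data(seed, n_p=30, n_t=50, intercept=1.5, vss_coef=-0.2, ctx_coef=0.1, sigma_b=0.6):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_p):
        b = rng.normal(0, sigma_b)
        for _ in range(n_t):
            vss = rng.choice(LEVELS)
            ctx = rng.random() < 0.5
            eta = intercept + vss_coef * vss + ctx_coef * ctx + b
            rows.append(
                dict(
                    participant_id=f"P{i:02d}",
                    vss=int(vss),
                    context_present=bool(ctx),
                    correct=int(rng.random() < expit(eta)),
                )
            )
    return pd.DataFrame(rows)


class TestRandomInterceptLogistic:
    def test_zero_variance_matches_plain_logistic(self):
        # draw chosen so the variance estimate collapses to (near) zero
        import statsmodels.api as sm

        df = _logistic_data(2, sigma_b=0.0)
        res = fit_random_intercept_logistic(df, set_size="vss")
        X = np.column_stack([np.ones(len(df)), df["context_present"], df["vss"]])
        ref = sm.Logit(df["correct"].to_numpy(), X).fit(disp=0)
        assert np.allclose(res.coefficients, ref.params, atol=1e-4)

    def test_negative_set_size_effects_give_odds_below_one(self):
        df = _logistic_data(2, vss_coef=-0.25)
        df["mss"] = df["vss"]  # same negative dependence on both set sizes
        res_v = fit_random_intercept_logistic(df, set_size="vss")
        res_m = fit_random_intercept_logistic(df, set_size="mss")
        for res in (res_v, res_m):
            row = res.odds_ratios[res.odds_ratios["term"].str.contains("ss")].iloc[0]
            assert row["odds_ratio"] < 1
            assert row["ci_high"] < 1

    def test_null_effect_ci_covers_one(self):
        covered = 0
        n_rep = 10
        for rep in range(n_rep):
            df = _logistic_data(100 + rep, vss_coef=0.0, ctx_coef=0.0, n_p=20, n_t=30)
            res = fit_random_intercept_logistic(df, set_size="vss")
            row = res.odds_ratios[res.odds_ratios["term"] == "vss"].iloc[0]
            if row["ci_low"] <= 1 <= row["ci_high"]:
                covered += 1
        assert covered >= int(0.8 * n_rep)

    def test_nonbinary_response_rejected(self):
        df = _logistic_data(3)
        df.loc[0, "correct"] = 2
        with pytest.raises(ValueError):
            fit_random_intercept_logistic(df, set_size="vss")
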