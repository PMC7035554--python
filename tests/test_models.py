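"""Regression models, LASSO selection and minute-scale back-transforms."""

import datetime as dt
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from orduration import (
    SyntheticConfig,
    backtransform_delta_minutes,
    backtransform_mean_minutes,
    fit_interaction_model,
    fit_model,
    generate_frame,
    lasso_select,
    model_i_spec,
    model_ii_spec,
    null_config,
    significance_code,
    truth_coefficients,
)
from orduration.models import ModelSpec


class TestBackTransform:
    """Minute-scale arithmetic on printed log-scale quantities."""

    @pytest.mark.parametrize(
        "intercept,coef,expect",
        [
            (4.97, -0.206, 117),  # first of four surgeries in a surgeon-day
            (4.97, -0.272, 110),  # surgeon F's mean duration
            (4.97, 0.0, 144),  # the baseline itself
        ],
    )
    def test_mean_minutes(self, intercept, coef, expect):
        assert backtransform_mean_minutes(intercept, coef) == expect

    def test_mean_minutes_identity_without_coefficient(self):
        assert backtransform_mean_minutes(4.0, rounded=False) == pytest.approx(np.exp(4.0))

    @pytest.mark.parametrize(
        "intercept,coef,expect",
        [
            (4.97, -0.094, 13),  # surgeon B vs the baseline surgeon
            (4.97, 0.0, 0),
            (4.97, -0.206, 27),  # exact arithmetic gives 26.9
        ],
    )
    def test_delta_minutes(self, intercept, coef, expect):
        assert backtransform_delta_minutes(intercept, coef) == expect

    def test_unrounded_values_are_retained(self):
        v = backtransform_delta_minutes(4.97, -0.206, rounded=False)
        assert v == pytest.approx(np.exp(4.97) - np.exp(4.764))
        assert round(v, 1) == 26.8


class TestFitModel:
    def test_zero_noise_limit_recovers_generating_coefficients(self):
        # sigma = 0: only minute rounding separates fit from truth
        cfg = replace(SyntheticConfig(), sigma=0.0)
        df, _ = generate_frame(cfg)
        fit = fit_model(df, model_i_spec(breakpoint=cfg.breakpoint))
        truth = truth_coefficients(cfg)
        for term, value in truth.items():
            assert fit.table.loc[term, "estimate"] == pytest.approx(value, abs=0.02), term
        assert fit.adj_r2 > 0.995

    def test_all_effects_zero_and_no_noise_gives_constant_duration(self):
        df, _ = generate_frame(null_config())
        assert (df["duration_min"] == 144.0).all()  # exp(4.97) ~ 143.97

    def test_ci_and_code_consistent_with_estimate_and_se(self, default_frame):
        df, _ = default_frame
        fit = fit_model(df, model_i_spec())
        t = fit.table
        tq = scipy.stats.t.ppf(0.975, fit.df_resid)
        assert np.allclose(t["ci_low"], t["estimate"] - tq * t["se"])
        assert np.allclose(t["ci_high"], t["estimate"] + tq * t["se"])
        p = 2 * scipy.stats.t.sf(np.abs(t["estimate"] / t["se"]), fit.df_resid)
        assert np.allclose(t["p"], p)
        assert all(significance_code(pv) == c for pv, c in zip(t["p"], t["code"]))

    def test_adjusted_r2_below_r2(self, default_frame):
        df, _ = default_frame
        fit = fit_model(df, model_i_spec())
        assert fit.adj_r2 <= fit.r2

    def test_reference_reencoding_preserves_fit(self, default_frame):
        df, _ = default_frame
        f_a = fit_model(df, model_i_spec(surgeon_ref="A"))
        f_b = fit_model(df, model_i_spec(surgeon_ref="B"))
        assert np.allclose(f_a.fitted, f_b.fitted)
        assert f_a.adj_r2 == pytest.approx(f_b.adj_r2)
        # coefficients shift by the old B effect
        b = f_a.table.loc["surgeon[B]", "estimate"]
        assert f_b.table.loc["surgeon[A]", "estimate"] == pytest.approx(-b)
        assert f_b.table.loc["surgeon[C]", "estimate"] == pytest.approx(
            f_a.table.loc["surgeon[C]", "estimate"] - b
        )

    def test_rank_deficiency_error_names_aliased_terms(self, default_frame):
        df, _ = default_frame
        df = df.copy()
        df["surgery_type"] = df["surgeon"]  # perfect aliasing
        with pytest.raises(ValueError, match="aliased.*surgery_type"):
            fit_model(df, model_i_spec())

    def test_caseload_and_position_never_coexist(self):
        with pytest.raises(ValueError, match="workload_form"):
            ModelSpec(workload_form="both")

    def test_surgeon_confounded_with_weekday_still_estimable(self):
        # one surgeon operates only on Tuesdays with an unusual type mix;
        # reference encoding must keep the design full rank
        rng = np.random.default_rng(5)
        n = 400
        base = pd.DataFrame(
            {
                "weekday": rng.choice(["Mon", "Tue", "Wed", "Sat"], n),
                "surgeon": rng.choice(["A", "B"], n),
                "surgery_type": rng.choice(["T1", "T2", "T3"], n),
                "anaesthetist": rng.choice(["X", "Y"], n),
                "or_daily_n": rng.integers(1, 7, n),
                "surgeon_daily_n": rng.integers(1, 5, n),
            }
        )
        oddball = base.sample(60, random_state=1).index
        base.loc[oddball, "surgeon"] = "Z"
        base.loc[oddball, "weekday"] = "Tue"
        base.loc[oddball, "surgery_type"] = rng.choice(["T3", "T4"], 60)
        base["log_duration"] = rng.normal(4.8, 0.4, n)
        fit = fit_model(base, model_i_spec())
        assert np.isfinite(fit.table["estimate"]).all()
        assert "surgeon[Z]" in fit.table.index


class TestModelEquivalence:
    def test_position_model_approximates_linear_caseload_truth(self, default_frame):
        # when the generating effect is linear in caseload k, the position
        # coefficients should track slope * (k - 1) within each k
        df, truth = default_frame
        slope = truth["coefficients"]["surgeon_daily_n"]
        fit = fit_model(df, model_ii_spec(4.0))
        for k in (2, 3):
            coefs = [
                fit.table.loc[f"position[{k}~{j}]", "estimate"] for j in range(1, k + 1)
            ]
            assert np.mean(coefs) == pytest.approx(slope * (k - 1), abs=0.08)


class TestInteractionModel:
    def test_generated_interaction_recovered_with_correct_sign(self):
        cfg = replace(
            SyntheticConfig(seed=11),
            mode="position",
            interaction_effects={"B:4~3": -0.434},
        )
        rng = np.random.default_rng(cfg.seed)
        hits = 0
        reps = 20
        for _ in range(reps):
            df, _ = generate_frame(replace(cfg, seed=int(rng.integers(2**31))))
            fit = fit_interaction_model(df, model_ii_spec(4.0))
            term = "surgeon[B]:position[4~3]"
            hits += term in fit.table.index and fit.table.loc[term, "estimate"] < 0
        assert hits >= int(0.9 * reps)

    def test_null_interactions_rarely_jointly_significant(self):
        # type-I error of the joint F-test for the interaction block
        cfg = replace(SyntheticConfig(seed=23), mode="position")
        rng = np.random.default_rng(cfg.seed)
        rejections = 0
        reps = 20
        for _ in range(reps):
            df, _ = generate_frame(replace(cfg, seed=int(rng.integers(2**31))))
            base = fit_model(df, model_ii_spec(4.0))
            full = fit_interaction_model(df, model_ii_spec(4.0))
            rss0 = float((base.resid**2).sum())
            rss1 = float((full.resid**2).sum())
            q = base.df_resid - full.df_resid
            f = ((rss0 - rss1) / q) / (rss1 / full.df_resid)
            p = scipy.stats.f.sf(f, q, full.df_resid)
            rejections += p < 0.05
        assert rejections <= 4  # ~1 expected at the nominal 5% level

    def test_single_surgeon_reduces_to_position_only_model(self, default_frame):
        df, _ = default_frame
        sub = df[df["surgeon"] == "A"]
        fit = fit_interaction_model(sub, model_ii_spec(4.0))
        assert not any(t.startswith("surgeon[") for t in fit.table.index)
        assert any(t.startswith("position[") for t in fit.table.index)


class TestLassoSelect:
    def test_zero_penalty_is_the_ols_limit_selecting_everything(self, default_frame):
        df, _ = default_frame
        sel = lasso_select(df, model_i_spec(), alpha=0.0)
        assert sel.selected == sel.candidates

    def test_large_penalty_selects_nothing(self, default_frame):
        df, _ = default_frame
        sel = lasso_select(df, model_i_spec(), alpha=10.0)
        assert sel.selected == []

    def test_cv_selection_deterministic_given_seed(self, default_frame):
        df, _ = default_frame
        s1 = lasso_select(df, model_i_spec(), seed=3)
        s2 = lasso_select(df, model_i_spec(), seed=3)
        assert s1.alpha == s2.alpha and s1.selected == s2.selected

    def test_strong_effects_always_survive_cv_selection(self):
        # strong generating effects (surgeon F, the big type contrasts,
        # the workload terms) should essentially always be selected
        rng = np.random.default_rng(17)
        must_keep = [
            "surgery_type[Esophageal cancer]",
            "surgery_type[Thoracoscopic pulmonary bullous resection]",
            "surgeon[F]",
        ]
        reps = 15
        hits = dict.fromkeys(must_keep, 0)
        for _ in range(reps):
            df, _ = generate_frame(SyntheticConfig(seed=int(rng.integers(2**31))))
            sel = lasso_select(df, model_i_spec(), seed=0)
            for t in must_keep:
                hits[t] += t in sel.selected
        for t, h in hits.items():
            assert h >= reps - 1, t

    def test_constant_outcome_rejected(self, default_frame):
        df, _ = default_frame
        df = df.copy()
        df["log_duration"] = 4.97
        with pytest.raises(ValueError, match="variance"):
            lasso_select(df, model_i_spec())
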