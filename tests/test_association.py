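"""Odds-ratio models, collinearity diagnostics, multinomial sensitivity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gaitpain as gp
from gaitpain.errors import InsufficientDataError


def two_by_two(a, b, c, d):
    """Exposure x outcome counts as an analysis frame."""
    y = np.repeat([1, 1, 0, 0], [a, b, c, d])
    x = np.repeat([1.0, 0.0, 1.0, 0.0], [a, b, c, d])
    return pd.DataFrame({"outcome2": y.astype(float), "x": x})


class TestBinaryLogistic:
    def test_contingency_table_or_matches_closed_form(self):
        block = gp.fit_binary_logistic(two_by_two(30, 70, 15, 85), ["x"])
        assert block.loc[0, "odds_ratio"] == pytest.approx(
            (30 * 85) / (70 * 15), rel=1e-6
        )

    def test_wald_ci_formula(self):
        block = gp.fit_binary_logistic(two_by_two(30, 70, 15, 85), ["x"])
        z = stats.norm.ppf(0.975)
        b, se = block.loc[0, "coef"], block.loc[0, "se"]
        assert block.loc[0, "ci_low"] == pytest.approx(np.exp(b - z * se), abs=1e-9)
        assert block.loc[0, "ci_high"] == pytest.approx(np.exp(b + z * se), abs=1e-9)
        assert block.loc[0, "ci_low"] <= block.loc[0, "odds_ratio"] <= block.loc[0, "ci_high"]

    def test_standardizing_rescales_or_but_not_deviance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2.5, 1500)
        y = (rng.random(1500) < 1 / (1 + np.exp(-(-0.5 + 0.4 * x)))).astype(float)
        raw = pd.DataFrame({"outcome2": y, "x": x})
        std = pd.DataFrame({"outcome2": y, "x": (x - x.mean()) / x.std(ddof=1)})
        import statsmodels.api as sm
        ll_raw = sm.Logit(y, sm.add_constant(raw[["x"]])).fit(disp=0).llf
        ll_std = sm.Logit(y, sm.add_constant(std[["x"]])).fit(disp=0).llf
        assert ll_raw == pytest.approx(ll_std, abs=1e-6)
        b1 = gp.fit_binary_logistic(raw, ["x"]).loc[0, "odds_ratio"]
        b2 = gp.fit_binary_logistic(std, ["x"]).loc[0, "odds_ratio"]
        assert b2 == pytest.approx(b1 ** x.std(ddof=1), rel=1e-3)

    def test_outcome_inversion_inverts_or(self):
        df = two_by_two(30, 70, 15, 85)
        flipped = df.assign(outcome2=1.0 - df["outcome2"])
        o1 = gp.fit_binary_logistic(df, ["x"]).loc[0, "odds_ratio"]
        o2 = gp.fit_binary_logistic(flipped, ["x"]).loc[0, "odds_ratio"]
        assert o1 * o2 == pytest.approx(1.0, abs=1e-6)


class TestCollinearity:
    def test_orthogonal_predictors_unflagged(self):
        rng = np.random.default_rng(1)
        raw = np.column_stack([np.ones(300), rng.normal(size=(300, 3))])
        q, _ = np.linalg.qr(raw)
        df = pd.DataFrame(q[:, 1:], columns=list("abc"))  # orthogonal, mean 0
        diag = gp.collinearity_diagnostics(df, ["a", "b", "c"])
        assert diag["flags"] == []
        np.testing.assert_allclose(diag["vif"].to_numpy(), 1.0, atol=1e-9)

    def test_duplicated_column_triggers_correlation_flag(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(size=200)})
        df["b"] = df["a"]
        df["c"] = rng.normal(size=200)
        diag = gp.collinearity_diagnostics(df, ["a", "b", "c"])
        assert any("|r|>0.80" in f for f in diag["flags"])

    def test_near_duplicate_triggers_vif_flag(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=2000)
        df = pd.DataFrame({"a": a, "b": a + 0.1 * rng.normal(size=2000),
                           "c": rng.normal(size=2000)})
        diag = gp.collinearity_diagnostics(df, ["a", "b", "c"])
        assert any("VIF>10" in f for f in diag["flags"])
        assert any("tolerance<0.10" in f for f in diag["flags"])

    def test_tolerance_is_reciprocal_vif(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        df["d"] = df["a"] * 0.5 + df["d"]
        diag = gp.collinearity_diagnostics(df, list("abcd"))
        np.testing.assert_allclose(
            diag["tolerance"].to_numpy(), 1.0 / diag["vif"].to_numpy(), atol=1e-9
        )

    def test_constant_column_flagged_and_excluded(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"a": rng.normal(size=100), "b": rng.normal(size=100),
                           "k": 1.0})
        diag = gp.collinearity_diagnostics(df, ["a", "b", "k"])
        assert any("constant" in f for f in diag["flags"])
        assert "k" not in diag["vif"].index


def three_category_cohort(seed, speed_beta_modsev=0.0, n=2000):
    spec = gp.CohortSpec(
        n_participants=n,
        coefficients={"sample_entropy": float(np.log(0.7))},
        intercept=-1.2,
        coefficients_modsev={"gait_speed": speed_beta_modsev},
        intercept_modsev=-2.2,
        seed=seed,
    )
    parts, feats, _ = gp.generate_cohort(spec)
    analysis, _ = gp.assemble_analysis_table(parts, feats)
    return analysis


class TestMultinomial:
    def test_two_category_input_reproduces_binary_model(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=1200)
        y = (rng.random(1200) < 1 / (1 + np.exp(-(-1.0 + 0.5 * x)))).astype(int)
        df = pd.DataFrame({
            "x": x,
            "outcome2": np.where(y == 1, "mild_unilateral", "no_pain"),
            "outcome3": np.where(y == 1, "mild_unilateral", "no_pain"),
        })
        binary = gp.fit_binary_logistic(df, ["x"])
        multi = gp.fit_multinomial_sensitivity(df, ["x"])
        assert multi.loc[0, "odds_ratio"] == pytest.approx(
            binary.loc[0, "odds_ratio"], abs=1e-6
        )

    def test_severe_only_speed_effect_pattern(self):
        """A speed effect confined to the moderate/severe contrast shows up
        there and not in the mild contrast."""
        agree = 0
        reps = 10
        for seed in range(reps):
            analysis = three_category_cohort(100 + seed,
                                             speed_beta_modsev=float(np.log(0.5)))
            block = gp.fit_multinomial_sensitivity(analysis, ["gait_speed",
                                                              "sample_entropy"])
            speed = block[block["variable"] == "gait_speed"].set_index("contrast")
            sev_or = speed.loc["modsev_vs_no_pain", "odds_ratio"]
            mild_ci = (speed.loc["mild_vs_no_pain", "ci_low"],
                       speed.loc["mild_vs_no_pain", "ci_high"])
            if sev_or < 1.0 and mild_ci[0] <= 1.0 <= mild_ci[1]:
                agree += 1
        assert agree >= 0.8 * reps

    def test_empty_category_rejected(self):
        df = pd.DataFrame({"x": [0.1, 0.2, 0.3],
                           "outcome3": [np.nan, np.nan, np.nan]})
        with pytest.raises(InsufficientDataError):
            gp.fit_multinomial_sensitivity(df, ["x"])


def po_frame(rng, n=600, diverge=False):
    X = rng.normal(size=(n, 3))
    b = np.array([0.8, -0.5, 0.3])
    if not diverge:
        eta = X @ b
        u = rng.random(n)
        p0 = 1 / (1 + np.exp(-(-0.5 - eta)))
        p01 = 1 / (1 + np.exp(-(1.0 - eta)))
        y = np.where(u < p0, 0, np.where(u < p01, 1, 2))
    else:
        l1 = 0.2 + X @ b
        l2 = -0.5 + X @ (-b)
        den = 1 + np.exp(l1) + np.exp(l2)
        u = rng.random(n)
        y = np.where(u < np.exp(l1) / den, 1,
                     np.where(u < (np.exp(l1) + np.exp(l2)) / den, 2, 0))
    labels = np.array(["no_pain", "mild_unilateral", "modsev_unilateral"])[y]
    df = pd.DataFrame(X, columns=["a", "b", "c"])
    df["outcome3"] = labels
    return df


class TestProportionalOdds:
    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            gp.proportional_odds_check(po_frame(rng), ["a", "b", "c"])["p_value"] < 0.05
            for _ in range(60)
        )
        assert 0.0 <= rejections / 60 <= 0.12

    def test_power_against_divergent_slopes(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            gp.proportional_odds_check(po_frame(rng, diverge=True),
                                       ["a", "b", "c"])["p_value"] < 0.05
            for _ in range(15)
        )
        assert rejections / 15 >= 0.8

    def test_two_category_input_rejected(self):
        rng = np.random.default_rng(2)
        df = po_frame(rng)
        df = df[df["outcome3"] != "modsev_unilateral"]
        with pytest.raises(InsufficientDataError):
            gp.proportional_odds_check(df, ["a", "b", "c"])
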