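"""Replicators: re-running prior studies' procedures on (simulated) data."""

import numpy as np
import pandas as pd
import pytest

from gma.model_core import BetweenStudySpec, BetweenStudyStat, GMAError, SignatureVector
from gma.replicators import (
    anova_signatures,
    between_study_statistics,
    discretize,
    effect_size_signatures,
    logistic_signatures,
    ols_signatures,
)


class TestOLS:
    def test_exact_fit(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        res = ols_signatures(X, [1.0, 3.0, 5.0], ["x"], include=("coefs", "mse", "r2"))
        assert res.converged
        d = res.signatures.as_dict()
        assert d["intercept"] == pytest.approx(1.0, abs=1e-12)
        assert d["b:x"] == pytest.approx(2.0, abs=1e-12)
        assert d["mse"] == pytest.approx(0.0, abs=1e-12)
        assert d["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_hand_normal_equations_oracle(self):
        # X=(0,1,2), y=(1,3,6): intercept 5/6, slope 5/2, SSE/(n-p) = 1/6
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        res = ols_signatures(X, [1.0, 3.0, 6.0], ["x"])
        d = res.signatures.as_dict()
        assert d["intercept"] == pytest.approx(5 / 6)
        assert d["b:x"] == pytest.approx(5 / 2)
        assert d["mse"] == pytest.approx(1 / 6)

    def test_constant_outcome_degenerate(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        res = ols_signatures(X, np.full(4, 2.5), ["x"], include=("coefs", "mse", "r2"))
        d = res.signatures.as_dict()
        assert d["b:x"] == pytest.approx(0.0, abs=1e-12)
        assert d["r2"] == 0.0  # defined as 0, not NaN

    def test_rank_deficiency_flagged_not_zero_filled(self, rng):
        X = pd.DataFrame({"a": np.ones(10), "b": np.ones(10)})
        res = ols_signatures(X, rng.standard_normal(10), ["a", "b"])
        assert not res.converged
        assert res.signatures is None
        assert "rank" in res.notes

    def test_statsmodels_agreement_on_random_datasets(self, rng):
        import statsmodels.api as sm

        for _ in range(50):
            n, k = int(rng.integers(12, 40)), int(rng.integers(1, 4))
            X = pd.DataFrame(rng.standard_normal((n, k)),
                             columns=[f"x{i}" for i in range(k)])
            y = rng.standard_normal(n)
            res = ols_signatures(X, y, list(X.columns), include=("coefs", "mse", "r2"))
            fit = sm.OLS(y, sm.add_constant(X.to_numpy())).fit()
            mine = res.signatures.values
            theirs = np.concatenate([fit.params, [fit.mse_resid, fit.rsquared]])
            assert np.max(np.abs(mine - theirs)) < 1e-8


class TestLogistic:
    def test_saturated_2x2_closed_form(self):
        # 10/20 successes at x=0, 15/20 at x=1 -> intercept 0, slope ln 3
        x = np.repeat([0.0, 1.0], 20)
        y = np.concatenate([np.repeat([1.0, 0.0], [10, 10]), np.repeat([1.0, 0.0], [15, 5])])
        res = logistic_signatures(pd.DataFrame({"x": x}), y, ["x"])
        assert res.converged
        d = res.signatures.as_dict()
        assert d["intercept"] == pytest.approx(0.0, abs=1e-7)
        assert d["b:x"] == pytest.approx(np.log(3.0), abs=1e-7)

    def test_null_slope_at_large_n(self, rng):
        x = rng.standard_normal(10_000)
        y = (rng.random(10_000) < 0.5).astype(float)  # independent of x
        res = logistic_signatures(pd.DataFrame({"x": x}), y, ["x"])
        assert abs(res.signatures["b:x"]) < 3 * 2 / np.sqrt(10_000)

    def test_subset_permutation_equivariance(self, rng):
        X = pd.DataFrame(rng.standard_normal((200, 2)), columns=["a", "b"])
        eta = 0.3 + 0.8 * X["a"] - 0.5 * X["b"]
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
        r1 = logistic_signatures(X, y, ["a", "b"]).signatures
        r2 = logistic_signatures(X, y, ["b", "a"]).signatures
        assert r1["b:a"] == pytest.approx(r2["b:a"], abs=1e-9)
        assert r1["b:b"] == pytest.approx(r2["b:b"], abs=1e-9)

    def test_separation_flagged(self):
        x = np.concatenate([-1 - np.arange(10.0), 1 + np.arange(10.0)])
        y = (x > 0).astype(float)  # perfectly separated
        res = logistic_signatures(pd.DataFrame({"x": x}), y, ["x"])
        assert not res.converged
        assert res.signatures is None

    def test_single_class_flagged(self):
        res = logistic_signatures(pd.DataFrame({"x": np.arange(10.0)}), np.ones(10), ["x"])
        assert not res.converged

    def test_statsmodels_agreement_on_random_datasets(self, rng):
        import statsmodels.api as sm

        checked = 0
        while checked < 50:
            n, k = int(rng.integers(60, 150)), int(rng.integers(1, 3))
            X = pd.DataFrame(rng.standard_normal((n, k)),
                             columns=[f"x{i}" for i in range(k)])
            eta = 0.2 + X.to_numpy() @ rng.uniform(-1, 1, k)
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            res = logistic_signatures(X, y, list(X.columns))
            if not res.converged:
                continue
            fit = sm.Logit(y, sm.add_constant(X.to_numpy())).fit(disp=0)
            assert np.max(np.abs(res.signatures.values - fit.params)) < 1e-6
            checked += 1


class TestDiscretize:
    def test_tercile_counts_on_1_to_100(self):
        levels = discretize(np.arange(1.0, 101.0), (33, 66))
        assert np.bincount(levels)[1:].tolist() == [33, 33, 34]

    def test_median_split(self):
        assert discretize(np.array([1.0, 2.0, 3.0, 4.0]), (50,)).tolist() == [1, 1, 2, 2]

    def test_monotone_transform_invariance(self, rng):
        v = rng.standard_normal(200)
        a = discretize(v, (25, 50, 75))
        b = discretize(np.exp(v), (25, 50, 75))
        assert np.array_equal(a, b)

    def test_degenerate_values_error(self):
        with pytest.raises(GMAError, match="degenerate"):
            discretize(np.ones(10), (50,))

    def test_bad_cutpoints_error(self):
        with pytest.raises(GMAError):
            discretize(np.arange(10.0), (66, 33))


class TestAnova:
    def test_one_way_hand_table_oracle(self):
        # 30 obs, 3 balanced levels, y identical within level at 0/1/2:
        # grand 1, effects (-1,0,1), MSE 0, MST = (10+0+10)/2 = 10
        x = np.arange(1.0, 31.0)
        y = np.repeat([0.0, 1.0, 2.0], 10)
        res = anova_signatures(pd.DataFrame({"x": x}), y, [("x", (100 / 3, 200 / 3))])
        d = res.signatures.as_dict()
        assert d["grand_mean"] == pytest.approx(1.0)
        assert [d["eff:x:1"], d["eff:x:2"], d["eff:x:3"]] == pytest.approx([-1, 0, 1])
        assert d["mst:x"] == pytest.approx(10.0)
        assert d["mse"] == pytest.approx(0.0, abs=1e-12)

    def test_globally_constant_outcome(self):
        x = np.arange(1.0, 31.0)
        res = anova_signatures(pd.DataFrame({"x": x}), np.full(30, 4.0), [("x", (33, 66))])
        d = res.signatures.as_dict()
        assert d["mst:x"] == pytest.approx(0.0, abs=1e-12)
        assert d["mse"] == pytest.approx(0.0, abs=1e-12)
        assert d["eff:x:1"] == pytest.approx(0.0, abs=1e-12)

    def test_signature_counts_6_7_11(self, rng):
        X = pd.DataFrame(rng.standard_normal((100, 2)), columns=["x1", "x2"])
        y = rng.standard_normal(100)
        r1 = anova_signatures(X, y, [("x1", (33, 66))])
        r2 = anova_signatures(X, y, [("x2", (25, 50, 75))])
        r3 = anova_signatures(X, y, [("x1", (33, 66)), ("x2", (25, 50, 75))])
        assert (len(r1.signatures), len(r2.signatures), len(r3.signatures)) == (6, 7, 11)

    def test_two_way_against_statsmodels_type2(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        X = pd.DataFrame(rng.standard_normal((120, 2)), columns=["x1", "x2"])
        y = 1 + X["x1"] + X["x2"] + rng.standard_normal(120)
        res = anova_signatures(X, y.to_numpy(), [("x1", (33, 66)), ("x2", (25, 50, 75))])
        d = res.signatures.as_dict()
        df = pd.DataFrame({
            "y": y,
            "a": discretize_levels(X["x1"], (33, 66)),
            "b": discretize_levels(X["x2"], (25, 50, 75)),
        })
        fit = smf.ols("y ~ C(a, Sum) + C(b, Sum)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert d["mst:x1"] == pytest.approx(
            table.loc["C(a, Sum)", "sum_sq"] / table.loc["C(a, Sum)", "df"], rel=1e-8)
        assert d["mst:x2"] == pytest.approx(
            table.loc["C(b, Sum)", "sum_sq"] / table.loc["C(b, Sum)", "df"], rel=1e-8)
        assert d["mse"] == pytest.approx(fit.mse_resid, rel=1e-8)
        # sum-to-zero effects match the Sum-coded coefficients
        assert d["grand_mean"] == pytest.approx(fit.params["Intercept"], rel=1e-8)
        assert d["eff:x1:1"] == pytest.approx(fit.params["C(a, Sum)[S.1]"], rel=1e-8)

    def test_interaction_term_against_statsmodels(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        X = pd.DataFrame(rng.standard_normal((150, 2)), columns=["x1", "x2"])
        y = (1 + X["x1"] * X["x2"] + rng.standard_normal(150)).to_numpy()
        res = anova_signatures(X, y, [("x1", (33, 66)), ("x2", (50,))],
                               include_interaction=True)
        d = res.signatures.as_dict()
        df = pd.DataFrame({
            "y": y,
            "a": discretize_levels(X["x1"], (33, 66)),
            "b": discretize_levels(X["x2"], (50,)),
        })
        fit = smf.ols("y ~ C(a, Sum) * C(b, Sum)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        key = "C(a, Sum):C(b, Sum)"
        assert d["mst:x1*x2"] == pytest.approx(
            table.loc[key, "sum_sq"] / table.loc[key, "df"], rel=1e-6)
        assert d["mse"] == pytest.approx(fit.mse_resid, rel=1e-8)

    def test_empty_cell_not_converged(self):
        x = np.concatenate([np.zeros(5) + np.arange(5) * 1e-3, [100.0]])
        # cutpoint layout leaves a middle bin empty for suitable data
        res = anova_signatures(pd.DataFrame({"x": np.array([1, 1.01, 1.02, 1.03, 50, 50.01])}),
                               np.arange(6.0), [("x", (40, 45))])
        assert not res.converged


def discretize_levels(col, cuts):
    from gma.replicators import discretize

    return discretize(col.to_numpy(), cuts)


class TestEffectSizes:
    def test_packaging(self):
        out = effect_size_signatures([0.3], [0.01])
        assert len(out) == 1
        assert out[0].as_dict() == {"effect": 0.3, "within_var": 0.01}

    def test_five_studies_ten_signatures(self):
        out = effect_size_signatures(np.linspace(0, 1, 5), np.full(5, 0.02))
        assert sum(len(sv) for sv in out) == 10

    def test_empty_and_nonpositive_variance_errors(self):
        with pytest.raises(GMAError):
            effect_size_signatures([], [])
        with pytest.raises(GMAError, match="positive"):
            effect_size_signatures([0.1], [0.0])


class TestBetweenStudy:
    def _spec(self):
        return BetweenStudySpec((BetweenStudyStat("var:effect", "variance", "effect"),))

    def test_identical_effects_zero_variance(self):
        svs = [SignatureVector(("effect",), [0.4]) for _ in range(4)]
        out = between_study_statistics(svs, self._spec())
        assert out["var:effect"] == pytest.approx(0.0, abs=1e-15)

    def test_hand_sample_variance(self):
        svs = [SignatureVector(("effect",), [v]) for v in (0.1, 0.3, 0.5)]
        out = between_study_statistics(svs, self._spec())
        assert out["var:effect"] == pytest.approx(0.04)  # denominator L-1

    def test_single_study_undefined(self):
        with pytest.raises(GMAError, match="undefined"):
            between_study_statistics([SignatureVector(("effect",), [0.1])], self._spec())

    def test_missing_label_is_named_error(self):
        svs = [SignatureVector(("other",), [0.1])] * 3
        with pytest.raises(GMAError, match="effect"):
            between_study_statistics(svs, self._spec())
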