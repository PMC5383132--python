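"""Estimator core: stacked errors, weighting, simulation plans, fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gma.estimator import (
    GMAEstimator,
    SignatureSimulator,
    SimulationPlan,
    UnderIdentifiedError,
    WeightMatrix,
    WeightUpdateError,
    fit_gma,
    initial_weight,
    objective,
    signature_error,
    simulate_signatures,
    update_weight,
)
from gma.model_core import (
    BetweenStudySpec,
    BetweenStudyStat,
    GMAError,
    PriorStudy,
    SignatureVector,
    build_meta_model,
)
from gma.replicators import ols_signatures


def _ols_study(study_id, subset, sigs, moments, n_obs=100, **options):
    return PriorStudy(
        study_id=study_id, n_obs=n_obs, covariate_subset=subset,
        replicator_kind="ols", replicator_options={"include_mse": True, **options},
        empirical_signatures=sigs, covariate_moments=moments,
    )


class TestSignatureError:
    def test_identical_gives_zero(self):
        sv = SignatureVector(("a", "b"), [1.0, 2.0])
        e = signature_error(sv, [sv, sv])
        assert np.array_equal(e.values, [0.0, 0.0])

    def test_mean_over_replicates(self):
        emp = SignatureVector(("a", "b"), [2.0, 2.0])
        sims = [SignatureVector(("a", "b"), [1.0, 1.0]),
                SignatureVector(("a", "b"), [3.0, 3.0])]
        assert np.array_equal(signature_error(emp, sims).values, [0.0, 0.0])

    def test_simple_difference(self):
        emp = SignatureVector(("a", "b"), [1.0, 2.0])
        sims = [SignatureVector(("a", "b"), [0.5, 2.5])]
        assert signature_error(emp, sims).values == pytest.approx([0.5, -0.5])

    def test_label_mismatch_lists_offender(self):
        emp = SignatureVector(("a",), [1.0])
        with pytest.raises(GMAError, match="do not match"):
            signature_error(emp, [SignatureVector(("z",), [1.0])])


class TestObjective:
    def test_zero_error(self):
        assert objective(np.zeros(3), WeightMatrix(np.eye(3))) == 0.0

    def test_identity_weight(self):
        assert objective(np.array([1.0, 2.0]), WeightMatrix(np.eye(2))) == 5.0

    def test_diagonal_weight(self):
        W = WeightMatrix(np.diag([4.0, 9.0]))
        assert objective(np.array([1.0, 1.0]), W) == 13.0

    def test_asymmetric_weight_rejected(self):
        with pytest.raises(GMAError, match="symmetric"):
            objective(np.ones(2), np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_permutation_invariance(self, rng):
        e = rng.standard_normal(6)
        A = rng.standard_normal((6, 6))
        W = A @ A.T
        perm = rng.permutation(6)
        assert objective(e[perm], W[np.ix_(perm, perm)]) == pytest.approx(
            objective(e, W), rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=8))
    def test_nonnegative_under_psd_weight(self, vals):
        e = np.asarray(vals)
        rng = np.random.default_rng(len(vals))
        A = rng.standard_normal((e.size, e.size))
        assert objective(e, A @ A.T) >= -1e-8


class TestInitialWeight:
    def test_reciprocal_square_formula(self):
        W = initial_weight(SignatureVector(("a", "b"), [2.0, 0.5]))
        assert np.allclose(np.diag(W.matrix), [0.25, 4.0])
        assert W.provenance == "initial-diagonal"

    def test_floor_handles_zeros(self):
        W = initial_weight(np.array([0.0]), floor=1e-6)
        assert W.matrix[0, 0] == pytest.approx(1e12)

    def test_unit_signatures_give_identity(self):
        W = initial_weight(np.array([1.0, -1.0, 1.0]))
        assert np.array_equal(W.matrix, np.eye(3))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=6))
    def test_diagonal_and_psd(self, vals):
        W = initial_weight(np.asarray(vals)).matrix
        assert np.array_equal(W, np.diag(np.diag(W)))
        assert (np.diag(W) > 0).all()


def _effect_study(study_id, n_obs):
    return PriorStudy(
        study_id=study_id, n_obs=n_obs, covariate_subset=(),
        replicator_kind="effect_size", replicator_options={"include_within": False},
        empirical_signatures=SignatureVector(("effect",), [0.0]),
    )


class TestUpdateWeight:
    def test_analytic_variance_oracle(self):
        # effect signatures of mean-only studies: Var = sigma_w^2 / n_l.
        # sigma_w = 20, n = (100, 400) -> variances (4, 1) -> W ~ diag(1/4, 1)
        model = build_meta_model("random_effects")
        beta = {"mu": 0.0, "tau": 0.0, "sigma_w": 20.0}
        studies = [_effect_study("s1", 100), _effect_study("s2", 400)]
        plan = SimulationPlan(seed=5)
        W, sigma = update_weight(model, beta, studies, plan, n_reps=2000)
        assert W.provenance == "simulated-inverse-covariance"
        assert np.diag(sigma) == pytest.approx([4.0, 1.0], rel=0.12)
        assert np.diag(W.matrix) == pytest.approx([0.25, 1.0], rel=0.12)

    def test_perfect_collinearity_without_ridge_errors(self):
        # a between-study "mean" of a single study's effect duplicates it exactly
        model = build_meta_model("random_effects")
        study = _effect_study("s1", 50)
        between = BetweenStudySpec(
            (BetweenStudyStat("m", "mean", "effect"),),
            SignatureVector(("m",), [0.0]),
        )
        with pytest.raises(WeightUpdateError):
            update_weight(model, {"mu": 0.0, "tau": 0.0, "sigma_w": 1.0}, [study],
                          SimulationPlan(seed=3), n_reps=300, ridge=0.0,
                          between=between)

    def test_large_ridge_limits_to_diagonal(self):
        model = build_meta_model("random_effects")
        studies = [_effect_study("s1", 50)]
        # effect + within_var are correlated in general; huge ridge kills it
        studies[0].replicator_options = {"include_within": True}
        studies[0].empirical_signatures = SignatureVector(("effect", "within_var"), [0, 1])
        W, _ = update_weight(model, {"mu": 0.0, "tau": 0.3, "sigma_w": 1.0}, studies,
                             SimulationPlan(seed=4), n_reps=500, ridge=1e6)
        off = abs(W.matrix[0, 1])
        assert off < 1e-3 * min(W.matrix[0, 0], W.matrix[1, 1])


class TestSimulateSignatures:
    def _setup(self, sigma=0.0):
        model = build_meta_model("linear", ("x1", "x2"))
        beta = model.make_parameters(
            {"intercept": 1.0, "b:x1": 2.0, "b:x2": -1.0, "sigma": sigma})
        moments = (np.zeros(2), np.eye(2))
        study = _ols_study("s1", ("x1", "x2"),
                           SignatureVector(("intercept", "b:x1", "b:x2", "mse"),
                                           [1.0, 2.0, -1.0, sigma**2]),
                           moments, n_obs=60)
        return model, beta, [study]

    def test_zero_noise_recovers_beta_every_replicate(self):
        model, beta, studies = self._setup(sigma=0.0)
        out = simulate_signatures(model, beta, studies, SimulationPlan(n_sim=8, seed=2))
        for sv in out:
            assert sv["s1::intercept"] == pytest.approx(1.0, abs=1e-10)
            assert sv["s1::b:x1"] == pytest.approx(2.0, abs=1e-10)
            assert sv["s1::b:x2"] == pytest.approx(-1.0, abs=1e-10)
            assert sv["s1::mse"] == pytest.approx(0.0, abs=1e-12)

    def test_same_plan_identical_output(self):
        model, beta, studies = self._setup(sigma=0.7)
        a = simulate_signatures(model, beta, studies, SimulationPlan(n_sim=5, seed=9))
        b = simulate_signatures(model, beta, studies, SimulationPlan(n_sim=5, seed=9))
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.values, sb.values)

    def test_common_random_numbers_bit_reproducible(self):
        model, beta, studies = self._setup(sigma=0.5)
        sim = SignatureSimulator(model, studies, None, SimulationPlan(n_sim=20, seed=1))
        m1, _, _ = sim.mean_signatures(beta.as_dict(), 20)
        m2, _, _ = sim.mean_signatures(beta.as_dict(), 20)
        assert np.array_equal(m1, m2)


class TestFit:
    def test_noiseless_self_consistency(self, rng):
        # one study containing all predictors, zero-noise signatures:
        # the fit reproduces the generating coefficients to optimizer tolerance
        model = build_meta_model("linear", ("x1", "x2"))
        truth = {"intercept": 0.5, "b:x1": 2.0, "b:x2": -1.5, "sigma": 0.0}
        X = rng.standard_normal((80, 2))
        y = 0.5 + 2.0 * X[:, 0] - 1.5 * X[:, 1]
        res = ols_signatures(pd.DataFrame(X, columns=["x1", "x2"]), y, ["x1", "x2"])
        study = _ols_study("s1", ("x1", "x2"), res.signatures,
                           (X.mean(axis=0), np.cov(X.T, ddof=1)), n_obs=80)
        est = GMAEstimator(model=model, rounds=0, n_starts=2, n_sim=20,
                           n_sim_final=20, seed=7,
                           start=model.make_parameters(
                               {"intercept": 0.0, "b:x1": 1.0, "b:x2": 0.0, "sigma": 0.5}))
        est.fit([study])
        for name in ("intercept", "b:x1", "b:x2"):
            assert est.beta_hat_[name] == pytest.approx(truth[name], abs=1e-4)
        assert est.beta_hat_["sigma"] == pytest.approx(0.0, abs=1e-3)
        assert est.objective_value_ < 1e-8

    def test_under_identification_refused(self):
        model = build_meta_model("linear", ("x1", "x2", "x3"))  # 5 params
        study = _ols_study("s1", ("x1",),
                           SignatureVector(("intercept", "b:x1", "mse"), [0, 1, 1]),
                           (np.zeros(3), np.eye(3)))
        with pytest.raises(UnderIdentifiedError):
            GMAEstimator(model=model).fit([study])

    def test_get_set_params_round_trip(self):
        est = GMAEstimator(n_sim=12, rounds=1)
        params = est.get_params()
        assert params["n_sim"] == 12
        est.set_params(n_sim=33)
        assert est.n_sim == 33
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_predict_requires_fit(self):
        est = GMAEstimator(model=build_meta_model("linear", ("x1",)))
        with pytest.raises(GMAError, match="not fitted"):
            est.predict(pd.DataFrame({"x1": [0.0]}))

    def test_efficiency_of_updated_weight(self):
        # two full-design OLS studies with very different sample sizes: the
        # initial magnitude-based diagonal weight treats them alike, the
        # simulated inverse-covariance weight downweights the small study,
        # reducing the sampling variance of the estimates
        from gma.scenarios import _seed_int

        model = build_meta_model("linear", ("x1",))
        var_r0, var_r2 = [], []
        for r in range(30):
            rng = np.random.default_rng(_seed_int(77, r))
            studies = []
            for sid, n in (("small", 25), ("big", 800)):
                X = rng.standard_normal((n, 1))
                y = 1.0 + 2.0 * X[:, 0] + rng.standard_normal(n)
                res = ols_signatures(pd.DataFrame(X, columns=["x1"]), y, ["x1"])
                studies.append(_ols_study(sid, ("x1",), res.signatures,
                                          (X.mean(axis=0), np.atleast_2d(np.cov(X.T, ddof=1))),
                                          n_obs=n))
            start = model.make_parameters({"intercept": 1.0, "b:x1": 2.0, "sigma": 1.0})
            common = dict(model=model, start=start, n_sim=30, n_sim_final=60,
                          n_starts=1, seed=_seed_int(78, r), weight_reps=300)
            e0 = GMAEstimator(rounds=0, **common).fit(studies)
            e2 = GMAEstimator(rounds=2, **common).fit(studies)
            var_r0.append(e0.params_[:2])
            var_r2.append(e2.params_[:2])
        v0 = np.var(np.asarray(var_r0), axis=0, ddof=1).sum()
        v2 = np.var(np.asarray(var_r2), axis=0, ddof=1).sum()
        assert v2 <= v0

    def test_chi0_invariant_to_signature_rescaling(self):
        # expressing one signature in different units (x10) while transforming
        # the weight matrix accordingly leaves the goodness of fit unchanged
        from gma.scenarios import generate_scenario

        model, studies, truth, _ = generate_scenario(1, seed=21)
        kwargs = dict(model=model, start=truth, n_sim=30, n_sim_final=150,
                      rounds=2, n_starts=1, seed=5, weight_reps=800)
        fit = GMAEstimator(**kwargs).fit(studies).fit_result_
        base = fit.chi0
        K = len(fit.error)
        T = np.eye(K)
        idx = list(fit.labels).index("study1::mse")
        T[idx, idx] = 10.0
        e_scaled = T @ fit.error
        Tinv = np.linalg.inv(T)
        W_scaled = Tinv @ fit.weight.matrix @ Tinv
        chi_scaled = fit.n_sim_final / (1 + fit.n_sim_final) * e_scaled @ W_scaled @ e_scaled
        assert chi_scaled == pytest.approx(base, rel=1e-9)
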