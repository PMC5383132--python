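"""Synthetic validation scenarios: generate "prior studies" from a known truth.

Each scenario specifies a true data-generating process, draws raw data from
it, runs each imitation prior study's statistical procedure once to produce
its "published" signatures (literature noise included), and packages the
study descriptions the aggregation estimator needs.  The truth is recorded so
recovery can be scored.

The seven scenario families:

1. linear truth ``y = 1 + x1 + x2 + x3 + e``, three two-predictor OLS priors
   (coefficients + MSE, 12 signatures);
2. same truth, three one-predictor OLS priors (9 signatures);
3. logistic truth ``Pr(y=1) = expit(1 + x1 + x2 + x3)``, two-predictor
   logistic priors;
4. logistic truth, one-predictor logistic priors;
5. continuous truth with interaction ``y = 1 + x1 + x2 + x1*x2 + e``, three
   ANOVA priors on percentile-discretized factors (6, 7 and 11 signatures);
6. nonlinear fluid-leakage truth in (time, temperature), two mis-specified
   linear priors with R^2 (7 signatures);
7. normal-normal random-effects truth, five published effect sizes with
   within-study variances, compared against DerSimonian-Laird.

Explanatory variables in scenarios 1-5 are equicorrelated standard normals
(correlation 0.5) — strong enough to induce the omitted-variable biases the
mis-specified priors display.  Studies hand the estimator the population
covariate moments (reported moments treated as consistent estimates of a
common covariate distribution); the methods note explains why per-study
sample moments would invalidate the interval-coverage experiments in either
direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimator import GMAEstimator, suggest_start
from .model_core import (
    BetweenStudySpec,
    BetweenStudyStat,
    GMAError,
    MetaModel,
    ParameterVector,
    PriorStudy,
    SignatureVector,
    build_meta_model,
    with_measurement_noise,
)
from .replicators import build_replicator

__all__ = [
    "ScenarioConfig",
    "RecoveryReport",
    "generate_scenario",
    "run_scenario",
    "dersimonian_laird",
    "run_random_effects_comparison",
    "run_measurement_error_extension",
    "scenario6_surface_comparison",
    "DEFAULT_FIT_KWARGS",
]

# Runtime-oriented defaults for repeated recovery experiments; estimation
# defaults (S=50/500, rounds=3, 5 starts) remain those of SimulationPlan.
DEFAULT_FIT_KWARGS: dict = dict(
    n_sim=30, n_sim_final=200, rounds=2, n_starts=2, weight_reps=400,
)


@dataclass
class ScenarioConfig:
    """One scenario setup: truth, per-study design, replication count."""

    scenario: int
    seed: int = 0
    n_obs: int = 100
    rho: float = 0.5
    n_reps: int = 200
    delta: float = 0.0          # measurement-noise fraction (scenario-1 extension)
    tau2: float = 0.1           # scenario 7 between-study variance
    mu: float = 0.3             # scenario 7 summary effect
    sigma_w: float = 1.0        # scenario 7 within-study sd of raw observations
    n_obs_per_study: tuple[int, ...] = (30, 50, 80, 40, 60)  # scenario 7
    level: float = 0.95
    fit_kwargs: dict = field(default_factory=lambda: dict(DEFAULT_FIT_KWARGS))

    def __post_init__(self):
        if self.scenario not in range(1, 8):
            raise GMAError(f"unknown scenario id {self.scenario}; valid ids are 1-7")


@dataclass
class RecoveryReport:
    """Aggregate of repeated generate -> fit -> score cycles."""

    scenario: int
    table: pd.DataFrame        # index: parameter; columns: true, mean_estimate, ...
    n_reps: int
    n_effective: int
    converged: list
    flagged: bool = False


def _seed_int(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] & 0x7FFFFFFF)


def _equicorrelated(k: int, rho: float) -> np.ndarray:
    return np.full((k, k), rho) + (1.0 - rho) * np.eye(k)


def _publish(replicator, subset, X_full: pd.DataFrame, y: np.ndarray,
             rng: np.random.Generator, redraw):
    """Run a study's procedure on raw data; redraw on (rare) non-convergence.

    Returns (signatures, raw covariate table used) so the study can "report"
    the sample moments of its own data.
    """
    res = replicator.run(X_full[list(subset)] if subset else X_full, y)
    attempts = 0
    while not res.converged and attempts < 20:
        attempts += 1
        X_full, y = redraw(rng)
        res = replicator.run(X_full[list(subset)] if subset else X_full, y)
    if not res.converged:
        raise GMAError(f"could not generate converged published signatures: {res.notes}")
    return res.signatures, X_full


def _linear_family(config: ScenarioConfig, seed: int, logistic: bool,
                   subsets: Sequence[tuple[str, ...]], delta: float = 0.0):
    predictors = ("x1", "x2", "x3")
    cov = _equicorrelated(3, config.rho)
    truth_vals = {"intercept": 1.0, "b:x1": 1.0, "b:x2": 1.0, "b:x3": 1.0}
    if logistic:
        model = build_meta_model("logistic", predictors)
    else:
        model = build_meta_model("linear", predictors)
        truth_vals["sigma"] = 1.0
    if delta > 0:
        model = with_measurement_noise(model, predictors)
        for c in predictors:
            truth_vals[f"delta:{c}"] = float(delta)
    truth = model.make_parameters(truth_vals)
    root = np.random.SeedSequence([seed, config.scenario])
    studies = []
    for i, subset in enumerate(subsets):
        rng = np.random.default_rng(root.spawn(i + 1)[i])

        def draw(rng):
            L = np.linalg.cholesky(cov)
            X = rng.standard_normal((config.n_obs, 3)) @ L.T
            if logistic:
                eta = 1.0 + X.sum(axis=1)
                y = (rng.random(config.n_obs) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
            else:
                y = 1.0 + X.sum(axis=1) + rng.standard_normal(config.n_obs)
            X_obs = X.copy()
            if delta > 0:
                for j in range(3):
                    sd = X[:, j].std(ddof=1)
                    X_obs[:, j] = X[:, j] + delta * sd * rng.standard_normal(config.n_obs)
            return pd.DataFrame(X_obs, columns=predictors), y

        kind = "logistic" if logistic else "ols"
        options = {} if logistic else {"include_mse": True}
        rep = build_replicator(kind, subset, options)
        X_obs, y = draw(rng)
        sigs, X_obs = _publish(rep, subset, X_obs, y, rng, draw)
        # Studies carry the population covariate moments: reported moments are
        # treated as consistent estimates of a common covariate distribution,
        # so the simulated X matches the generating distribution and the
        # simulated signature covariance equals Var of the published
        # signatures (see the methods note on why sample moments would break
        # the coverage experiments in either direction).
        moments = (np.zeros(3), cov)
        noise_params = {c: f"delta:{c}" for c in predictors} if delta > 0 else {}
        studies.append(PriorStudy(
            study_id=f"study{i + 1}", n_obs=config.n_obs, covariate_subset=subset,
            replicator_kind=kind, replicator_options=options,
            empirical_signatures=sigs, covariate_moments=moments,
            noise_params=noise_params,
        ))
    return model, studies, truth, None


def _scenario5(config: ScenarioConfig, seed: int):
    predictors = ("x1", "x2")
    cov = _equicorrelated(2, config.rho)
    model = build_meta_model("linear", predictors, terms=("x1", "x2", "x1*x2"))
    truth = model.make_parameters(
        {"intercept": 1.0, "b:x1": 1.0, "b:x2": 1.0, "b:x1*x2": 1.0, "sigma": 1.0}
    )
    designs = [
        ("study1", {"factors": (("x1", (33.0, 66.0)),)}),
        ("study2", {"factors": (("x2", (25.0, 50.0, 75.0)),)}),
        ("study3", {"factors": (("x1", (33.0, 66.0)), ("x2", (25.0, 50.0, 75.0)))}),
    ]
    root = np.random.SeedSequence([seed, 5])
    studies = []
    for i, (sid, options) in enumerate(designs):
        rng = np.random.default_rng(root.spawn(i + 1)[i])

        def draw(rng):
            L = np.linalg.cholesky(cov)
            X = rng.standard_normal((config.n_obs, 2)) @ L.T
            y = 1.0 + X[:, 0] + X[:, 1] + X[:, 0] * X[:, 1] + rng.standard_normal(config.n_obs)
            return pd.DataFrame(X, columns=predictors), y

        rep = build_replicator("anova", (), options)
        X, y = draw(rng)
        sigs, X = _publish(rep, (), X, y, rng, draw)
        moments = (np.zeros(2), cov)
        studies.append(PriorStudy(
            study_id=sid, n_obs=config.n_obs, covariate_subset=tuple(c for c, _ in options["factors"]),
            replicator_kind="anova", replicator_options=options,
            empirical_signatures=sigs, covariate_moments=moments,
        ))
    return model, studies, truth, None


def _scenario6(config: ScenarioConfig, seed: int):
    predictors = ("time", "temperature")
    model = build_meta_model("fluid_leakage", predictors, center=50.0)
    truth = model.make_parameters(
        {"intercept": 1.0, "rate": 0.05, "temp_sensitivity": 0.03, "sigma": 0.5}
    )
    n = max(config.n_obs, 120)
    mean = np.array([5.0, 50.0])
    cov = np.diag([2.5**2, 15.0**2])
    root = np.random.SeedSequence([seed, 6])
    designs = [
        ("study1", ("time",), {"include_mse": False, "include_r2": True}),
        ("study2", ("time", "temperature"), {"include_mse": False, "include_r2": True}),
    ]
    studies = []
    for i, (sid, subset, options) in enumerate(designs):
        rng = np.random.default_rng(root.spawn(i + 1)[i])

        def draw(rng):
            X = mean + rng.standard_normal((n, 2)) @ np.sqrt(cov)
            from .model_core import evaluate_mean

            mu = evaluate_mean(model, truth, X)
            y = mu + truth["sigma"] * rng.standard_normal(n)
            return pd.DataFrame(X, columns=predictors), y

        rep = build_replicator("ols", subset, options)
        X_full, y = draw(rng)
        sigs, X_full = _publish(rep, subset, X_full, y, rng, draw)
        moments = (mean.copy(), cov.copy())
        studies.append(PriorStudy(
            study_id=sid, n_obs=n, covariate_subset=subset,
            replicator_kind="ols", replicator_options=options,
            empirical_signatures=sigs, covariate_moments=moments,
        ))
    return model, studies, truth, None


def _scenario7(config: ScenarioConfig, seed: int):
    model = build_meta_model("random_effects")
    tau = float(np.sqrt(max(config.tau2, 0.0)))
    truth = model.make_parameters({"mu": config.mu, "tau": tau, "sigma_w": config.sigma_w})
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    rep = build_replicator("effect_size", (), {})
    studies, effects = [], []
    for i, n_l in enumerate(config.n_obs_per_study):
        b_l = tau * rng.standard_normal()
        y = config.mu + b_l + config.sigma_w * rng.standard_normal(n_l)
        res = rep.run(np.empty((n_l, 0)), y)
        studies.append(PriorStudy(
            study_id=f"study{i + 1}", n_obs=int(n_l), covariate_subset=(),
            replicator_kind="effect_size", replicator_options={},
            empirical_signatures=res.signatures,
        ))
        effects.append(res.signatures["effect"])
    between = BetweenStudySpec(
        (BetweenStudyStat("var:effect", "variance", "effect"),),
        SignatureVector(("var:effect",), [float(np.var(effects, ddof=1))]),
    )
    return model, studies, truth, between


def generate_scenario(config: ScenarioConfig | int, seed: int | None = None,
                      **overrides):
    """Generate (meta-model, prior studies with published signatures, truth, between).

    ``config`` may be a :class:`ScenarioConfig` or a bare scenario id (1-7);
    keyword overrides update the config fields.
    """
    if isinstance(config, int):
        config = ScenarioConfig(scenario=config)
    if overrides or seed is not None:
        kwargs = {**config.__dict__}
        kwargs.pop("fit_kwargs", None)
        kwargs.update(overrides)
        if seed is not None:
            kwargs["seed"] = seed
        fit_kwargs = config.fit_kwargs
        config = ScenarioConfig(**kwargs)
        config.fit_kwargs = fit_kwargs
    seed = config.seed if seed is None else seed
    pairs = (("x1", "x2"), ("x2", "x3"), ("x1", "x3"))
    singles = (("x1",), ("x2",), ("x3",))
    if config.scenario == 1:
        return _linear_family(config, seed, logistic=False, subsets=pairs, delta=config.delta)
    if config.scenario == 2:
        return _linear_family(config, seed, logistic=False, subsets=singles)
    if config.scenario == 3:
        return _linear_family(config, seed, logistic=True, subsets=pairs)
    if config.scenario == 4:
        return _linear_family(config, seed, logistic=True, subsets=singles)
    if config.scenario == 5:
        return _scenario5(config, seed)
    if config.scenario == 6:
        return _scenario6(config, seed)
    return _scenario7(config, seed)


def _fit_once(model, studies, between, seed: int, level: float, fit_kwargs: Mapping):
    kwargs = dict(DEFAULT_FIT_KWARGS)
    kwargs.update(fit_kwargs)
    est = GMAEstimator(model=model, start=suggest_start(model, studies),
                       seed=seed, **kwargs)
    est.fit(studies, between=between)
    ci = est.confidence_intervals(level)
    return est, ci


def run_scenario(config: ScenarioConfig) -> RecoveryReport:
    """Repeat generate -> fit -> score; aggregate bias, spread and CI coverage."""
    if config.n_reps < 1:
        raise GMAError("n_reps must be at least 1")
    estimates, halfwidths, covered, conv = [], [], [], []
    truth_vec = None
    n_fail = 0
    for r in range(config.n_reps):
        gseed = _seed_int(config.seed, 11, r)
        model, studies, truth, between = generate_scenario(config, seed=gseed)
        truth_vec = truth
        try:
            est, ci = _fit_once(model, studies, between, _seed_int(config.seed, 13, r),
                                config.level, config.fit_kwargs)
        except GMAError:
            n_fail += 1
            conv.append(False)
            continue
        conv.append(bool(est.fit_result_.converged))
        estimates.append(est.params_)
        halfwidths.append((ci["upper"] - ci["lower"]).to_numpy() / 2.0)
        covered.append(
            (ci["lower"].to_numpy() <= truth.values)
            & (truth.values <= ci["upper"].to_numpy())
        )
    if not estimates:
        raise GMAError("every replication failed to fit")
    E = np.asarray(estimates)
    H = np.asarray(halfwidths)
    C = np.asarray(covered, dtype=float)
    table = pd.DataFrame(
        {
            "true": truth_vec.values,
            "mean_estimate": E.mean(axis=0),
            "bias": E.mean(axis=0) - truth_vec.values,
            "sd": E.std(axis=0, ddof=1) if E.shape[0] > 1 else np.zeros(E.shape[1]),
            "mean_ci_halfwidth": H.mean(axis=0),
            "coverage": C.mean(axis=0),
        },
        index=list(truth_vec.names),
    )
    return RecoveryReport(
        scenario=config.scenario, table=table, n_reps=config.n_reps,
        n_effective=len(estimates), converged=conv,
        flagged=n_fail > 0.2 * config.n_reps,
    )


# ---------------------------------------------------------------------------
# scenario 7 comparator: DerSimonian-Laird
# ---------------------------------------------------------------------------


def dersimonian_laird(effects, within_vars) -> tuple[float, float, float]:
    """Classical moment-based random-effects meta-analysis.

    Returns (summary effect, between-study variance tau^2, se of the summary
    effect).  ``Q = sum w_i (y_i - ybar_w)^2`` with fixed-effect weights
    ``w_i = 1/v_i``; ``tau^2 = max(0, (Q - (L-1)) / (sum w - sum w^2 / sum w))``;
    the summary effect re-weights by ``1/(v_i + tau^2)``.
    """
    y = np.asarray(effects, dtype=float).ravel()
    v = np.asarray(within_vars, dtype=float).ravel()
    if y.size < 2:
        raise GMAError("DerSimonian-Laird needs at least two studies")
    if y.shape != v.shape or np.any(v <= 0):
        raise GMAError("within-study variances must be positive and match effects")
    w = 1.0 / v
    ybar = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - ybar) ** 2))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - (y.size - 1)) / denom)
    w_star = 1.0 / (v + tau2)
    mu = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(np.sqrt(1.0 / np.sum(w_star)))
    return mu, tau2, se


def run_random_effects_comparison(tau2_levels: Sequence[float] = (0.0, 0.025, 0.05, 0.1, 0.2),
                                  n_reps: int = 200, seed: int = 0,
                                  config: ScenarioConfig | None = None,
                                  fit_kwargs: Mapping | None = None) -> pd.DataFrame:
    """Paired RMSE comparison of the aggregation estimator vs DerSimonian-Laird.

    Data are generated under the normal-normal random-effects assumptions
    (which favour the classical method).  Returns one row per true tau^2
    level with RMSEs for the summary effect and tau^2, plus the paired
    standard error of the squared-error difference for the summary effect.
    """
    base = config or ScenarioConfig(scenario=7)
    fit_kwargs = dict(fit_kwargs or base.fit_kwargs)
    rows = []
    for li, tau2 in enumerate(tau2_levels):
        err_mu_g, err_mu_d, err_t_g, err_t_d = [], [], [], []
        for r in range(n_reps):
            gseed = _seed_int(seed, 17, li, r)
            model, studies, truth, between = generate_scenario(
                base, seed=gseed, tau2=float(tau2)
            )
            effects = [s.empirical_signatures["effect"] for s in studies]
            withins = [s.empirical_signatures["within_var"] for s in studies]
            mu_dl, tau2_dl, _ = dersimonian_laird(effects, withins)
            try:
                est, _ = _fit_once(model, studies, between,
                                   _seed_int(seed, 19, li, r), base.level, fit_kwargs)
            except GMAError:
                continue
            bh = est.beta_hat_
            err_mu_g.append(bh["mu"] - truth["mu"])
            err_mu_d.append(mu_dl - truth["mu"])
            err_t_g.append(bh["tau"] ** 2 - tau2)
            err_t_d.append(tau2_dl - tau2)
        eg, ed = np.asarray(err_mu_g), np.asarray(err_mu_d)
        diff = eg**2 - ed**2
        rows.append({
            "tau2": float(tau2),
            "n_effective": eg.size,
            "rmse_mu_gma": float(np.sqrt(np.mean(eg**2))),
            "rmse_mu_dl": float(np.sqrt(np.mean(ed**2))),
            "rmse_tau2_gma": float(np.sqrt(np.mean(np.asarray(err_t_g) ** 2))),
            "rmse_tau2_dl": float(np.sqrt(np.mean(np.asarray(err_t_d) ** 2))),
            "paired_se_mu": float(diff.std(ddof=1) / np.sqrt(diff.size)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# measurement-error extension (scenario-1 base)
# ---------------------------------------------------------------------------


def run_measurement_error_extension(deltas: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
                                    n_reps: int = 100, seed: int = 0,
                                    config: ScenarioConfig | None = None,
                                    fit_kwargs: Mapping | None = None) -> pd.DataFrame:
    """Estimate measurement-noise fractions alongside the meta-model.

    The scenario-1 world is regenerated with normal measurement noise of
    fraction ``delta`` of each predictor's standard deviation; the meta-model
    is augmented with one bounded noise parameter per predictor.  Reports, per
    delta level: the average CI width and pooled coverage of the structural
    parameters, the spread of their estimates, and the recovered noise level.
    """
    base = config or ScenarioConfig(scenario=1)
    fit_kwargs = dict(fit_kwargs or base.fit_kwargs)
    rows = []
    for li, delta in enumerate(deltas):
        widths, cover, d_hats, ests = [], [], [], []
        for r in range(n_reps):
            gseed = _seed_int(seed, 23, li, r)
            model, studies, truth, between = generate_scenario(
                base, seed=gseed, delta=float(delta)
            )
            if delta == 0:
                # keep the augmented parameterization even at zero truth
                model0, studies0, truth0, _ = generate_scenario(
                    base, seed=gseed, delta=1e-9
                )
                model, studies, truth = model0, studies0, truth0
                truth = model.make_parameters(
                    {**truth.as_dict(), **{p: 0.0 for p in model.noise_params}}
                )
            try:
                est, ci = _fit_once(model, studies, between,
                                    _seed_int(seed, 29, li, r), base.level, fit_kwargs)
            except GMAError:
                continue
            structural = [n for n in model.param_names if not n.startswith("delta:")]
            sub = ci.loc[structural]
            widths.append((sub["upper"] - sub["lower"]).to_numpy())
            tvals = np.array([truth[n] for n in structural])
            cover.append((sub["lower"].to_numpy() <= tvals) & (tvals <= sub["upper"].to_numpy()))
            d_hats.extend(est.beta_hat_[p] for p in model.noise_params)
            ests.append([est.beta_hat_[n] for n in structural])
        W = np.asarray(widths)
        C = np.asarray(cover, dtype=float)
        E = np.asarray(ests)
        rows.append({
            "delta": float(delta),
            "n_effective": W.shape[0],
            "mean_ci_width": float(W.mean()),
            "coverage": float(C.mean()),
            "median_delta_hat": float(np.median(d_hats)),
            "estimate_sd": float(E.std(axis=0, ddof=1).mean()) if E.shape[0] > 1 else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenario 6 surface comparison
# ---------------------------------------------------------------------------


def scenario6_surface_comparison(seed: int = 0, grid: int = 25,
                                 fit_kwargs: Mapping | None = None) -> dict:
    """Fit the nonlinear meta-model and compare predicted surfaces on a grid.

    Returns the Pearson correlation between each model's predicted surface
    and the true mean surface: the fitted nonlinear meta-model and the two
    mis-specified linear priors (reconstructed from their published
    coefficients).  The qualitative claim being checked: aggregation recovers
    nonlinear structure that none of the priors contained.
    """
    config = ScenarioConfig(scenario=6, seed=seed)
    model, studies, truth, _ = generate_scenario(config)
    est, _ = _fit_once(model, studies, None, _seed_int(seed, 31), config.level,
                       fit_kwargs or config.fit_kwargs)
    t = np.linspace(0.0, 10.0, grid)
    temp = np.linspace(20.0, 80.0, grid)
    T, P = np.meshgrid(t, temp)
    X = pd.DataFrame({"time": T.ravel(), "temperature": P.ravel()})
    from .model_core import evaluate_mean

    true_surface = evaluate_mean(model, truth, X)
    fitted_surface = est.predict(X)

    def lin_surface(study):
        sv = study.empirical_signatures
        out = np.full(len(X), sv["intercept"])
        for c in study.covariate_subset:
            out = out + sv[f"b:{c}"] * X[c].to_numpy()
        return out

    def corr(a, b):
        return float(np.corrcoef(a, b)[0, 1])

    return {
        "fitted": corr(true_surface, fitted_surface),
        "prior_time_only": corr(true_surface, lin_surface(studies[0])),
        "prior_time_temperature": corr(true_surface, lin_surface(studies[1])),
        "beta_hat": est.beta_hat_.as_dict(),
        "truth": truth.as_dict(),
    }
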