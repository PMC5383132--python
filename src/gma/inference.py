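"""Uncertainty quantification and diagnostics for an aggregation fit.

* Asymptotic parameter covariance from the simulated-moments sandwich
  (finite-difference Jacobian of the mean simulated signatures under common
  random numbers).
* Goodness of fit: the simulation-corrected quadratic form
  ``chi0 = S/(1+S) * e' W* e`` at the optimum, asymptotically chi-square with
  ``dim(signatures) - dim(beta)`` degrees of freedom when ``W*`` is the
  inverse covariance of the signature estimators at the studies' actual
  sample sizes.
* Model selection: ``MSC = chi0 + 2 dim(beta)``, lower preferred.
* Parametric bootstrap confidence intervals (raw study data are unavailable
  by construction, so pseudo-empirical signature sets are simulated from the
  fitted meta-model at each study's sample size and refit).
* Leave-one-study-out influence: the drop in chi0 when each study is
  excluded, ranking outlying studies.
* Wald tests of linear parameter combinations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimator import (
    GMAEstimator,
    GMAFit,
    SignatureSimulator,
    SimulationPlan,
    UnderIdentifiedError,
    parameter_covariance_matrix,
)
from .model_core import (
    BetweenStudySpec,
    GMAError,
    MetaModel,
    ParameterVector,
    PriorStudy,
    SignatureVector,
)

__all__ = [
    "JacobianEstimate",
    "FitAssessment",
    "jacobian",
    "parameter_covariance",
    "chi0_statistic",
    "msc",
    "bootstrap_ci",
    "loo_influence",
    "wald_test",
    "compare_models",
]


@dataclass
class JacobianEstimate:
    """Finite-difference sensitivity of mean signatures to parameters."""

    D: np.ndarray
    step_sizes: np.ndarray
    param_names: tuple[str, ...]
    labels: tuple[str, ...]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.D))


@dataclass
class FitAssessment:
    """Goodness of fit and model selection summary."""

    chi0: float
    dof: int
    p_value: float | None
    msc: float

    def __post_init__(self):
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise GMAError("p-value outside [0, 1]")


def jacobian(model: MetaModel, beta_hat: ParameterVector, studies: Sequence[PriorStudy],
             plan: SimulationPlan, between: BetweenStudySpec | None = None,
             rel_step: float = 1e-3) -> JacobianEstimate:
    """Central finite differences of S-averaged simulated signatures.

    Uses common random numbers (the same plan seed for every perturbed
    evaluation) so the differences reflect the parameters only.  A zero
    column triggers a warning naming the insensitive parameter.
    """
    sim = SignatureSimulator(model, studies, between, plan)
    steps = np.array([rel_step * max(abs(v), 1.0) for v in beta_hat.values])
    D = GMAEstimator._jacobian_matrix(sim, beta_hat, plan, rel_step=rel_step)
    return JacobianEstimate(D=D, step_sizes=steps, param_names=beta_hat.names,
                            labels=sim.stacked_labels)


def parameter_covariance(D, W, sigma_hat, n_sim: int | None = None) -> np.ndarray:
    """Sandwich parameter covariance; reduces to (D' Sigma^-1 D)^-1 at optimal W."""
    Dm = D.D if isinstance(D, JacobianEstimate) else np.asarray(D, float)
    Wm = getattr(W, "matrix", W)
    return parameter_covariance_matrix(Dm, np.asarray(Wm, float), np.asarray(sigma_hat, float), n_sim)


def chi0_statistic(fit: GMAFit) -> FitAssessment:
    """Simulation-corrected goodness-of-fit statistic and its chi-square p-value."""
    if fit.weight.provenance != "simulated-inverse-covariance":
        raise GMAError(
            "chi0 requires the efficient weight matrix (provenance "
            "'simulated-inverse-covariance'); refit with rounds >= 1"
        )
    S = fit.n_sim_final
    chi0 = float(S / (1.0 + S) * fit.error @ fit.weight.matrix @ fit.error)
    dof = fit.dof
    p = float(stats.chi2.sf(chi0, dof)) if dof >= 1 else None
    return FitAssessment(chi0=chi0, dof=dof, p_value=p, msc=msc(chi0, len(fit.beta_hat)))


def msc(chi0: float, n_params: int) -> float:
    """Model selection criterion chi0 + 2 dim(beta); lower is preferred."""
    if not np.isfinite(chi0):
        raise GMAError("chi0 must be finite")
    return float(chi0) + 2.0 * int(n_params)


def _studies_with_signatures(studies: Sequence[PriorStudy],
                             blocks: dict[str, np.ndarray],
                             labels_per_study: dict[str, tuple[str, ...]]) -> list[PriorStudy]:
    out = []
    for st in studies:
        vals = blocks[st.study_id]
        new = PriorStudy(
            study_id=st.study_id, n_obs=st.n_obs,
            covariate_subset=st.covariate_subset,
            replicator_kind=st.replicator_kind,
            replicator_options=dict(st.replicator_options),
            empirical_signatures=SignatureVector(labels_per_study[st.study_id], vals),
            covariate_moments=st.covariate_moments,
            covariate_table=st.covariate_table,
            noise_params=dict(st.noise_params),
        )
        out.append(new)
    return out


def bootstrap_ci(model: MetaModel, studies: Sequence[PriorStudy], fit: GMAFit,
                 B: int = 500, level: float = 0.95, seed: int = 0,
                 between: BetweenStudySpec | None = None,
                 refit_kwargs: dict | None = None):
    """Parametric bootstrap percentile intervals.

    Simulates ``B`` pseudo-empirical signature sets from the fitted meta-model
    at each study's actual sample size, refits each (single start at the point
    estimate, fixed weight), and returns percentile intervals plus the full
    draw table.  Errors out when more than 10% of refits fail.
    """
    plan = fit.plan
    sim = SignatureSimulator(model, studies, between, SimulationPlan(
        n_sim=B, n_sim_final=B, seed=int(seed) + 104_729,
        sample_size=plan.sample_size,
    ))
    pseudo, bad, _ = sim.signature_matrix(fit.beta_hat.as_dict(), B)
    if pseudo is None:
        raise GMAError("bootstrap simulation failed at the fitted parameters")
    labels_per_study = {ws.study.study_id: ws.labels for ws in sim.workspaces}
    kwargs = dict(
        n_sim=plan.n_sim, n_sim_final=plan.n_sim, rounds=0, n_starts=1,
        polish=plan.polish, seed=plan.seed, fixed_weight=fit.weight,
        sample_size=plan.sample_size, retry_budget=plan.retry_budget,
    )
    kwargs.update(refit_kwargs or {})
    draws = np.full((B, len(fit.beta_hat)), np.nan)
    failures = int(bad.sum())
    for b in range(B):
        if bad[b]:
            continue
        blocks = sim.split_blocks(pseudo[b])
        b_studies = _studies_with_signatures(studies, blocks, labels_per_study)
        b_between = None
        if between is not None:
            b_between = BetweenStudySpec(
                between.stats,
                SignatureVector(tuple(s.name for s in between.stats), blocks["between"]),
            )
        try:
            est = GMAEstimator(model=model, start=fit.beta_hat, **kwargs)
            est.fit(b_studies, between=b_between)
            draws[b] = est.params_
        except GMAError:
            failures += 1
    if failures > 0.10 * B:
        raise GMAError(
            f"{failures}/{B} bootstrap refits failed to converge; the fit may be "
            f"fragile (inspect the per-study errors)"
        )
    alpha = 1.0 - level
    good = draws[~np.isnan(draws).any(axis=1)]
    lo = np.percentile(good, 100 * alpha / 2, axis=0)
    hi = np.percentile(good, 100 * (1 - alpha / 2), axis=0)
    table = pd.DataFrame(
        {"estimate": fit.beta_hat.values, "lower": lo, "upper": hi},
        index=list(fit.beta_hat.names),
    )
    return table, pd.DataFrame(good, columns=list(fit.beta_hat.names))


def loo_influence(model: MetaModel, studies: Sequence[PriorStudy], fit: GMAFit,
                  between: BetweenStudySpec | None = None,
                  refit_kwargs: dict | None = None) -> pd.DataFrame:
    """Leave-one-study-out goodness-of-fit changes, ranked by delta chi0.

    Refits with each study removed (starting from the full-fit estimate) and
    reports chi0 without the study, the drop ``delta_chi0 = chi0_full -
    chi0_without``, and the degrees-of-freedom change.  Large drops flag the
    study as inconsistent with the rest.  A reduced problem that no longer
    identifies the meta-model is marked not assessable.
    """
    if len(studies) < 2:
        raise GMAError("leave-one-study-out needs at least two studies")
    if fit.chi0 is None:
        raise GMAError("full fit carries no chi0; refit with rounds >= 1")
    plan = fit.plan
    kwargs = dict(
        n_sim=plan.n_sim, n_sim_final=plan.n_sim_final, rounds=max(1, plan.rounds - 1),
        n_starts=1, polish=plan.polish, seed=plan.seed, weight_reps=plan.weight_reps,
        weight_ridge=plan.weight_ridge, sample_size=plan.sample_size,
        retry_budget=plan.retry_budget,
    )
    kwargs.update(refit_kwargs or {})
    rows = []
    for st in studies:
        reduced = [s for s in studies if s.study_id != st.study_id]
        row = {"study_id": st.study_id, "assessable": True,
               "chi0_without": np.nan, "delta_chi0": np.nan, "dof_change": np.nan}
        try:
            est = GMAEstimator(model=model, start=fit.beta_hat, **kwargs)
            est.fit(reduced, between=between if between is not None and len(reduced) >= 2 else None)
            row["chi0_without"] = est.chi0_
            row["delta_chi0"] = fit.chi0 - est.chi0_
            row["dof_change"] = fit.dof - est.dof_
        except (UnderIdentifiedError, GMAError) as exc:
            row["assessable"] = False
            row["note"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("study_id")
    return table.sort_values("delta_chi0", ascending=False)


def wald_test(fit: GMAFit, constraint, value: float = 0.0) -> tuple[float, float]:
    """Two-sided Wald test of a linear parameter combination c' beta = value.

    ``constraint`` is either a parameter name or a coefficient vector over
    ``fit.beta_hat.names``.
    """
    if fit.covariance is None:
        raise GMAError("fit carries no parameter covariance")
    names = fit.beta_hat.names
    if isinstance(constraint, str):
        c = np.zeros(len(names))
        c[names.index(constraint)] = 1.0
    else:
        c = np.asarray(constraint, float)
        if c.shape != (len(names),):
            raise GMAError(f"constraint vector must have length {len(names)}")
    var = float(c @ fit.covariance @ c)
    if var <= 0:
        raise GMAError("constraint combination has zero estimated variance")
    z = (float(c @ fit.beta_hat.values) - value) / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def compare_models(models: Sequence[MetaModel], studies: Sequence[PriorStudy],
                   between: BetweenStudySpec | None = None, starts=None,
                   **fit_kwargs) -> pd.DataFrame:
    """Fit several candidate meta-models and rank them by MSC (lower first)."""
    rows = []
    starts = starts or [None] * len(models)
    for model, start in zip(models, starts):
        est = GMAEstimator(model=model, start=start, **fit_kwargs)
        est.fit(studies, between=between)
        rows.append({
            "model": model.name,
            "n_params": model.n_params,
            "chi0": est.chi0_,
            "dof": est.dof_,
            "msc": est.msc_,
        })
    return pd.DataFrame(rows).sort_values("msc").reset_index(drop=True)
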