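"""The aggregation estimator: match simulated to empirical signatures.

Given a meta-model, a list of prior studies and (optionally) a between-study
signature block, the estimator simulates every study's procedure ``S`` times
under a candidate parameter vector, forms the stacked error

    e(beta) = empirical signatures - mean over s of simulated signatures

(between-study block first, then studies in order), and minimizes the
weighted quadratic form ``e' W e``.  The weight matrix starts diagonal with
entries proportional to the reciprocal squared empirical signatures and is
iterated toward the inverse of the simulated signature covariance, which is
the efficient choice.

Common random numbers are used throughout: all covariate and error draws are
functions of (master seed, replicate, study) only — never of the candidate
parameters — so the simulated-signature map is deterministic and the
optimization surface well behaved.  Optimization is derivative-free
(Nelder-Mead with jittered multi-starts, bounds handled by smooth parameter
transforms) followed by a least-squares polish on the Cholesky-whitened
residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .model_core import (
    BetweenStudySpec,
    GMAError,
    MetaModel,
    ParameterVector,
    PriorStudy,
    SignatureVector,
)
from .replicators import between_study_statistics, build_replicator
from .samplers import CovariateSource, MomentSource, TableSource

__all__ = [
    "UnderIdentifiedError",
    "WeightUpdateError",
    "SimulationPlan",
    "WeightMatrix",
    "GMAFit",
    "SignatureSimulator",
    "GMAEstimator",
    "signature_error",
    "objective",
    "initial_weight",
    "update_weight",
    "simulate_signatures",
    "fit_gma",
    "suggest_start",
]


class UnderIdentifiedError(GMAError):
    """Fewer signatures than parameters: the meta-model cannot be identified."""


class WeightUpdateError(GMAError):
    """The simulated signature covariance could not be inverted."""


@dataclass
class SimulationPlan:
    """How the objective is simulated.

    ``n_sim`` replications per objective evaluation during optimization,
    ``n_sim_final`` for the final signature evaluation, weight updates use
    ``weight_reps`` independent replicates.  ``sample_size`` overrides the
    per-study simulated sample size (defaults to each study's own n_l).
    The master ``seed`` fixes every draw for the lifetime of one fit.
    """

    n_sim: int = 50
    n_sim_final: int = 500
    seed: int = 0
    sample_size: int | Mapping[str, int] | None = None
    common_random_numbers: bool = True
    rounds: int = 3
    n_starts: int = 5
    jitter: float = 0.5
    weight_reps: int = 1000
    weight_ridge: float = 1e-6
    weight_floor: float = 1e-6
    polish: bool = True
    maxiter: int | None = None
    xatol: float = 1e-5
    fatol: float = 1e-10
    retry_budget: int = 5
    nonconvergence_penalty: float = 1e8

    def __post_init__(self):
        if self.n_sim < 1 or self.n_sim_final < 1:
            raise GMAError("simulation counts must be at least 1")

    def study_n(self, study: PriorStudy) -> int:
        if self.sample_size is None:
            return study.n_obs
        if isinstance(self.sample_size, Mapping):
            return int(self.sample_size.get(study.study_id, study.n_obs))
        return int(self.sample_size)


@dataclass
class WeightMatrix:
    """Positive semi-definite weight over the stacked signature space."""

    matrix: np.ndarray
    provenance: str = "user"  # initial-diagonal | simulated-inverse-covariance | user
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise GMAError("weight matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8, rtol=1e-6):
            raise GMAError("weight matrix must be symmetric")


def initial_weight(empirical: SignatureVector | np.ndarray, floor: float = 1e-6) -> WeightMatrix:
    """Diagonal starting weight, entries 1 / max(signature^2, floor^2)."""
    vals = empirical.values if isinstance(empirical, SignatureVector) else np.asarray(empirical, float)
    diag = 1.0 / np.maximum(vals**2, floor**2)
    labels = empirical.labels if isinstance(empirical, SignatureVector) else None
    return WeightMatrix(np.diag(diag), provenance="initial-diagonal", labels=labels)


def objective(e, W: WeightMatrix | np.ndarray) -> float:
    """The weighted squared matching objective e' W e."""
    evec = e.values if isinstance(e, SignatureVector) else np.asarray(e, float)
    mat = W.matrix if isinstance(W, WeightMatrix) else np.asarray(W, float)
    if not np.allclose(mat, mat.T, atol=1e-8, rtol=1e-6):
        raise GMAError("weight matrix must be symmetric")
    if mat.shape != (evec.size, evec.size):
        raise GMAError(
            f"weight matrix of shape {mat.shape} does not match error of length {evec.size}"
        )
    return float(evec @ mat @ evec)


def signature_error(empirical: SignatureVector, simulated: Sequence[SignatureVector]) -> SignatureVector:
    """Empirical minus mean-simulated signatures, label-aligned."""
    if not simulated:
        raise GMAError("no simulated signature vectors supplied")
    offenders = [sv.labels for sv in simulated if sv.labels != empirical.labels]
    if offenders:
        raise GMAError(
            f"simulated signature labels {offenders[0]} do not match empirical "
            f"labels {empirical.labels}"
        )
    mean = np.mean([sv.values for sv in simulated], axis=0)
    return SignatureVector(empirical.labels, empirical.values - mean)


# ---------------------------------------------------------------------------
# parameter transforms (bounds -> unconstrained optimizer space)
# ---------------------------------------------------------------------------


class _Transform:
    """Smooth bijections from R to each parameter's feasible interval.

    One-sided bounds use a square map (beta = lo + u^2) so boundary values —
    a zero error variance, a zero between-study variance — are attainable
    exactly; two-sided bounds use a scaled logistic.
    """

    def __init__(self, names: Sequence[str], bounds: Mapping[str, tuple]):
        self.names = tuple(names)
        self.kinds, self.lo, self.hi = [], [], []
        for n in self.names:
            lo, hi = bounds.get(n, (None, None))
            if lo is None and hi is None:
                self.kinds.append("id")
            elif hi is None:
                self.kinds.append("lower")
            elif lo is None:
                self.kinds.append("upper")
            else:
                self.kinds.append("both")
            self.lo.append(lo)
            self.hi.append(hi)

    def to_beta(self, u: np.ndarray) -> np.ndarray:
        out = np.empty_like(u)
        for i, kind in enumerate(self.kinds):
            if kind == "id":
                out[i] = u[i]
            elif kind == "lower":
                out[i] = self.lo[i] + u[i] ** 2
            elif kind == "upper":
                out[i] = self.hi[i] - u[i] ** 2
            else:
                span = self.hi[i] - self.lo[i]
                out[i] = self.lo[i] + span / (1.0 + np.exp(-np.clip(u[i], -40.0, 40.0)))
        return out

    def to_u(self, beta: np.ndarray) -> np.ndarray:
        out = np.empty_like(np.asarray(beta, float))
        for i, kind in enumerate(self.kinds):
            b = beta[i]
            if kind == "id":
                out[i] = b
            elif kind == "lower":
                out[i] = np.sqrt(max(b - self.lo[i], 0.0))
            elif kind == "upper":
                out[i] = np.sqrt(max(self.hi[i] - b, 0.0))
            else:
                span = self.hi[i] - self.lo[i]
                frac = np.clip((b - self.lo[i]) / span, 1e-6, 1 - 1e-6)
                out[i] = np.log(frac / (1 - frac))
        return out


# ---------------------------------------------------------------------------
# the simulation workspace
# ---------------------------------------------------------------------------


def _covariate_source(model: MetaModel, study: PriorStudy) -> CovariateSource | None:
    if not model.predictor_names:
        return None
    if study.covariate_table is not None:
        missing = [c for c in model.predictor_names if c not in study.covariate_table.columns]
        if missing:
            raise GMAError(
                f"study {study.study_id!r} covariate table lacks predictor(s) {missing}"
            )
        return TableSource(study.covariate_table[list(model.predictor_names)])
    if study.covariate_moments is None:
        raise GMAError(
            f"study {study.study_id!r} has neither covariate moments nor a covariate table"
        )
    mean, cov = study.covariate_moments
    if mean.shape[0] != len(model.predictor_names):
        raise GMAError(
            f"study {study.study_id!r} moments cover {mean.shape[0]} variables; the "
            f"meta-model needs all {len(model.predictor_names)} predictors "
            f"({model.predictor_names}) to simulate outcomes"
        )
    return MomentSource(mean, cov, names=model.predictor_names)


class _StudyWorkspace:
    """Pre-drawn randomness and bound replicators for one study."""

    def __init__(self, model: MetaModel, study: PriorStudy, n: int, S: int,
                 seed_seq: np.random.SeedSequence, retry_entropy: int):
        self.study = study
        self.n = n
        self.model = model
        self.retry_entropy = retry_entropy
        self.replicator = build_replicator(
            study.replicator_kind, study.covariate_subset, study.replicator_options
        )
        self.labels = self.replicator.labels
        self.empirical = None
        if study.empirical_signatures is not None:
            sv = study.empirical_signatures
            if set(sv.labels) != set(self.labels):
                raise GMAError(
                    f"study {study.study_id!r} empirical labels {sv.labels} do "
                    f"not match what the {study.replicator_kind} replicator "
                    f"produces ({self.labels})"
                )
            # align to the replicator's canonical ordering
            self.empirical = SignatureVector(
                self.labels, [sv[l] for l in self.labels]
            )
        rng = np.random.default_rng(seed_seq)
        self.source = _covariate_source(model, study)
        I = len(model.predictor_names)
        if self.source is None:
            self.X = np.zeros((S, n, 0))
        else:
            self.X = self.source.sample(S * n, rng).reshape(S, n, I)
        self.X_flat = self.X.reshape(S * n, I)
        if model.outcome_kind == "binary":
            self.unif = rng.random((S, n))
            self.eps = None
        else:
            self.eps = rng.standard_normal((S, n))
            self.unif = None
        self.z_re = rng.standard_normal(S) if model.random_effect_sd_param else None
        # measurement-noise machinery
        self.noise_cols = tuple(study.noise_params.keys())
        for col, pname in study.noise_params.items():
            if col not in model.predictor_names:
                raise GMAError(f"noise column {col!r} not a predictor of {model.name!r}")
            if pname not in model.param_names:
                raise GMAError(f"noise parameter {pname!r} not in the meta-model")
        self.noise_idx = [model.predictor_names.index(c) for c in self.noise_cols]
        self.noise_pnames = [study.noise_params[c] for c in self.noise_cols]
        self.noise_z = rng.standard_normal((S, n, len(self.noise_cols))) if self.noise_cols else None
        self.col_sd = (
            self.X[:, :, self.noise_idx].std(axis=1, ddof=1) if self.noise_cols else None
        )  # (S, #noisy)
        self.subset_idx = [model.predictor_names.index(c) for c in study.covariate_subset]
        self._bound_cache: dict[int, object] = {}

    def measured_X(self, S: int, beta: Mapping[str, float]) -> np.ndarray:
        base = self.X[:S][:, :, self.subset_idx]
        if not self.noise_cols:
            return base
        Xm = self.X[:S].copy()
        for j, (ci, pname) in enumerate(zip(self.noise_idx, self.noise_pnames)):
            delta = beta[pname]
            Xm[:, :, ci] += delta * self.col_sd[:S, j][:, None] * self.noise_z[:S, :, j]
        return Xm[:, :, self.subset_idx]

    def bound_for(self, S: int, beta: Mapping[str, float]):
        if self.noise_cols:
            return self.replicator.bind(self.measured_X(S, beta))
        if S not in self._bound_cache:
            self._bound_cache[S] = self.replicator.bind(self.X[:S][:, :, self.subset_idx])
        return self._bound_cache[S]

    def outcomes(self, S: int, beta: Mapping[str, float]) -> np.ndarray | None:
        model = self.model
        mu_flat = model.mean_function(self.X_flat[: S * self.n], beta)
        mu = np.asarray(mu_flat, float).reshape(S, self.n)
        if not np.all(np.isfinite(mu)):
            return None
        if model.outcome_kind == "binary":
            if mu.min() < -1e-12 or mu.max() > 1 + 1e-12:
                return None
            return (self.unif[:S] < mu).astype(float)
        y = mu
        if model.random_effect_sd_param:
            tau = beta[model.random_effect_sd_param]
            if tau < 0:
                return None
            y = y + tau * self.z_re[:S, None]
        if model.error_sd_param:
            sd = beta[model.error_sd_param]
            if sd < 0:
                return None
            y = y + sd * self.eps[:S]
        return y

    def simulate(self, S: int, beta: Mapping[str, float], retry_budget: int):
        """(values (S, m), bad mask (S,), n_retries) for this study."""
        y = self.outcomes(S, beta)
        if y is None:
            return None, np.ones(S, dtype=bool), 0
        bound = self.bound_for(S, beta)
        values, ok, _ = bound(y)
        n_retries = 0
        if not ok.all() and retry_budget > 0:
            for s in np.flatnonzero(~ok):
                for attempt in range(1, retry_budget + 1):
                    n_retries += 1
                    res = self._retry_once(int(s), attempt, beta)
                    if res is not None:
                        values[s] = res
                        ok[s] = True
                        break
        return values, ~ok, n_retries

    def _retry_once(self, s: int, attempt: int, beta: Mapping[str, float]):
        """Resimulate one replicate from a shifted sub-seed."""
        ss = np.random.SeedSequence([self.retry_entropy, s, attempt])
        rng = np.random.default_rng(ss)
        I = len(self.model.predictor_names)
        X = self.source.sample(self.n, rng) if self.source is not None else np.zeros((self.n, 0))
        mu = np.asarray(self.model.mean_function(X, beta), float)
        if not np.all(np.isfinite(mu)):
            return None
        if self.model.outcome_kind == "binary":
            y = (rng.random(self.n) < mu).astype(float)
        else:
            y = mu
            if self.model.random_effect_sd_param:
                y = y + beta[self.model.random_effect_sd_param] * rng.standard_normal()
            if self.model.error_sd_param:
                y = y + beta[self.model.error_sd_param] * rng.standard_normal(self.n)
        Xm = X.copy()
        for j, (ci, pname) in enumerate(zip(self.noise_idx, self.noise_pnames)):
            sd = X[:, ci].std(ddof=1)
            Xm[:, ci] = X[:, ci] + beta[pname] * sd * rng.standard_normal(self.n)
        bound = self.replicator.bind(Xm[None, :, self.subset_idx] if I else np.zeros((1, self.n, 0)))
        values, ok, _ = bound(y[None, :])
        return values[0] if ok[0] else None


class SignatureSimulator:
    """Simulates stacked signature vectors under common random numbers.

    The stacked order is: between-study block first (if any), then each
    study's signatures in study order, labels in replicator order.
    """

    def __init__(self, model: MetaModel, studies: Sequence[PriorStudy],
                 between: BetweenStudySpec | None = None,
                 plan: SimulationPlan | None = None):
        if not studies:
            raise GMAError("at least one prior study is required")
        self.model = model
        self.studies = list(studies)
        self.between = between
        self.plan = plan or SimulationPlan()
        self.S_max = max(self.plan.n_sim, self.plan.n_sim_final)
        root = np.random.SeedSequence(self.plan.seed)
        children = root.spawn(len(self.studies) + 2)
        self._weight_seed_seq = children[-2]
        self._retry_root = int(children[-1].generate_state(1)[0] & 0x7FFFFFFF)
        self.workspaces = [
            _StudyWorkspace(
                model, st, self.plan.study_n(st), self.S_max, children[i],
                retry_entropy=self._retry_root + i,
            )
            for i, st in enumerate(self.studies)
        ]
        labels = []
        self._between_names = ()
        if between is not None:
            for stat in between.stats:
                for ws in self.workspaces:
                    if stat.label not in ws.labels:
                        raise GMAError(
                            f"between-study statistic {stat.name!r} references "
                            f"label {stat.label!r} absent from study "
                            f"{ws.study.study_id!r}"
                        )
            self._between_names = tuple(s.name for s in between.stats)
            labels.extend(f"between::{n}" for n in self._between_names)
        self._blocks = []
        offset = len(labels)
        for ws in self.workspaces:
            labels.extend(f"{ws.study.study_id}::{l}" for l in ws.labels)
            self._blocks.append((offset, offset + len(ws.labels)))
            offset += len(ws.labels)
        self.stacked_labels = tuple(labels)
        self.n_signatures = len(labels)

    # -- empirical side ----------------------------------------------------

    def empirical_stacked(self) -> np.ndarray:
        parts = []
        if self.between is not None:
            if self.between.empirical is None:
                raise GMAError("between-study spec lacks empirical values")
            parts.append(self.between.empirical.values)
        for ws in self.workspaces:
            if ws.empirical is None:
                raise GMAError(f"study {ws.study.study_id!r} lacks empirical signatures")
            parts.append(ws.empirical.values)
        return np.concatenate(parts)

    # -- simulated side ----------------------------------------------------

    def signature_matrix(self, beta, n_sim: int | None = None):
        """Simulate ``n_sim`` stacked signature vectors at ``beta``.

        Returns (values (n_sim, K), bad-row mask, number of retried replicates).
        """
        S = int(n_sim or self.plan.n_sim)
        if S > self.S_max:
            raise GMAError(f"requested {S} replicates but only {self.S_max} are drawn")
        bdict = beta.as_dict() if isinstance(beta, ParameterVector) else dict(beta)
        per_study, bad = [], np.zeros(S, dtype=bool)
        retries = 0
        for ws in self.workspaces:
            values, bad_l, r = ws.simulate(S, bdict, self.plan.retry_budget)
            retries += r
            if values is None:
                return None, np.ones(S, dtype=bool), retries
            per_study.append(values)
            bad |= bad_l
        cols = []
        if self.between is not None:
            for stat in self.between.stats:
                mat = np.stack(
                    [vals[:, ws.labels.index(stat.label)]
                     for ws, vals in zip(self.workspaces, per_study)],
                    axis=1,
                )
                if stat.kind == "variance":
                    cols.append(mat.var(axis=1, ddof=1))
                else:
                    cols.append(mat.mean(axis=1))
        between_block = [np.stack(cols, axis=1)] if cols else []
        values = np.concatenate(between_block + per_study, axis=1)
        return values, bad, retries

    def mean_signatures(self, beta, n_sim: int | None = None):
        """Mean stacked signatures over replicates; returns (mean, n_bad, retries)."""
        values, bad, retries = self.signature_matrix(beta, n_sim)
        if values is None or bad.all():
            return None, int(bad.sum()), retries
        if bad.any():
            mean = values[~bad].mean(axis=0)
        else:
            mean = values.mean(axis=0)
        return mean, int(bad.sum()), retries

    def split_blocks(self, stacked: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        if self._between_names:
            out["between"] = stacked[: len(self._between_names)]
        for ws, (a, b) in zip(self.workspaces, self._blocks):
            out[ws.study.study_id] = stacked[a:b]
        return out

    def fresh(self, n_reps: int, seed_index: int) -> "SignatureSimulator":
        """An independent simulator (new draws) for weight estimation/bootstrap."""
        child = self._weight_seed_seq.spawn(seed_index + 1)[seed_index]
        seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        plan = replace(self.plan, seed=seed, n_sim=n_reps, n_sim_final=n_reps)
        return SignatureSimulator(self.model, self.studies, self.between, plan)


def simulate_signatures(model: MetaModel, beta, studies: Sequence[PriorStudy],
                        plan: SimulationPlan, between: BetweenStudySpec | None = None
                        ) -> list[SignatureVector]:
    """Simulate S stacked signature vectors under the plan (public operation)."""
    sim = SignatureSimulator(model, studies, between, plan)
    values, bad, _ = sim.signature_matrix(beta, plan.n_sim)
    if values is None:
        raise GMAError("simulation failed for every replicate (non-finite model output)")
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise GMAError(
            f"replicator did not converge for replicate {idx} after retries "
            f"(study set: {[s.study_id for s in studies]})"
        )
    return [SignatureVector(sim.stacked_labels, row) for row in values]


def update_weight(model: MetaModel, beta_hat, studies: Sequence[PriorStudy],
                  plan: SimulationPlan, n_reps: int | None = None,
                  ridge: float | None = None, between: BetweenStudySpec | None = None,
                  _sim: SignatureSimulator | None = None, _seed_index: int = 0) -> tuple[WeightMatrix, np.ndarray]:
    """Estimate W as the (ridged) inverse covariance of simulated signatures.

    Simulates ``n_reps`` independent stacked signature vectors at the studies'
    actual sample sizes and inverts their sample covariance.  Returns the
    weight matrix and the covariance estimate itself.
    """
    base = _sim or SignatureSimulator(model, studies, between, plan)
    n_reps = int(n_reps if n_reps is not None else plan.weight_reps)
    ridge = plan.weight_ridge if ridge is None else float(ridge)
    fresh = base.fresh(n_reps, _seed_index)
    values, bad, _ = fresh.signature_matrix(beta_hat, n_reps)
    if values is None:
        raise WeightUpdateError("simulation at beta_hat produced no usable replicates")
    if bad.any():
        values = values[~bad]
    if values.shape[0] < values.shape[1] + 2:
        raise WeightUpdateError(
            f"only {values.shape[0]} usable replicates for a {values.shape[1]}-"
            f"dimensional signature covariance; increase weight_reps"
        )
    sigma = np.cov(values, rowvar=False)
    sigma = np.atleast_2d(sigma)
    ridged = sigma + ridge * np.diag(np.diag(sigma))
    try:
        w = np.linalg.inv(ridged)
    except np.linalg.LinAlgError:
        w = None
    if w is None or not np.all(np.isfinite(w)):
        raise WeightUpdateError(
            "signature covariance is singular even after ridging; increase the "
            "ridge or prune collinear signatures"
        )
    cond = np.linalg.cond(ridged)
    if cond > 1e14:
        raise WeightUpdateError(
            f"signature covariance is numerically singular (condition number "
            f"{cond:.3g}); increase the ridge or prune collinear signatures"
        )
    w = 0.5 * (w + w.T)
    return (
        WeightMatrix(w, provenance="simulated-inverse-covariance", labels=base.stacked_labels),
        sigma,
    )


# ---------------------------------------------------------------------------
# fit result container
# ---------------------------------------------------------------------------


@dataclass
class GMAFit:
    """Everything a fit produced: estimates, weights, errors, fit statistics."""

    beta_hat: ParameterVector
    weight: WeightMatrix
    objective_value: float
    error: np.ndarray
    labels: tuple[str, ...]
    per_study_errors: dict[str, np.ndarray]
    chi0: float | None
    dof: int
    p_value: float | None
    msc: float | None
    covariance: np.ndarray | None
    sigma_hat: np.ndarray | None
    jacobian: np.ndarray | None
    n_sim_final: int
    plan: SimulationPlan
    model_name: str
    trace: list = field(default_factory=list)
    converged: bool = True
    n_bad_replicates: int = 0

    def standard_errors(self) -> np.ndarray | None:
        if self.covariance is None:
            return None
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------


class GMAEstimator:
    """Scikit-learn-style estimator for generalized model aggregation.

    Parameters mirror :class:`SimulationPlan`; ``fit(studies, between=...)``
    estimates the meta-model and exposes the results as fitted attributes
    (``params_``, ``beta_hat_``, ``covariance_``, ``chi0_``, ``dof_``,
    ``msc_``, ...).  ``predict(X)`` evaluates the fitted mean surface.
    """

    _param_spec = (
        "model", "start", "n_sim", "n_sim_final", "rounds", "n_starts", "jitter",
        "seed", "weight_reps", "weight_ridge", "polish", "maxiter", "retry_budget",
        "nonconvergence_penalty", "sample_size", "fixed_weight", "xatol", "fatol",
    )

    def __init__(self, model: MetaModel | None = None, start=None, *, n_sim: int = 50,
                 n_sim_final: int = 500, rounds: int = 3, n_starts: int = 5,
                 jitter: float = 0.5, seed: int = 0, weight_reps: int = 1000,
                 weight_ridge: float = 1e-6, polish: bool = True,
                 maxiter: int | None = None, retry_budget: int = 5,
                 nonconvergence_penalty: float = 1e8, sample_size=None,
                 fixed_weight: WeightMatrix | None = None,
                 xatol: float = 1e-5, fatol: float = 1e-10):
        self.model = model
        self.start = start
        self.n_sim = n_sim
        self.n_sim_final = n_sim_final
        self.rounds = rounds
        self.n_starts = n_starts
        self.jitter = jitter
        self.seed = seed
        self.weight_reps = weight_reps
        self.weight_ridge = weight_ridge
        self.polish = polish
        self.maxiter = maxiter
        self.retry_budget = retry_budget
        self.nonconvergence_penalty = nonconvergence_penalty
        self.sample_size = sample_size
        self.fixed_weight = fixed_weight
        self.xatol = xatol
        self.fatol = fatol

    # -- sklearn plumbing --------------------------------------------------

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_spec}

    def set_params(self, **params) -> "GMAEstimator":
        for k, v in params.items():
            if k not in self._param_spec:
                raise ValueError(f"invalid parameter {k!r} for GMAEstimator")
            setattr(self, k, v)
        return self

    def _plan(self) -> SimulationPlan:
        return SimulationPlan(
            n_sim=self.n_sim, n_sim_final=self.n_sim_final, seed=self.seed,
            sample_size=self.sample_size, rounds=self.rounds, n_starts=self.n_starts,
            jitter=self.jitter, weight_reps=self.weight_reps,
            weight_ridge=self.weight_ridge, polish=self.polish, maxiter=self.maxiter,
            retry_budget=self.retry_budget,
            nonconvergence_penalty=self.nonconvergence_penalty,
            xatol=self.xatol, fatol=self.fatol,
        )

    # -- fitting -----------------------------------------------------------

    def fit(self, studies: Sequence[PriorStudy], between: BetweenStudySpec | None = None):
        if self.model is None:
            raise GMAError("GMAEstimator needs a meta-model before fitting")
        model = self.model
        plan = self._plan()
        sim = SignatureSimulator(model, studies, between, plan)
        emp = sim.empirical_stacked()
        K, p = sim.n_signatures, model.n_params
        if K < p:
            raise UnderIdentifiedError(
                f"{K} signatures cannot identify {p} parameters; add studies or "
                f"signatures, or simplify the meta-model"
            )

        start = self.start if self.start is not None else model.default_parameters()
        if not isinstance(start, ParameterVector):
            start = model.make_parameters(start)
        bounds = dict(model.default_bounds)
        bounds.update(start.bounds)
        tf = _Transform(model.param_names, bounds)
        u0 = tf.to_u(start.values)

        W = self.fixed_weight or initial_weight(emp, plan.weight_floor)
        sigma_hat = None
        penalty = plan.nonconvergence_penalty
        bad_total = 0

        def make_objective(wmat: np.ndarray):
            def f(u: np.ndarray) -> float:
                if not np.all(np.isfinite(u)):
                    return penalty * K
                beta = tf.to_beta(u)
                mean, n_bad, _ = sim.mean_signatures(model.make_parameters(beta).as_dict(), plan.n_sim)
                if mean is None:
                    return penalty * K
                e = emp - mean
                return float(e @ wmat @ e) + penalty * n_bad / plan.n_sim
            return f

        rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 7_919]))
        scale = np.maximum(np.abs(u0), 1.0)
        starts = [u0] + [
            u0 + plan.jitter * scale * rng.standard_normal(u0.shape)
            for _ in range(max(plan.n_starts - 1, 0))
        ]

        trace: list[dict] = []
        best_u = u0
        opt_ok = True
        n_rounds = max(int(plan.rounds), 0)

        def minimize_at(wobj: WeightMatrix, start_points):
            nonlocal opt_ok
            f = make_objective(wobj.matrix)
            best = None
            for s0 in start_points:
                res = optimize.minimize(
                    f, s0, method="Nelder-Mead",
                    options={
                        "xatol": plan.xatol, "fatol": plan.fatol,
                        "maxiter": plan.maxiter or 250 * len(s0),
                        "adaptive": len(s0) > 4,
                    },
                )
                if best is None or res.fun < best.fun:
                    best = res
            if not best.success:
                opt_ok = False
            u_best = best.x
            if plan.polish:
                polished = self._polish(u_best, wobj.matrix, tf, sim, emp, plan)
                if polished is not None and f(polished) <= best.fun:
                    u_best = polished
            return u_best, f(u_best)

        for r in range(max(n_rounds, 1)):
            start_points = starts if r == 0 else [best_u]
            best_u, fval = minimize_at(W, start_points)
            trace.append({
                "round": r + 1,
                "beta": dict(zip(model.param_names, map(float, tf.to_beta(best_u)))),
                "objective": float(fval),
                "weight": W.provenance,
            })
            if n_rounds == 0:
                break
            if r < n_rounds:
                if self.fixed_weight is not None:
                    continue
                W, sigma_hat = update_weight(
                    model, model.make_parameters(tf.to_beta(best_u)).as_dict(),
                    studies, plan, between=between, _sim=sim, _seed_index=r,
                )

        beta_vals = tf.to_beta(best_u)
        beta_hat = ParameterVector(model.param_names, beta_vals, bounds)

        # final high-precision evaluation
        Sf = plan.n_sim_final
        mean_final, n_bad, _ = sim.mean_signatures(beta_hat.as_dict(), Sf)
        if mean_final is None:
            raise GMAError("final signature evaluation failed at the optimum")
        bad_total += n_bad
        e_final = emp - mean_final
        obj_final = float(e_final @ W.matrix @ e_final)
        dof = K - p

        chi0 = p_value = msc_val = None
        if W.provenance == "simulated-inverse-covariance":
            chi0 = float(Sf / (1.0 + Sf) * obj_final)
            msc_val = chi0 + 2.0 * p
            if dof >= 1:
                p_value = float(stats.chi2.sf(chi0, dof))

        D = self._jacobian_matrix(sim, beta_hat, plan)
        covariance = None
        if sigma_hat is not None:
            covariance = parameter_covariance_matrix(D, W.matrix, sigma_hat, n_sim=Sf)

        fit = GMAFit(
            beta_hat=beta_hat, weight=W, objective_value=obj_final, error=e_final,
            labels=sim.stacked_labels, per_study_errors=sim.split_blocks(e_final),
            chi0=chi0, dof=dof, p_value=p_value, msc=msc_val, covariance=covariance,
            sigma_hat=sigma_hat, jacobian=D, n_sim_final=Sf, plan=plan,
            model_name=model.name, trace=trace, converged=opt_ok,
            n_bad_replicates=bad_total,
        )
        self.simulator_ = sim
        self.fit_result_ = fit
        self.beta_hat_ = beta_hat
        self.params_ = beta_vals
        self.param_names_ = model.param_names
        self.weight_ = W
        self.sigma_hat_ = sigma_hat
        self.covariance_ = covariance
        self.objective_value_ = obj_final
        self.error_ = e_final
        self.labels_ = sim.stacked_labels
        self.chi0_ = chi0
        self.dof_ = dof
        self.p_value_ = p_value
        self.msc_ = msc_val
        self.jacobian_ = D
        self.trace_ = trace
        self.n_signatures_ = K
        return self

    @staticmethod
    def _polish(u0, wmat, tf, sim, emp, plan):
        """Gauss-Newton refinement on Cholesky-whitened residuals L' e(beta)."""
        try:
            L = np.linalg.cholesky(wmat + 1e-12 * np.diag(np.diag(wmat)))
        except np.linalg.LinAlgError:
            return None

        def resid(u):
            beta = tf.to_beta(u)
            mean, n_bad, _ = sim.mean_signatures(
                dict(zip(sim.model.param_names, beta)), plan.n_sim
            )
            if mean is None or n_bad > 0:
                return np.full(emp.shape[0], 1e6)
            return L.T @ (emp - mean)

        try:
            res = optimize.least_squares(
                resid, u0, method="lm" if emp.size >= u0.size else "trf",
                xtol=1e-10, ftol=1e-10, max_nfev=200 * len(u0),
            )
        except Exception:
            return None
        return res.x if np.all(np.isfinite(res.x)) else None

    @staticmethod
    def _jacobian_matrix(sim: SignatureSimulator, beta_hat: ParameterVector,
                         plan: SimulationPlan, rel_step: float = 1e-3) -> np.ndarray:
        """Central finite differences of S-averaged signatures (common random numbers)."""
        base = beta_hat.values
        K = sim.n_signatures
        D = np.zeros((K, base.size))
        for j in range(base.size):
            h = rel_step * max(abs(base[j]), 1.0)
            lo, hi = beta_hat.bounds.get(beta_hat.names[j], (None, None))
            up, down = base.copy(), base.copy()
            up[j] += h
            down[j] -= h
            if lo is not None and down[j] < lo:
                down[j] = lo
            if hi is not None and up[j] > hi:
                up[j] = hi
            span = up[j] - down[j]
            if span <= 0:
                continue
            m_up, _, _ = sim.mean_signatures(dict(zip(beta_hat.names, up)), plan.n_sim_final)
            m_dn, _, _ = sim.mean_signatures(dict(zip(beta_hat.names, down)), plan.n_sim_final)
            if m_up is None or m_dn is None:
                continue
            D[:, j] = (m_up - m_dn) / span
        zero_cols = [beta_hat.names[j] for j in range(base.size) if np.allclose(D[:, j], 0.0)]
        if zero_cols:
            warnings.warn(
                f"signatures are insensitive to parameter(s) {zero_cols}; "
                f"identification hazard", RuntimeWarning, stacklevel=2,
            )
        return D

    # -- post-fit conveniences ----------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Evaluate the fitted mean surface on a covariate table."""
        from .model_core import evaluate_mean

        self._check_fitted()
        return evaluate_mean(self.model, self.beta_hat_, X)

    def confidence_intervals(self, level: float = 0.95):
        """Wald confidence intervals from the analytic parameter covariance."""
        import pandas as pd

        self._check_fitted()
        if self.covariance_ is None:
            raise GMAError("no parameter covariance available (rounds=0 fit?)")
        se = np.sqrt(np.clip(np.diag(self.covariance_), 0.0, None))
        z = stats.norm.ppf(0.5 + level / 2.0)
        est = self.params_
        return pd.DataFrame(
            {
                "estimate": est,
                "se": se,
                "lower": est - z * se,
                "upper": est + z * se,
            },
            index=list(self.param_names_),
        )

    def _check_fitted(self):
        if not hasattr(self, "beta_hat_"):
            raise GMAError("this GMAEstimator instance is not fitted yet")


def parameter_covariance_matrix(D: np.ndarray, W: np.ndarray, sigma: np.ndarray,
                                n_sim: int | None = None) -> np.ndarray:
    """Sandwich covariance (D'WD)^-1 D'W Sigma W D (D'WD)^-1 (x simulation correction).

    Reduces to (D' Sigma^-1 D)^-1 at the optimal W = Sigma^-1.  The factor
    (1 + 1/S) accounts for residual Monte-Carlo noise in the S-averaged
    simulated signatures.
    """
    D = np.asarray(D, float)
    W = np.asarray(W, float)
    B = D.T @ W @ D
    try:
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError:
        raise GMAError(
            "D'WD is singular: some parameter combination is unidentified by the "
            "signatures"
        ) from None
    M = D.T @ W @ sigma @ W @ D
    cov = Binv @ M @ Binv
    if n_sim:
        cov = cov * (1.0 + 1.0 / float(n_sim))
    return 0.5 * (cov + cov.T)


def fit_gma(model: MetaModel, studies: Sequence[PriorStudy],
            between: BetweenStudySpec | None = None, start=None, **kwargs) -> GMAFit:
    """Functional wrapper around :class:`GMAEstimator`."""
    est = GMAEstimator(model=model, start=start, **kwargs)
    est.fit(studies, between=between)
    return est.fit_result_


def suggest_start(model: MetaModel, studies: Sequence[PriorStudy]) -> ParameterVector:
    """Heuristic starting values read off the published signatures.

    Coefficient parameters start at the mean of the matching published
    coefficients across studies (0 when never reported); the error sd starts
    at the root of the mean published MSE; random-effects means/variances
    start at the published effects' mean/dispersion.
    """
    vals = dict(model.default_parameters().as_dict())
    sums: dict[str, list[float]] = {}
    mses, effects, withins = [], [], []
    for st in studies:
        sv = st.empirical_signatures
        if sv is None:
            continue
        for label, v in sv.as_dict().items():
            if label == "intercept" and "intercept" in vals:
                sums.setdefault("intercept", []).append(v)
            elif label.startswith("b:") and label in model.param_names:
                sums.setdefault(label, []).append(v)
            elif label == "mse":
                mses.append(v)
            elif label == "effect":
                effects.append(v)
            elif label == "within_var":
                withins.append(v)
            elif label == "grand_mean" and "intercept" in vals:
                sums.setdefault("intercept", []).append(v)
    for k, v in sums.items():
        vals[k] = float(np.mean(v))
    if model.error_sd_param and mses:
        vals[model.error_sd_param] = float(np.sqrt(max(np.mean(mses), 1e-12)))
    if "mu" in vals and effects:
        vals["mu"] = float(np.mean(effects))
    if model.random_effect_sd_param and len(effects) >= 2:
        excess = np.var(effects, ddof=1) - (np.mean(withins) if withins else 0.0)
        vals[model.random_effect_sd_param] = float(np.sqrt(max(excess, 1e-4)))
    if model.error_sd_param == "sigma_w" and withins and studies:
        nbar = float(np.mean([s.n_obs for s in studies]))
        vals["sigma_w"] = float(np.sqrt(max(np.mean(withins) * nbar, 1e-8)))
    return model.make_parameters(vals)
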