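"""Meta-model declaration and evaluation.

A *meta-model* is a candidate data-generating process ``y = f(x, e; beta)``:
a deterministic mean function of explanatory variables plus an error model.
Its parameter vector ``beta`` includes the error-model parameters (e.g. the
error standard deviation for continuous outcomes), so a fully specified
``beta`` pins down the whole generating process.

Meta-models are declared through a registry of named mean-function builders
(``linear``, ``logistic``, ``random_effects``, ``fluid_leakage`` plus
user-registered ones) rather than parsed from formula strings.  Interaction,
quadratic and log terms are expressed inside the builders so covariate tables
stay raw and a single table can serve several candidate models.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GMAError",
    "MissingPredictorError",
    "NonFiniteOutputError",
    "SignatureVector",
    "ParameterVector",
    "MetaModel",
    "PriorStudy",
    "BetweenStudyStat",
    "BetweenStudySpec",
    "register_mean_function",
    "build_meta_model",
    "with_measurement_noise",
    "evaluate_mean",
    "simulate_response",
]


class GMAError(Exception):
    """Base class for errors raised by this package."""


class MissingPredictorError(GMAError):
    """A covariate table lacks a predictor required by the meta-model."""


class NonFiniteOutputError(GMAError):
    """The mean function produced a non-finite value."""


# ---------------------------------------------------------------------------
# signature vectors
# ---------------------------------------------------------------------------


class SignatureVector:
    """An ordered, labelled vector of statistics.

    This is the common currency between what a prior study published and what
    a simulated replication of that study produces.  Labels are unique within
    one vector and the ordering is significant: stacking across studies is
    deterministic (study order, then label order within a study).
    """

    __slots__ = ("labels", "values")

    def __init__(self, labels: Sequence[str], values: Sequence[float]):
        labels = tuple(str(l).strip() for l in labels)
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or len(labels) != values.shape[0]:
            raise GMAError(
                f"labels ({len(labels)}) and values ({values.shape}) do not align"
            )
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise GMAError(f"duplicate signature labels: {dupes}")
        self.labels = labels
        self.values = values

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SignatureVector)
            and self.labels == other.labels
            and np.array_equal(self.values, other.values)
        )

    def __getitem__(self, label: str) -> float:
        try:
            return float(self.values[self.labels.index(label)])
        except ValueError:
            raise KeyError(f"signature label {label!r} not present") from None

    def as_dict(self) -> dict[str, float]:
        return {l: float(v) for l, v in zip(self.labels, self.values)}

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        body = ", ".join(f"{l}={v:.6g}" for l, v in zip(self.labels, self.values))
        return f"SignatureVector({body})"

    @staticmethod
    def from_dict(d: Mapping[str, float]) -> "SignatureVector":
        return SignatureVector(tuple(d.keys()), np.array(list(d.values()), float))


# ---------------------------------------------------------------------------
# parameter vectors
# ---------------------------------------------------------------------------


@dataclass
class ParameterVector:
    """Named parameter values with optional per-parameter bounds."""

    names: tuple[str, ...]
    values: np.ndarray
    bounds: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise GMAError(
                f"parameter vector has {len(self.names)} names but "
                f"values of shape {self.values.shape}"
            )
        if len(set(self.names)) != len(self.names):
            raise GMAError("duplicate parameter names")
        for name, (lo, hi) in self.bounds.items():
            if name not in self.names:
                raise GMAError(f"bound given for unknown parameter {name!r}")
            v = self[name]
            if lo is not None and v < lo - 1e-12:
                raise GMAError(f"parameter {name!r}={v} below lower bound {lo}")
            if hi is not None and v > hi + 1e-12:
                raise GMAError(f"parameter {name!r}={v} above upper bound {hi}")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        try:
            return float(self.values[self.names.index(name)])
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}

    def with_values(self, values: Sequence[float]) -> "ParameterVector":
        return ParameterVector(self.names, np.asarray(values, float), dict(self.bounds))

    def to_json(self) -> str:
        return json.dumps(
            {
                "names": list(self.names),
                "values": list(map(float, self.values)),
                "bounds": {k: list(v) for k, v in self.bounds.items()},
            }
        )

    @staticmethod
    def from_json(s: str) -> "ParameterVector":
        d = json.loads(s)
        bounds = {
            k: (None if v[0] is None else float(v[0]), None if v[1] is None else float(v[1]))
            for k, v in d.get("bounds", {}).items()
        }
        return ParameterVector(tuple(d["names"]), np.array(d["values"], float), bounds)


# ---------------------------------------------------------------------------
# meta-models
# ---------------------------------------------------------------------------


@dataclass
class MetaModel:
    """A declared data-generating process ``y = f(x, e; beta)``.

    ``mean_function(X, beta)`` maps an ``(n, I)`` covariate array (columns in
    ``predictor_names`` order) and a parameter mapping to one mean value per
    row (a probability for binary outcomes).  The error model is additive
    normal for continuous outcomes (standard deviation held in
    ``error_sd_param``); binary outcomes are Bernoulli at the evaluated
    probability and carry no error parameter.  ``random_effect_sd_param``, if
    set, names the standard deviation of a study-level normal intercept shift
    shared by all rows of one simulated study sample (the random-effects
    meta-analysis case).  ``noise_params`` lists measurement-error parameters
    (fractions of a predictor's standard deviation) that the estimator may
    attach to individual studies.
    """

    name: str
    param_names: tuple[str, ...]
    predictor_names: tuple[str, ...]
    mean_function: Callable[[np.ndarray, Mapping[str, float]], np.ndarray]
    outcome_kind: str = "continuous"  # or "binary"
    error_sd_param: str | None = "sigma"
    random_effect_sd_param: str | None = None
    noise_params: tuple[str, ...] = ()
    default_values: dict[str, float] = field(default_factory=dict)
    default_bounds: dict[str, tuple[float | None, float | None]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        self.param_names = tuple(self.param_names)
        self.predictor_names = tuple(self.predictor_names)
        if len(set(self.param_names)) != len(self.param_names):
            raise GMAError("duplicate parameter names in meta-model")
        if self.outcome_kind not in ("continuous", "binary"):
            raise GMAError(f"unknown outcome kind {self.outcome_kind!r}")
        if self.outcome_kind == "binary" and self.error_sd_param is not None:
            raise GMAError("binary meta-models carry no error sd parameter")
        for p in (self.error_sd_param, self.random_effect_sd_param, *self.noise_params):
            if p is not None and p not in self.param_names:
                raise GMAError(f"error-model parameter {p!r} missing from param_names")

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def default_parameters(self) -> ParameterVector:
        vals = [self.default_values.get(n, 0.0) for n in self.param_names]
        return ParameterVector(self.param_names, np.array(vals, float), dict(self.default_bounds))

    def make_parameters(self, values: Mapping[str, float] | Sequence[float]) -> ParameterVector:
        if isinstance(values, Mapping):
            missing = [n for n in self.param_names if n not in values]
            if missing:
                raise GMAError(f"missing parameter values for {missing}")
            arr = np.array([values[n] for n in self.param_names], float)
        else:
            arr = np.asarray(values, float)
        return ParameterVector(self.param_names, arr, dict(self.default_bounds))


def _as_predictor_array(model: MetaModel, X) -> np.ndarray:
    """Reorder/validate a covariate table into ``(n, I)`` ndarray form."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in model.predictor_names if c not in X.columns]
        if missing:
            raise MissingPredictorError(
                f"covariate table lacks predictor column(s) {missing} "
                f"required by meta-model {model.name!r}"
            )
        return X[list(model.predictor_names)].to_numpy(dtype=float)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[1] != len(model.predictor_names):
        raise MissingPredictorError(
            f"covariate array has {arr.shape[1]} columns; meta-model "
            f"{model.name!r} expects {len(model.predictor_names)} "
            f"({model.predictor_names})"
        )
    return arr


def evaluate_mean(model: MetaModel, beta, X) -> np.ndarray:
    """Evaluate the deterministic mean function, one value per covariate row."""
    arr = _as_predictor_array(model, X)
    bdict = beta.as_dict() if isinstance(beta, ParameterVector) else dict(beta)
    missing = [n for n in model.param_names if n not in bdict]
    if missing:
        raise GMAError(f"incomplete parameter vector; missing {missing}")
    out = np.asarray(model.mean_function(arr, bdict), dtype=float)
    if out.shape != (arr.shape[0],):
        raise GMAError(
            f"mean function returned shape {out.shape}, expected ({arr.shape[0]},)"
        )
    if not np.all(np.isfinite(out)):
        bad = int(np.flatnonzero(~np.isfinite(out))[0])
        raise NonFiniteOutputError(
            f"mean function of {model.name!r} is non-finite at row {bad}"
        )
    if model.outcome_kind == "binary" and (out.min() < -1e-12 or out.max() > 1 + 1e-12):
        raise GMAError("binary meta-model mean function left [0, 1]")
    return out


def simulate_response(model: MetaModel, beta, X, seed) -> np.ndarray:
    """Draw one outcome vector from the meta-model.  Identical seed, identical output."""
    if seed is None:
        raise GMAError("simulate_response requires an explicit seed")
    mu = evaluate_mean(model, beta, X)
    bdict = beta.as_dict() if isinstance(beta, ParameterVector) else dict(beta)
    rng = np.random.default_rng(seed)
    if model.outcome_kind == "binary":
        return (rng.random(mu.shape[0]) < mu).astype(float)
    y = mu.copy()
    if model.random_effect_sd_param is not None:
        tau = bdict[model.random_effect_sd_param]
        if tau < 0:
            raise GMAError(
                f"random-effect sd parameter {model.random_effect_sd_param!r} is negative"
            )
        y = y + tau * rng.standard_normal()
    if model.error_sd_param is not None:
        sd = bdict[model.error_sd_param]
        if sd < 0:
            raise GMAError(f"error sd parameter {model.error_sd_param!r} is negative")
        y = y + sd * rng.standard_normal(mu.shape[0])
    return y


# ---------------------------------------------------------------------------
# prior studies and between-study signatures
# ---------------------------------------------------------------------------


@dataclass
class PriorStudy:
    """One published study to be replicated in simulation.

    ``replicator_kind`` is one of ``ols | logistic | anova | effect_size``;
    ``replicator_options`` carries kind-specific settings (ANOVA cutpoints,
    whether R^2 was reported, ...).  ``empirical_signatures`` is the study's
    published statistic vector.  Explanatory-variable samples come from
    ``covariate_table`` if given, else a multivariate-normal draw from
    ``covariate_moments`` (mean vector and covariance over the meta-model's
    full predictor list).  ``noise_params`` maps predictor columns to
    measurement-error parameters of the meta-model (the measurement channel
    of this study).
    """

    study_id: str
    n_obs: int
    covariate_subset: tuple[str, ...]
    replicator_kind: str
    replicator_options: dict = field(default_factory=dict)
    empirical_signatures: SignatureVector | None = None
    covariate_moments: tuple[np.ndarray, np.ndarray] | None = None
    covariate_table: pd.DataFrame | None = None
    noise_params: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.covariate_subset = tuple(self.covariate_subset)
        self.n_obs = int(self.n_obs)
        if self.n_obs < 1:
            raise GMAError(f"study {self.study_id!r} has non-positive n_obs")
        if self.covariate_moments is not None:
            mean, cov = self.covariate_moments
            self.covariate_moments = (
                np.asarray(mean, float),
                np.asarray(cov, float),
            )


@dataclass(frozen=True)
class BetweenStudyStat:
    """One statistic computed across studies' per-study signatures."""

    name: str
    kind: str  # "variance" | "mean"
    label: str  # per-study signature label it aggregates

    def __post_init__(self):
        if self.kind not in ("variance", "mean"):
            raise GMAError(f"unknown between-study statistic kind {self.kind!r}")


@dataclass
class BetweenStudySpec:
    """Between-study signature block: definitions plus their empirical values."""

    stats: tuple[BetweenStudyStat, ...]
    empirical: SignatureVector | None = None

    def __post_init__(self):
        self.stats = tuple(self.stats)
        if self.empirical is not None:
            want = tuple(s.name for s in self.stats)
            if self.empirical.labels != want:
                raise GMAError(
                    f"between-study empirical labels {self.empirical.labels} "
                    f"do not match statistic names {want}"
                )


# ---------------------------------------------------------------------------
# mean-function registry
# ---------------------------------------------------------------------------

_MEAN_BUILDERS: dict[str, Callable[..., MetaModel]] = {}


def register_mean_function(name: str):
    """Register a meta-model builder under ``name`` (decorator)."""

    def deco(fn):
        _MEAN_BUILDERS[name] = fn
        return fn

    return deco


def build_meta_model(kind: str, predictors: Sequence[str] = (), **options) -> MetaModel:
    """Construct a meta-model from the registry of named builders."""
    if kind not in _MEAN_BUILDERS:
        raise GMAError(
            f"unknown meta-model kind {kind!r}; known: {sorted(_MEAN_BUILDERS)}"
        )
    return _MEAN_BUILDERS[kind](tuple(predictors), **options)


_TERM_RE = re.compile(
    r"^(?P<log>log\((?P<logvar>\w+)\))$|^(?P<sq>(?P<sqvar>\w+)\^2)$|"
    r"^(?P<int>(?P<a>\w+)\*(?P<b>\w+))$|^(?P<plain>\w+)$"
)


def _compile_term(term: str, predictors: tuple[str, ...]):
    """Turn a term string (``x1``, ``x1*x2``, ``x1^2``, ``log(x1)``) into a column function."""
    m = _TERM_RE.match(term.replace(" ", ""))
    idx = {p: i for i, p in enumerate(predictors)}

    def col(name: str) -> int:
        if name not in idx:
            raise GMAError(f"term {term!r} references unknown predictor {name!r}")
        return idx[name]

    if m is None:
        raise GMAError(f"cannot parse model term {term!r}")
    if m.group("plain"):
        j = col(m.group("plain"))
        return lambda X: X[:, j]
    if m.group("int"):
        a, b = col(m.group("a")), col(m.group("b"))
        return lambda X: X[:, a] * X[:, b]
    if m.group("sq"):
        j = col(m.group("sqvar"))
        return lambda X: X[:, j] ** 2
    j = col(m.group("logvar"))

    def logcol(X):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.log(X[:, j])

    return logcol


def _linear_mean(predictors, terms):
    fns = [_compile_term(t, predictors) for t in terms]
    pnames = [f"b:{t}" for t in terms]

    def mean(X, beta):
        out = np.full(X.shape[0], beta["intercept"], dtype=float)
        for t, fn in zip(pnames, fns):
            out += beta[t] * fn(X)
        return out

    return mean, pnames


@register_mean_function("linear")
def _build_linear(predictors, terms=None, sigma0=1.0, name="linear"):
    """Linear-in-parameters continuous model: intercept + sum of terms + N(0, sigma^2)."""
    terms = tuple(terms) if terms is not None else tuple(predictors)
    mean, pnames = _linear_mean(predictors, terms)
    params = ("intercept", *pnames, "sigma")
    defaults = {n: 0.0 for n in params}
    defaults["sigma"] = float(sigma0)
    return MetaModel(
        name=name,
        param_names=params,
        predictor_names=predictors,
        mean_function=mean,
        outcome_kind="continuous",
        error_sd_param="sigma",
        default_values=defaults,
        default_bounds={"sigma": (0.0, None)},
    )


@register_mean_function("logistic")
def _build_logistic(predictors, terms=None, name="logistic"):
    """Binary-outcome model: Pr(y=1) = expit(intercept + sum of terms)."""
    terms = tuple(terms) if terms is not None else tuple(predictors)
    lin, pnames = _linear_mean(predictors, terms)

    def mean(X, beta):
        eta = lin(X, beta)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-eta))

    params = ("intercept", *pnames)
    return MetaModel(
        name=name,
        param_names=params,
        predictor_names=predictors,
        mean_function=mean,
        outcome_kind="binary",
        error_sd_param=None,
        default_values={n: 0.0 for n in params},
    )


@register_mean_function("random_effects")
def _build_random_effects(predictors=(), name="random_effects"):
    """Random-effects meta-analysis truth: y = mu + N(0, tau^2) per study + N(0, sigma_w^2)."""
    if predictors:
        raise GMAError("random_effects meta-model takes no predictors")

    def mean(X, beta):
        return np.full(X.shape[0], beta["mu"], dtype=float)

    return MetaModel(
        name=name,
        param_names=("mu", "tau", "sigma_w"),
        predictor_names=(),
        mean_function=mean,
        outcome_kind="continuous",
        error_sd_param="sigma_w",
        random_effect_sd_param="tau",
        default_values={"mu": 0.0, "tau": 0.1, "sigma_w": 1.0},
        default_bounds={"tau": (0.0, None), "sigma_w": (0.0, None)},
    )


@register_mean_function("fluid_leakage")
def _build_fluid_leakage(predictors=("time", "temperature"), center=50.0, name="fluid_leakage"):
    """Nonlinear leakage surface: b0 + rate * time^2 * exp(k * (temperature - center))."""
    if len(predictors) != 2:
        raise GMAError("fluid_leakage expects exactly two predictors (time, temperature)")

    def mean(X, beta):
        t, temp = X[:, 0], X[:, 1]
        with np.errstate(over="ignore"):
            return beta["intercept"] + beta["rate"] * t**2 * np.exp(
                beta["temp_sensitivity"] * (temp - center)
            )

    return MetaModel(
        name=name,
        param_names=("intercept", "rate", "temp_sensitivity", "sigma"),
        predictor_names=tuple(predictors),
        mean_function=mean,
        outcome_kind="continuous",
        error_sd_param="sigma",
        default_values={
            "intercept": 0.0,
            "rate": 0.01,
            "temp_sensitivity": 0.0,
            "sigma": 1.0,
        },
        default_bounds={"sigma": (0.0, None)},
    )


def with_measurement_noise(model: MetaModel, columns: Sequence[str], delta0: float = 0.1) -> MetaModel:
    """Augment a meta-model with measurement-noise parameters ``delta:<col>``.

    Each parameter is the measurement-noise standard deviation of one
    predictor expressed as a fraction (in [0, 1]) of that predictor's actual
    standard deviation; studies opt in via their ``noise_params`` mapping.
    """
    new_params = []
    for c in columns:
        if c not in model.predictor_names:
            raise GMAError(f"noise column {c!r} is not a predictor of {model.name!r}")
        new_params.append(f"delta:{c}")
    defaults = dict(model.default_values)
    bounds = dict(model.default_bounds)
    for p in new_params:
        defaults[p] = float(delta0)
        bounds[p] = (0.0, 1.0)
    return MetaModel(
        name=f"{model.name}+measurement_noise",
        param_names=model.param_names + tuple(new_params),
        predictor_names=model.predictor_names,
        mean_function=model.mean_function,
        outcome_kind=model.outcome_kind,
        error_sd_param=model.error_sd_param,
        random_effect_sd_param=model.random_effect_sd_param,
        noise_params=model.noise_params + tuple(new_params),
        default_values=defaults,
        default_bounds=bounds,
    )
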