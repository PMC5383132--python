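"""Signature functions: faithful re-runs of prior studies' statistical procedures.

Each replicator re-executes one study's published analysis (OLS, logistic
regression, ANOVA on discretized factors, or effect-size reporting) on
simulated data and returns the same statistics the study published, as a
labelled :class:`~gma.model_core.SignatureVector`.

Because the estimation objective evaluates every replicator hundreds of times
per optimizer step, each replicator also exposes a *batched* path:
``bind(X_stack)`` fixes the covariate draws for all ``S`` simulation
replicates at once (they do not change with the candidate parameters under
common random numbers) and returns a callable mapping the ``(S, n)`` outcome
stack to an ``(S, m)`` signature stack.  The scalar ``run(X, y)`` API wraps
the batched path with ``S = 1``.

Numerical conventions (documented per-operation below): OLS mean squared
error uses the residual mean square denominator ``n - p`` by default; R^2 of
a constant-outcome fit is reported as 0; ANOVA effects use sum-to-zero
coding; between-study sample variances use denominator ``L - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import BetweenStudySpec, GMAError, SignatureVector

__all__ = [
    "ReplicatorResult",
    "Replicator",
    "OLSReplicator",
    "LogisticReplicator",
    "AnovaReplicator",
    "EffectSizeReplicator",
    "build_replicator",
    "ols_signatures",
    "logistic_signatures",
    "anova_signatures",
    "effect_size_signatures",
    "discretize",
    "between_study_statistics",
]


@dataclass
class ReplicatorResult:
    """Outcome of one replication: signatures when converged, a note when not."""

    signatures: SignatureVector | None
    converged: bool
    notes: str = ""

    def __post_init__(self):
        if not self.converged and self.signatures is not None:
            raise GMAError("non-converged replications must not carry signatures")


def _as_matrix(X, subset: tuple[str, ...]) -> np.ndarray:
    """Extract the study's covariate subset as an (n, k) array, in subset order."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in subset if c not in X.columns]
        if missing:
            raise GMAError(f"covariate table lacks column(s) {missing}")
        return X[list(subset)].to_numpy(dtype=float)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[1] != len(subset):
        raise GMAError(
            f"covariate array has {arr.shape[1]} columns, replicator expects "
            f"{len(subset)} ({subset})"
        )
    return arr


class Replicator:
    """Base class: a study's statistical procedure h(X, y)."""

    kind: str = ""
    subset: tuple[str, ...] = ()

    @property
    def labels(self) -> tuple[str, ...]:  # pragma: no cover - overridden
        raise NotImplementedError

    def bind(self, X_stack: np.ndarray):  # pragma: no cover - overridden
        """Fix covariate draws; return f(Y_stack) -> (values (S, m), converged (S,), note)."""
        raise NotImplementedError

    def run(self, X, y) -> ReplicatorResult:
        """Apply the procedure to one dataset."""
        arr = _as_matrix(X, self.subset) if self.subset else np.empty((len(y), 0))
        y = np.asarray(y, dtype=float).ravel()
        if arr.shape[0] != y.shape[0]:
            raise GMAError("X and y lengths differ")
        bound = self.bind(arr[None, :, :])
        values, conv, note = bound(y[None, :])
        if not conv[0]:
            return ReplicatorResult(None, False, note or "replication did not converge")
        return ReplicatorResult(SignatureVector(self.labels, values[0]), True, note)


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------


@dataclass
class OLSReplicator(Replicator):
    """Ordinary least squares with intercept.

    Signatures: ``intercept``, ``b:<col>`` per subset column, optionally
    ``mse`` (residual mean square, SSE/(n-p) by default, SSE/n when
    ``mse_denominator='n'``) and ``r2`` (coefficient of determination, defined
    as 0 for a constant outcome).
    """

    subset: tuple[str, ...] = ()
    include_mse: bool = True
    include_r2: bool = False
    mse_denominator: str = "n-p"

    kind = "ols"

    def __post_init__(self):
        self.subset = tuple(self.subset)
        if self.mse_denominator not in ("n-p", "n"):
            raise GMAError(f"unknown mse denominator {self.mse_denominator!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        out = ["intercept", *(f"b:{c}" for c in self.subset)]
        if self.include_mse:
            out.append("mse")
        if self.include_r2:
            out.append("r2")
        return tuple(out)

    def bind(self, X_stack: np.ndarray):
        S, n, k = X_stack.shape
        p = k + 1
        if n <= p:
            raise GMAError(f"OLS needs n > {p} observations, got {n}")
        A = np.concatenate([np.ones((S, n, 1)), X_stack], axis=2)
        G = np.einsum("sni,snj->sij", A, A)
        # Rank/conditioning check on the fixed designs (independent of y).
        ok = np.ones(S, dtype=bool)
        eig = np.linalg.eigvalsh(G)
        ok &= eig[:, 0] > 1e-10 * np.maximum(eig[:, -1], 1.0)
        try:
            Ginv = np.linalg.inv(np.where(ok[:, None, None], G, np.eye(p)))
        except np.linalg.LinAlgError:  # pragma: no cover - guarded by eig check
            ok[:] = False
            Ginv = np.tile(np.eye(p), (S, 1, 1))
        denom = (n - p) if self.mse_denominator == "n-p" else n

        def compute(Y: np.ndarray):
            aty = np.einsum("snp,sn->sp", A, Y)
            coef = np.einsum("spq,sq->sp", Ginv, aty)
            cols = [coef]
            if self.include_mse or self.include_r2:
                resid = Y - np.einsum("snp,sp->sn", A, coef)
                sse = np.einsum("sn,sn->s", resid, resid)
            if self.include_mse:
                cols.append((sse / denom)[:, None])
            if self.include_r2:
                centered = Y - Y.mean(axis=1, keepdims=True)
                sst = np.einsum("sn,sn->s", centered, centered)
                r2 = np.where(sst > 1e-12 * n, 1.0 - sse / np.where(sst > 0, sst, 1.0), 0.0)
                cols.append(r2[:, None])
            values = np.concatenate(cols, axis=1)
            note = "" if ok.all() else "rank-deficient design"
            return values, ok.copy(), note

        return compute


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


@dataclass
class LogisticReplicator(Replicator):
    """Maximum-likelihood logistic regression with intercept.

    Fitted by Newton-Raphson on the log-likelihood, batched across simulation
    replicates.  Complete or quasi-complete separation and non-convergence
    are flagged rather than returning arbitrary coefficients.
    """

    subset: tuple[str, ...] = ()
    max_iter: int = 40
    tol: float = 1e-9
    coef_cap: float = 30.0

    kind = "logistic"

    def __post_init__(self):
        self.subset = tuple(self.subset)

    @property
    def labels(self) -> tuple[str, ...]:
        return ("intercept", *(f"b:{c}" for c in self.subset))

    def bind(self, X_stack: np.ndarray):
        S, n, k = X_stack.shape
        p = k + 1
        A = np.concatenate([np.ones((S, n, 1)), X_stack], axis=2)
        eye = np.eye(p)

        def compute(Y: np.ndarray):
            both = (Y.max(axis=1) > 0.5) & (Y.min(axis=1) < 0.5)
            beta = np.zeros((S, p))
            active = both.copy()
            converged = np.zeros(S, dtype=bool)
            for _ in range(self.max_iter):
                idx = np.flatnonzero(active)
                if idx.size == 0:
                    break
                Ai, bi = A[idx], beta[idx]
                eta = np.clip(np.einsum("snp,sp->sn", Ai, bi), -35.0, 35.0)
                mu = 1.0 / (1.0 + np.exp(-eta))
                w = mu * (1.0 - mu)
                g = np.einsum("snp,sn->sp", Ai, Y[idx] - mu)
                H = np.einsum("snp,sn,snq->spq", Ai, w, Ai) + 1e-10 * eye
                try:
                    step = np.linalg.solve(H, g[:, :, None])[:, :, 0]
                except np.linalg.LinAlgError:
                    break
                # Damp outsized steps (keeps divergence detectable, not explosive).
                norms = np.maximum(np.linalg.norm(step, axis=1), 1e-12)
                step = np.where((norms > 5.0)[:, None], step * (5.0 / norms)[:, None], step)
                beta[idx] = bi + step
                done = np.abs(g).max(axis=1) < self.tol * n
                converged[idx[done]] = True
                active[idx[done]] = False
                capped = np.abs(beta[idx]).max(axis=1) > self.coef_cap
                active[idx[capped]] = False
            # separation: coefficients ran away, or every observation is
            # perfectly predicted at the stationary point
            eta = np.clip(np.einsum("snp,sp->sn", A, beta), -35.0, 35.0)
            mu = 1.0 / (1.0 + np.exp(-eta))
            perfect = np.abs(Y - mu).max(axis=1) < 1e-5
            sep = both & ((np.abs(beta).max(axis=1) > self.coef_cap) | perfect)
            ok = converged & both & ~sep
            notes = []
            if (~both).any():
                notes.append("single outcome class")
            if sep.any() or (both & ~converged & ~sep).any():
                notes.append("separation or non-convergence detected")
            return beta, ok, "; ".join(notes)

        return compute


# ---------------------------------------------------------------------------
# ANOVA on discretized factors
# ---------------------------------------------------------------------------


def discretize(values, cutpoints: Sequence[float]) -> np.ndarray:
    """Assign levels 1..k+1 by within-sample empirical percentiles.

    ``cutpoints`` are percentile positions, strictly increasing in (0, 100).
    Boundary values fall in the lower bin (left-closed convention); a level
    assignment is invariant under monotone transforms of ``values``.
    """
    values = np.asarray(values, dtype=float).ravel()
    cut = np.asarray(cutpoints, dtype=float).ravel()
    if cut.size == 0 or np.any(cut <= 0) or np.any(cut >= 100) or np.any(np.diff(cut) <= 0):
        raise GMAError("cutpoints must be strictly increasing percentiles in (0, 100)")
    if values.size and np.all(values == values[0]):
        raise GMAError("degenerate binning: all values identical")
    thresholds = np.percentile(values, cut)
    return np.searchsorted(thresholds, values, side="left") + 1


def _levels_batch(X_col: np.ndarray, cutpoints) -> tuple[np.ndarray, int]:
    """Per-replicate discretization of an (S, n) column stack."""
    cut = np.asarray(cutpoints, dtype=float).ravel()
    S, n = X_col.shape
    levels = np.empty((S, n), dtype=np.int64)
    for s in range(S):
        levels[s] = discretize(X_col[s], cut)
    return levels, cut.size + 1


def _sum_to_zero_design(levels: np.ndarray, k: int) -> np.ndarray:
    """(S, n, k-1) sum-to-zero dummy block for levels in 1..k."""
    S, n = levels.shape
    D = np.zeros((S, n, k - 1))
    for j in range(1, k):
        D[:, :, j - 1] = np.where(levels == j, 1.0, np.where(levels == k, -1.0, 0.0))
    return D


def _compile_lstsq(design: np.ndarray):
    """Precompute the fixed-design least-squares solve for a (S, n, q) stack.

    Returns (ok, solve) where solve(Y) -> (coef, rss); the Gram inverse and
    rank check are done once, per-outcome work is two matmuls.
    """
    G = np.einsum("sni,snj->sij", design, design)
    eig = np.linalg.eigvalsh(G)
    ok = eig[:, 0] > 1e-10 * np.maximum(eig[:, -1], 1.0)
    q = design.shape[2]
    Ginv = np.linalg.inv(np.where(ok[:, None, None], G, np.eye(q)))

    def solve(Y: np.ndarray):
        aty = np.einsum("snq,sn->sq", design, Y)
        coef = np.einsum("spq,sq->sp", Ginv, aty)
        resid = Y - np.einsum("snq,sq->sn", design, coef)
        rss = np.einsum("sn,sn->s", resid, resid)
        return coef, rss

    return ok, solve


@dataclass
class AnovaReplicator(Replicator):
    """Fixed-effects ANOVA on factors formed by percentile discretization.

    ``factors`` is a sequence of ``(column, cutpoints)`` pairs; each covariate
    is cut into levels at within-sample percentiles, then a one-way or
    two-way (additive, optionally with interaction) ANOVA is run.

    Signatures: grand mean, per-level main effects in sum-to-zero coding
    (``eff:<col>:<level>``), one mean square due to treatment per factor
    (``mst:<col>``, plus ``mst:<a>*<b>`` with an interaction), and the mean
    squared error — 6 signatures for a 3-level one-way design, 7 for a
    4-level one-way design, 11 for the additive two-factor design.

    One-way designs use the classical decomposition (raw grand mean,
    level-mean effects, between-group mean square).  Multi-factor designs use
    least squares in sum-to-zero coding with Type-II treatment sums of
    squares, which coincides with the classical table for balanced data.
    """

    factors: tuple[tuple[str, tuple[float, ...]], ...] = ()
    include_interaction: bool = False

    kind = "anova"

    def __post_init__(self):
        self.factors = tuple((str(c), tuple(map(float, cp))) for c, cp in self.factors)
        if not self.factors:
            raise GMAError("AnovaReplicator needs at least one factor")
        if len(self.factors) > 2:
            raise GMAError("at most two factors supported")
        if self.include_interaction and len(self.factors) != 2:
            raise GMAError("interaction requires exactly two factors")
        self.subset = tuple(c for c, _ in self.factors)

    @property
    def labels(self) -> tuple[str, ...]:
        out = ["grand_mean"]
        for col, cuts in self.factors:
            out.extend(f"eff:{col}:{j + 1}" for j in range(len(cuts) + 1))
        for col, _ in self.factors:
            out.append(f"mst:{col}")
        if self.include_interaction:
            a, b = self.subset
            out.append(f"mst:{a}*{b}")
        out.append("mse")
        return tuple(out)

    def bind(self, X_stack: np.ndarray):
        S, n, _ = X_stack.shape
        level_sets, ks = [], []
        for j, (_, cuts) in enumerate(self.factors):
            lv, k = _levels_batch(X_stack[:, :, j], cuts)
            level_sets.append(lv)
            ks.append(k)
        ok0 = np.ones(S, dtype=bool)
        for lv, k in zip(level_sets, ks):
            counts = np.stack([(lv == j + 1).sum(axis=1) for j in range(k)], axis=1)
            ok0 &= (counts > 0).all(axis=1)

        if len(self.factors) == 1:
            lv, k = level_sets[0], ks[0]
            masks = np.stack([(lv == j + 1) for j in range(k)], axis=2).astype(float)
            counts = masks.sum(axis=1)  # (S, k)
            safe_counts = np.where(counts > 0, counts, 1.0)

            def compute_oneway(Y: np.ndarray):
                grand = Y.mean(axis=1)
                level_sums = np.einsum("snk,sn->sk", masks, Y)
                level_means = level_sums / safe_counts
                effects = level_means - grand[:, None]
                ssb = np.einsum("sk,sk->s", counts, effects**2)
                mst = ssb / (k - 1)
                yhat = np.einsum("snk,sk->sn", masks, level_means)
                resid = Y - yhat
                sse = np.einsum("sn,sn->s", resid, resid)
                mse = sse / np.maximum(n - k, 1)
                values = np.concatenate(
                    [grand[:, None], effects, mst[:, None], mse[:, None]], axis=1
                )
                note = "" if ok0.all() else "empty factor cell"
                return values, ok0.copy(), note

            return compute_oneway

        # two factors: sum-to-zero least squares, Type-II sums of squares
        ka, kb = ks
        Da = _sum_to_zero_design(level_sets[0], ka)
        Db = _sum_to_zero_design(level_sets[1], kb)
        ones = np.ones((S, n, 1))
        D_add = np.concatenate([ones, Da, Db], axis=2)
        D_noA = np.concatenate([ones, Db], axis=2)
        D_noB = np.concatenate([ones, Da], axis=2)
        if self.include_interaction:
            inter = np.einsum("sni,snj->snij", Da, Db).reshape(S, n, (ka - 1) * (kb - 1))
            D_full = np.concatenate([D_add, inter], axis=2)
        else:
            D_full = D_add
        p_full = D_full.shape[2]
        ok_add, solve_add = _compile_lstsq(D_add)
        _, solve_noA = _compile_lstsq(D_noA)
        _, solve_noB = _compile_lstsq(D_noB)
        if self.include_interaction:
            ok_full, solve_full = _compile_lstsq(D_full)
        else:
            ok_full, solve_full = ok_add, solve_add

        def compute_twoway(Y: np.ndarray):
            coef_add, rss_add = solve_add(Y)
            if self.include_interaction:
                _, rss_full = solve_full(Y)
            else:
                rss_full = rss_add
            _, rss_noA = solve_noA(Y)
            _, rss_noB = solve_noB(Y)
            grand = coef_add[:, 0]
            eff_a = coef_add[:, 1:ka]
            eff_a = np.concatenate([eff_a, -eff_a.sum(axis=1, keepdims=True)], axis=1)
            eff_b = coef_add[:, ka : ka + kb - 1]
            eff_b = np.concatenate([eff_b, -eff_b.sum(axis=1, keepdims=True)], axis=1)
            mst_a = np.maximum(rss_noA - rss_add, 0.0) / (ka - 1)
            mst_b = np.maximum(rss_noB - rss_add, 0.0) / (kb - 1)
            cols = [grand[:, None], eff_a, eff_b, mst_a[:, None], mst_b[:, None]]
            if self.include_interaction:
                mst_ab = np.maximum(rss_add - rss_full, 0.0) / ((ka - 1) * (kb - 1))
                cols.append(mst_ab[:, None])
            mse = rss_full / np.maximum(n - p_full, 1)
            cols.append(mse[:, None])
            values = np.concatenate(cols, axis=1)
            ok = ok0 & ok_add & ok_full
            note = "" if ok.all() else "empty factor cell or deficient design"
            return values, ok, note

        return compute_twoway


# ---------------------------------------------------------------------------
# effect sizes (random-effects meta-analysis studies)
# ---------------------------------------------------------------------------


@dataclass
class EffectSizeReplicator(Replicator):
    """A study that reports a mean effect and its within-study variance.

    From raw simulated data ``y`` it computes ``effect = mean(y)`` and
    ``within_var = var(y, ddof=1)/n`` (the variance of the mean).
    """

    include_within: bool = True

    kind = "effect_size"
    subset: tuple[str, ...] = ()

    @property
    def labels(self) -> tuple[str, ...]:
        return ("effect", "within_var") if self.include_within else ("effect",)

    def bind(self, X_stack: np.ndarray):
        S, n, _ = X_stack.shape
        if n < 2 and self.include_within:
            raise GMAError("within-study variance needs at least 2 observations")

        def compute(Y: np.ndarray):
            effect = Y.mean(axis=1)
            if self.include_within:
                within = Y.var(axis=1, ddof=1) / n
                values = np.stack([effect, within], axis=1)
            else:
                values = effect[:, None]
            return values, np.ones(S, dtype=bool), ""

        return compute


_REPLICATORS = {
    "ols": OLSReplicator,
    "logistic": LogisticReplicator,
    "anova": AnovaReplicator,
    "effect_size": EffectSizeReplicator,
}


def build_replicator(kind: str, subset: Sequence[str] = (), options: dict | None = None) -> Replicator:
    """Instantiate a replicator from its registry name and per-study options."""
    options = dict(options or {})
    if kind not in _REPLICATORS:
        raise GMAError(f"unknown replicator kind {kind!r}; known: {sorted(_REPLICATORS)}")
    if kind == "anova":
        factors = options.pop("factors", None)
        if factors is None:
            raise GMAError("anova replicator requires a 'factors' option")
        return AnovaReplicator(factors=tuple((c, tuple(cp)) for c, cp in factors), **options)
    if kind == "effect_size":
        return EffectSizeReplicator(**options)
    return _REPLICATORS[kind](subset=tuple(subset), **options)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def ols_signatures(X, y, subset: Sequence[str], include: Sequence[str] = ("coefs", "mse")) -> ReplicatorResult:
    """OLS signature function (coefficients, optionally MSE and R^2)."""
    rep = OLSReplicator(
        subset=tuple(subset),
        include_mse="mse" in include,
        include_r2="r2" in include,
    )
    return rep.run(X, y)


def logistic_signatures(X, y, subset: Sequence[str]) -> ReplicatorResult:
    """Logistic-regression signature function (ML coefficients with intercept)."""
    return LogisticReplicator(subset=tuple(subset)).run(X, y)


def anova_signatures(X, y, factors, include_interaction: bool = False) -> ReplicatorResult:
    """ANOVA signature function on percentile-discretized factors."""
    rep = AnovaReplicator(
        factors=tuple((c, tuple(cp)) for c, cp in factors),
        include_interaction=include_interaction,
    )
    return rep.run(X, y)


def effect_size_signatures(effects, within_vars) -> list[SignatureVector]:
    """Package published effect sizes and within-study variances, one vector per study."""
    effects = np.asarray(effects, dtype=float).ravel()
    within = np.asarray(within_vars, dtype=float).ravel()
    if effects.size == 0:
        raise GMAError("no effect sizes supplied")
    if effects.shape != within.shape:
        raise GMAError("effects and within-study variances differ in length")
    if np.any(within <= 0):
        raise GMAError("within-study variances must be positive")
    return [
        SignatureVector(("effect", "within_var"), np.array([e, v]))
        for e, v in zip(effects, within)
    ]


def between_study_statistics(per_study: Sequence[SignatureVector], spec: BetweenStudySpec) -> SignatureVector:
    """Compute the between-study signature block from per-study signature vectors.

    Sample variances across studies use denominator ``L - 1``.
    """
    values = []
    for stat in spec.stats:
        col = []
        for sv in per_study:
            try:
                col.append(sv[stat.label])
            except KeyError:
                raise GMAError(
                    f"between-study statistic {stat.name!r} references label "
                    f"{stat.label!r} missing from a study"
                ) from None
        col = np.asarray(col, dtype=float)
        if stat.kind == "variance":
            if col.size < 2:
                raise GMAError(
                    f"between-study variance {stat.name!r} undefined for "
                    f"{col.size} study(ies)"
                )
            values.append(col.var(ddof=1))
        else:
            values.append(col.mean())
    return SignatureVector(tuple(s.name for s in spec.stats), np.array(values))
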