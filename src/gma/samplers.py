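"""Explanatory-variable samplers.

Prior studies rarely ship their raw covariates, so simulated replications
need samples of explanatory variables consistent with what each study
reported.  Three strategies are supported, mirroring common reporting
practice:

* ``TableSource`` — an empirical covariate table (rows resampled with
  replacement when more rows are needed than supplied);
* ``MomentSource`` — multivariate-normal draws from a reported mean vector
  and covariance matrix;
* ``CalibratedSource`` — an empirical base table affinely transformed per
  column so its means and variances exactly match the study's reported ones
  (closed form; rank correlations of the base table are preserved).

Optional measurement noise is layered on top: a noisy predictor gets an
additive normal error whose standard deviation is a fraction ``delta`` of the
predictor's own standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import GMAError

__all__ = [
    "NotPSDError",
    "CovariateSource",
    "TableSource",
    "MomentSource",
    "CalibratedSource",
    "NoiseSpec",
    "sample_from_moments",
    "calibrate_sampler",
    "apply_affine",
    "add_measurement_noise",
]


class NotPSDError(GMAError):
    """A reported covariance matrix is not positive semi-definite."""


def _ensure_psd(cov: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Validate symmetry/PSD-ness; project tiny numerical indefiniteness away.

    Eigenvalues more negative than ``-tol`` (relative to the largest) raise
    :class:`NotPSDError` reporting the most negative eigenvalue; mildly
    negative ones are clipped to zero (nearest-PSD projection).
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise GMAError(f"covariance must be square, got shape {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-8, rtol=1e-8):
        raise GMAError("covariance matrix is not symmetric")
    cov = 0.5 * (cov + cov.T)
    w, V = np.linalg.eigh(cov)
    scale = max(1.0, float(np.max(np.abs(w))) if w.size else 1.0)
    if w.size and w.min() < -tol * scale:
        raise NotPSDError(
            f"covariance is not positive semi-definite; most negative "
            f"eigenvalue {w.min():.6g}"
        )
    w = np.clip(w, 0.0, None)
    return (V * w) @ V.T


class CovariateSource:
    """Abstract source of explanatory-variable samples."""

    names: tuple[str, ...]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass
class TableSource(CovariateSource):
    """Use an empirical covariate table directly (rows verbatim, tiled as needed).

    When a prior study's raw explanatory variables are available they are used
    as-is rather than resampled, so repeated draws are deterministic and the
    design is held fixed across simulation replicates.
    """

    table: pd.DataFrame

    def __post_init__(self):
        self.table = pd.DataFrame(self.table)
        self.names = tuple(self.table.columns)
        self._arr = self.table.to_numpy(dtype=float)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        reps = -(-n // self._arr.shape[0])
        return np.tile(self._arr, (reps, 1))[:n]


@dataclass
class MomentSource(CovariateSource):
    """Multivariate-normal sampler from a reported mean vector and covariance."""

    mean: np.ndarray
    cov: np.ndarray
    names: tuple[str, ...] = ()

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float).ravel()
        k = self.mean.shape[0]
        self.cov = _ensure_psd(self.cov)
        if self.cov.shape != (k, k):
            raise GMAError(
                f"mean has {k} entries but covariance shape is {self.cov.shape}"
            )
        if not self.names:
            self.names = tuple(f"x{i + 1}" for i in range(k))
        # Cholesky-like factor of the (possibly projected) PSD covariance.
        w, V = np.linalg.eigh(self.cov)
        self._factor = V * np.sqrt(np.clip(w, 0.0, None))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((n, self.mean.shape[0]))
        return self.mean + z @ self._factor.T


@dataclass
class CalibratedSource(CovariateSource):
    """Empirical base table put through a per-column affine transform.

    Rows are used verbatim (tiled as needed) like :class:`TableSource`, after
    the shift/scale calibration fitted by :func:`calibrate_sampler`.
    """

    base: pd.DataFrame
    shift: np.ndarray
    scale: np.ndarray

    def __post_init__(self):
        self.base = pd.DataFrame(self.base)
        self.names = tuple(self.base.columns)
        self.shift = np.asarray(self.shift, float).ravel()
        self.scale = np.asarray(self.scale, float).ravel()
        if np.any(self.scale <= 0):
            raise GMAError("calibrated transforms require strictly positive scales")
        self._arr = self.base.to_numpy(dtype=float)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        reps = -(-n // self._arr.shape[0])
        return np.tile(self._arr, (reps, 1))[:n] * self.scale + self.shift


def sample_from_moments(mean, cov, n: int, seed, names: Sequence[str] | None = None) -> pd.DataFrame:
    """Draw ``n`` multivariate-normal covariate rows from reported moments."""
    if n < 1:
        raise GMAError("sample size must be at least 1")
    src = MomentSource(mean, cov, tuple(names) if names else ())
    rng = np.random.default_rng(seed)
    return pd.DataFrame(src.sample(int(n), rng), columns=list(src.names))


def calibrate_sampler(base_table: pd.DataFrame, target_mean, target_var):
    """Closed-form per-column affine calibration of an empirical table.

    ``scale = sqrt(target_var / base_var)``, ``shift = target_mean -
    scale * base_mean``; the transformed table reproduces the target means and
    variances exactly (the reported signatures it is meant to match) while
    preserving the base table's rank correlations.
    """
    base_table = pd.DataFrame(base_table)
    arr = base_table.to_numpy(dtype=float)
    target_mean = np.asarray(target_mean, float).ravel()
    target_var = np.asarray(target_var, float).ravel()
    if arr.shape[1] != target_mean.shape[0] or arr.shape[1] != target_var.shape[0]:
        raise GMAError("target moments do not match the number of base columns")
    if np.any(target_var < 0):
        raise GMAError("target variances must be nonnegative")
    base_mean = arr.mean(axis=0)
    base_var = arr.var(axis=0, ddof=1)
    zero = base_var <= 0
    if np.any(zero & (target_var > 0)):
        bad = [base_table.columns[i] for i in np.flatnonzero(zero & (target_var > 0))]
        raise GMAError(
            f"base column(s) {bad} have zero variance; cannot calibrate to a "
            f"nonzero target variance"
        )
    scale = np.where(zero, 1.0, np.sqrt(np.where(zero, 1.0, target_var / np.where(zero, 1.0, base_var))))
    shift = target_mean - scale * base_mean
    return shift, scale


def apply_affine(table: pd.DataFrame, shift, scale) -> pd.DataFrame:
    """Apply a per-column affine transform returned by :func:`calibrate_sampler`."""
    table = pd.DataFrame(table)
    arr = table.to_numpy(dtype=float) * np.asarray(scale, float) + np.asarray(shift, float)
    return pd.DataFrame(arr, columns=table.columns, index=table.index)


@dataclass
class NoiseSpec:
    """Measurement-noise specification: per-column delta in [0, 1] plus a seed.

    ``delta`` is the noise standard deviation expressed as a fraction of the
    column's actual standard deviation.
    """

    delta: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for col, d in self.delta.items():
            if d < 0:
                raise GMAError(f"noise delta for column {col!r} is negative")


def add_measurement_noise(X: pd.DataFrame, spec: NoiseSpec) -> pd.DataFrame:
    """Add normal measurement noise to selected columns; others stay bit-identical."""
    X = pd.DataFrame(X)
    unknown = [c for c in spec.delta if c not in X.columns]
    if unknown:
        raise GMAError(f"noise specified for unknown column(s) {unknown}")
    out = X.copy()
    rng = np.random.default_rng(spec.seed)
    for col, d in spec.delta.items():
        if d == 0:
            continue
        sd = float(out[col].std(ddof=1))
        out[col] = out[col].to_numpy(dtype=float) + rng.normal(0.0, d * sd, size=len(out))
    return out
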