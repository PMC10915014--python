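"""Yeo-Johnson power transformation with per-column maximum-likelihood lambda.

The transform pushes each feature column toward Gaussianity while handling
negative values (unlike Box-Cox):

    y >= 0, lam != 0:  ((y + 1)^lam - 1) / lam
    y >= 0, lam == 0:  log(y + 1)
    y <  0, lam != 2:  -((-y + 1)^(2 - lam) - 1) / (2 - lam)
    y <  0, lam == 2:  -log(-y + 1)

lambda is chosen per column by maximizing the Gaussian profile
log-likelihood of the transformed values including the Jacobian term
``(lam - 1) * sum sign(y) log(|y| + 1)``, searched on [-5, 5].  Transformed
columns are z-standardized with the fitted mean/sd so mixed-unit features
can feed a neural network; the fitted parameters are serializable and are
applied unchanged to held-out folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize

from .errors import DegenerateInputError, ValidationError
from .io_formats import FeatureMatrix

LAMBDA_BOUNDS = (-5.0, 5.0)
LAMBDA_XATOL = 1e-5


def yj_transform(y, lam: float):
    """Piecewise Yeo-Johnson transform; continuous and strictly increasing."""
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    pos = y >= 0
    if abs(lam) > 1e-12:
        out[pos] = ((y[pos] + 1.0) ** lam - 1.0) / lam
    else:
        out[pos] = np.log1p(y[pos])
    neg = ~pos
    if abs(lam - 2.0) > 1e-12:
        out[neg] = -(((-y[neg] + 1.0) ** (2.0 - lam)) - 1.0) / (2.0 - lam)
    else:
        out[neg] = -np.log1p(-y[neg])
    return float(out) if out.ndim == 0 else out


def yj_inverse(z, lam: float):
    """Inverse of :func:`yj_transform` (useful for simulating known lambda)."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    if abs(lam) > 1e-12:
        out[pos] = (z[pos] * lam + 1.0) ** (1.0 / lam) - 1.0
    else:
        out[pos] = np.expm1(z[pos])
    neg = ~pos
    if abs(lam - 2.0) > 1e-12:
        out[neg] = 1.0 - (1.0 - (2.0 - lam) * z[neg]) ** (1.0 / (2.0 - lam))
    else:
        out[neg] = -np.expm1(-z[neg])
    return float(out) if out.ndim == 0 else out


def yj_log_likelihood(column, lam: float) -> float:
    """Gaussian profile log-likelihood of the transformed column at ``lam``."""
    y = np.asarray(column, dtype=float)
    n = len(y)
    z = yj_transform(y, lam)
    var = z.var()
    if var <= 0:
        return -np.inf
    jacobian = (lam - 1.0) * np.sum(np.sign(y) * np.log1p(np.abs(y)))
    return float(-0.5 * n * np.log(var) + jacobian)


def fit_lambda(column) -> tuple[float, float]:
    """Maximum-likelihood lambda for one column and the attained value.

    Bounded scalar search on [-5, 5] with absolute tolerance 1e-5; a
    constant column raises."""
    y = np.asarray(column, dtype=float)
    if len(y) < 10:
        raise ValidationError("need at least 10 values to fit lambda")
    if np.ptp(y) == 0:
        raise DegenerateInputError("constant column: lambda undefined")
    res = scipy.optimize.minimize_scalar(
        lambda lam: -yj_log_likelihood(y, lam),
        bounds=LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": LAMBDA_XATOL},
    )
    return float(res.x), float(-res.fun)


@dataclass
class TransformParams:
    """Per-column fitted lambda, attained log-likelihood and z-scaling."""

    lambdas: dict[str, float]
    loglik: dict[str, float]
    fit_mean: dict[str, float]
    fit_sd: dict[str, float]
    passthrough: list[str] = field(default_factory=list)  # constant columns

    def to_dict(self) -> dict:
        return {
            "lambdas": self.lambdas,
            "loglik": self.loglik,
            "fit_mean": self.fit_mean,
            "fit_sd": self.fit_sd,
            "passthrough": self.passthrough,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransformParams":
        return cls(
            lambdas=dict(d["lambdas"]),
            loglik=dict(d["loglik"]),
            fit_mean=dict(d["fit_mean"]),
            fit_sd=dict(d["fit_sd"]),
            passthrough=list(d.get("passthrough", [])),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "TransformParams":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def fit_transform_matrix(fm: FeatureMatrix) -> tuple[FeatureMatrix, TransformParams]:
    """Fit lambda per column, transform and z-standardize.

    Constant columns are passed through untransformed and flagged in
    ``params.passthrough``.  The returned params reproduce the transform
    bit-identically in apply-only mode (fold hygiene: fit on training rows
    only, then :func:`apply_transform` on held-out rows).
    """
    params = TransformParams({}, {}, {}, {}, [])
    out = {}
    for col in fm.columns:
        y = fm.values[col].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            params.passthrough.append(col)
            out[col] = y
            continue
        lam, ll = fit_lambda(y)
        z = yj_transform(y, lam)
        mu, sd = float(z.mean()), float(z.std())
        sd = sd if sd > 0 else 1.0
        params.lambdas[col] = lam
        params.loglik[col] = ll
        params.fit_mean[col] = mu
        params.fit_sd[col] = sd
        out[col] = (z - mu) / sd
    transformed = FeatureMatrix(
        values=pd.DataFrame(out, columns=fm.columns),
        labels=fm.labels.copy(),
        branch=fm.branch,
    )
    return transformed, params


def apply_transform(fm: FeatureMatrix, params: TransformParams) -> FeatureMatrix:
    """Apply previously fitted parameters to new rows (no refitting)."""
    out = {}
    for col in fm.columns:
        y = fm.values[col].to_numpy(dtype=float)
        if col in params.passthrough:
            out[col] = y
            continue
        if col not in params.lambdas:
            raise ValidationError(f"no fitted lambda for column {col!r}")
        z = yj_transform(y, params.lambdas[col])
        out[col] = (z - params.fit_mean[col]) / params.fit_sd[col]
    return FeatureMatrix(
        values=pd.DataFrame(out, columns=fm.columns),
        labels=fm.labels.copy(),
        branch=fm.branch,
    )
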