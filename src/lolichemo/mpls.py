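"""Modified partial least squares (MPLS) regression.

MPLS is PLS1 with one change: after each factor is extracted, the X
residual at every wavelength (and, optionally, the y residual) is divided
by its standard deviation before the next factor is computed.  The
per-factor divisors are remembered so prediction can replay them in
training order.  With residual scaling switched off the algorithm is
exactly classical NIPALS PLS1, which is the cross-check used in the test
suite.  The rescaling damps wavelengths whose residual variance is
already small, which in practice stabilises high-factor models on noisy
reflectance data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DomainError, RankError

__all__ = ["MPLSModel", "fit_mpls", "predict", "save_model", "load_model"]

_SCHEMA = "lolichemo-mpls/1"


@dataclass
class MPLSFactor:
    weight: np.ndarray        # (p,) unit-norm weight vector
    x_loading: np.ndarray     # (p,) loading from score regression on X
    y_loading: float          # scalar regression of y on the score
    x_scaling: np.ndarray | None  # (p,) residual SD divisors applied *after* this factor
    y_scaling: float          # y-residual divisor applied after this factor (1.0 if off)


@dataclass
class MPLSModel:
    x_center: np.ndarray
    y_center: float
    factors: list[MPLSFactor]
    scale_residuals: bool
    scale_y_residual: bool

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def coefficients(self) -> tuple[np.ndarray, float]:
        """Equivalent affine form: yhat = intercept + x @ beta.

        The prediction replay is affine in x whatever the scaling, so the
        coefficient vector is obtained by pushing the identity basis
        through it.
        """
        p = self.x_center.size
        basis = np.eye(p) + self.x_center
        beta = predict(self, basis) - self.y_center
        intercept = self.y_center - float(self.x_center @ beta)
        return beta, intercept


def save_model(model: MPLSModel, path: str | Path, treatment: str | None = None) -> None:
    """Serialise a model as self-describing JSON (versioned schema)."""
    doc = {
        "schema": _SCHEMA,
        "treatment": treatment,
        "x_center": model.x_center.tolist(),
        "y_center": model.y_center,
        "scale_residuals": model.scale_residuals,
        "scale_y_residual": model.scale_y_residual,
        "factors": [
            {
                "weight": f.weight.tolist(),
                "x_loading": f.x_loading.tolist(),
                "y_loading": f.y_loading,
                "x_scaling": None if f.x_scaling is None else f.x_scaling.tolist(),
                "y_scaling": f.y_scaling,
            }
            for f in model.factors
        ],
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def load_model(path: str | Path) -> tuple[MPLSModel, str | None]:
    """Load a model written by :func:`save_model`; returns (model, treatment code)."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("schema") != _SCHEMA:
        raise DomainError(f"unknown model schema {doc.get('schema')!r}")
    factors = [
        MPLSFactor(
            weight=np.asarray(f["weight"], dtype=float),
            x_loading=np.asarray(f["x_loading"], dtype=float),
            y_loading=float(f["y_loading"]),
            x_scaling=None if f["x_scaling"] is None else np.asarray(f["x_scaling"], dtype=float),
            y_scaling=float(f["y_scaling"]),
        )
        for f in doc["factors"]
    ]
    model = MPLSModel(
        x_center=np.asarray(doc["x_center"], dtype=float),
        y_center=float(doc["y_center"]),
        factors=factors,
        scale_residuals=bool(doc["scale_residuals"]),
        scale_y_residual=bool(doc["scale_y_residual"]),
    )
    return model, doc.get("treatment")


def _column_sd(x: np.ndarray) -> np.ndarray:
    return x.std(axis=0, ddof=1)


def fit_mpls(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int = 10,
    scale_residuals: bool = True,
    scale_y_residual: bool = True,
) -> MPLSModel:
    """Fit an MPLS (or, with ``scale_residuals=False``, a PLS1) model.

    Parameters
    ----------
    X
        ``(n, p)`` treated spectra.
    y
        ``(n,)`` reference concentrations.
    n_factors
        Latent factors to extract; must not exceed ``min(n-1, p)``.
    scale_residuals
        Divide every X-residual column by its SD after each factor
        (the "modified" in MPLS); divisors are stored for prediction.
    scale_y_residual
        Also standardise the y residual between factors.  Ignored when
        ``scale_residuals`` is off.

    Notes
    -----
    A residual column whose SD underflows to zero is left unscaled for
    that factor (unit divisor) and a warning is emitted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise DomainError("X rows and y length differ")
    if n_factors < 1 or n_factors > min(n - 1, p):
        raise RankError(f"n_factors={n_factors} outside [1, min(n-1, p)={min(n-1, p)}]")
    if np.std(y) == 0:
        raise DomainError("reference values have zero variance")

    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    E = X - x_center
    f = y - y_center
    factors: list[MPLSFactor] = []

    for _ in range(n_factors):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm == 0:
            break  # y residual orthogonal to X residual: nothing left to model
        w /= norm
        t = E @ w
        tt = float(t @ t)
        if tt == 0:
            break
        pvec = E.T @ t / tt
        q = float(f @ t) / tt
        E = E - np.outer(t, pvec)
        f = f - q * t

        x_scaling = None
        y_scaling = 1.0
        if scale_residuals:
            sd = _column_sd(E)
            bad = sd <= 0
            if bad.any():
                warnings.warn(
                    f"{int(bad.sum())} residual column(s) with zero SD left unscaled",
                    stacklevel=2,
                )
                sd = sd.copy()
                sd[bad] = 1.0
            E = E / sd
            x_scaling = sd
            if scale_y_residual:
                fsd = float(np.std(f, ddof=1))
                if fsd > 0:
                    f = f / fsd
                    y_scaling = fsd
        factors.append(MPLSFactor(w, pvec, q, x_scaling, y_scaling))

    return MPLSModel(
        x_center=x_center,
        y_center=y_center,
        factors=factors,
        scale_residuals=scale_residuals,
        scale_y_residual=scale_y_residual,
    )


def predict(model: MPLSModel, X: np.ndarray) -> np.ndarray:
    """Predict reference concentrations for treated spectra.

    Replays the training pipeline row-wise: centre, then for each factor
    score-project, deflate, and apply the stored residual scalings in
    training order.  Output is in the reference units the model was fit
    in (mg·kg⁻¹ or mg·g⁻¹).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_center.size:
        raise DomainError(
            f"spectrum length {X.shape[1]} does not match model grid {model.x_center.size}"
        )
    E = X - model.x_center
    yhat = np.full(X.shape[0], model.y_center)
    y_scale = 1.0
    for fac in model.factors:
        t = E @ fac.weight
        yhat = yhat + y_scale * fac.y_loading * t
        E = E - np.outer(t, fac.x_loading)
        if fac.x_scaling is not None:
            E = E / fac.x_scaling
        y_scale *= fac.y_scaling
    return yhat
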