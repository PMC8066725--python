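"""Second-order response-surface models on coded factors.

Each response y is modelled by the full ten-term quadratic

    y = b0 + b1*x1 + b2*x2 + b3*x3
        + b11*x1^2 + b22*x2^2 + b33*x3^2
        + b12*x1*x2 + b13*x1*x3 + b23*x2*x3 + error

fitted by ordinary least squares on the coded (-1/0/+1) design columns.
Effects are screened by single-degree-of-freedom F tests of the partial
sum of squares against the residual mean square.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .doe import DesignTable, FactorSpec
from .errors import SingularDesignError, ValidationError

__all__ = [
    "COEF_NAMES",
    "EFFECT_NAMES",
    "QuadraticModel",
    "AnovaTable",
    "model_matrix",
    "fit_quadratic",
    "predict",
    "r_squared",
    "anova_effects",
    "surface_slice",
]

COEF_NAMES = ("b0", "b1", "b2", "b3", "b11", "b22", "b33", "b12", "b13", "b23")
#: labels for the nine non-intercept effects, aligned with COEF_NAMES[1:]
EFFECT_NAMES = ("x1", "x2", "x3", "x1^2", "x2^2", "x3^2", "x1*x2", "x1*x3", "x2*x3")


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the coded cube [-1, +1]^3."""


def model_matrix(coded) -> np.ndarray:
    """Ten-column quadratic model matrix for coded points of shape (n, 3)."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    if coded.shape[1] != 3:
        raise ValidationError("coded points must have 3 columns")
    x1, x2, x3 = coded.T
    return np.column_stack(
        [np.ones(len(coded)), x1, x2, x3, x1**2, x2**2, x3**2, x1 * x2, x1 * x3, x2 * x3]
    )


@dataclass(frozen=True)
class QuadraticModel:
    """A fitted (or constructed) full quadratic surface.

    ``coefficients`` holds the ten terms in :data:`COEF_NAMES` order.
    ``residual_df``/``residual_ms`` summarize the fit error; ``r_squared``
    is the unadjusted coefficient of determination.
    """

    response_name: str
    coefficients: np.ndarray
    factors: tuple[FactorSpec, ...] | None = None
    residual_df: int = 0
    residual_ms: float = float("nan")
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        if coef.shape != (10,):
            raise ValidationError("coefficients must be a length-10 vector")
        object.__setattr__(self, "coefficients", coef)

    @property
    def beta0(self) -> float:
        return float(self.coefficients[0])

    @property
    def linear(self) -> np.ndarray:
        return self.coefficients[1:4]

    @property
    def quadratic(self) -> np.ndarray:
        return self.coefficients[4:7]

    @property
    def interactions(self) -> np.ndarray:
        return self.coefficients[7:10]

    def predict(self, points) -> np.ndarray | float:
        """Evaluate the polynomial at coded point(s); warns beyond the cube."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if np.any(np.abs(pts) > 1 + 1e-12):
            warnings.warn(
                f"predicting {self.response_name!r} outside the coded cube",
                ExtrapolationWarning,
                stacklevel=2,
            )
        out = model_matrix(pts) @ self.coefficients
        return float(out[0]) if np.ndim(points) == 1 else out

    def named_coefficients(self) -> dict[str, float]:
        return {n: float(c) for n, c in zip(COEF_NAMES, self.coefficients)}

    def to_json(self) -> str:
        payload = {
            "response": self.response_name,
            "coefficients": self.named_coefficients(),
            "r2": None if np.isnan(self.r_squared) else float(self.r_squared),
            "residual_df": int(self.residual_df),
            "residual_ms": None if np.isnan(self.residual_ms) else float(self.residual_ms),
            "factors": None
            if self.factors is None
            else [
                {"name": f.name, "low": f.low, "high": f.high, "center": f.center, "units": f.units}
                for f in self.factors
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "QuadraticModel":
        payload = json.loads(text)
        coef = np.array([payload["coefficients"][n] for n in COEF_NAMES])
        factors = None
        if payload.get("factors"):
            factors = tuple(
                FactorSpec(
                    name=f["name"], low=f["low"], high=f["high"],
                    center=f.get("center"), units=f.get("units", ""),
                )
                for f in payload["factors"]
            )
        return cls(
            response_name=payload["response"],
            coefficients=coef,
            factors=factors,
            residual_df=payload.get("residual_df", 0),
            residual_ms=payload.get("residual_ms") or float("nan"),
            r_squared=float("nan") if payload.get("r2") is None else payload["r2"],
        )


def _degenerate_sst(sst: float, y: np.ndarray) -> bool:
    # constant responses accumulate O(eps) rounding in the mean; treat
    # variance at the noise floor of the data's magnitude as zero
    floor = (len(y) * (np.finfo(float).eps * max(1.0, float(np.abs(y).max()))) ** 2) * 16
    return sst <= floor


def fit_quadratic(design: DesignTable, y, response_name: str = "") -> QuadraticModel:
    """Ordinary-least-squares fit of the full quadratic on coded factors.

    Requires at least 11 runs (10 coefficients + 1 residual degree of
    freedom is not required, but identifiability is).  For a response with
    zero variance, R^2 is reported as 0 by convention.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (design.n_runs,):
        raise ValidationError(
            f"response length {y.shape} does not match design with {design.n_runs} runs"
        )
    if design.n_runs < 11:
        raise ValidationError("need at least 11 runs to fit the 10-term quadratic")
    M = model_matrix(design.runs)
    if np.linalg.matrix_rank(M) < 10:
        raise SingularDesignError("model matrix is rank deficient for this design")
    coef, *_ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ coef
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    if _degenerate_sst(sst, y):
        warnings.warn("degenerate (constant) response; R^2 reported as 0", stacklevel=2)
        r2 = 0.0
    else:
        r2 = 1.0 - sse / sst
    df = design.n_runs - 10
    return QuadraticModel(
        response_name=response_name,
        coefficients=coef,
        factors=design.factors,
        residual_df=df,
        residual_ms=sse / df if df > 0 else float("nan"),
        r_squared=r2,
    )


def predict(model: QuadraticModel, point) -> np.ndarray | float:
    """Evaluate ``model`` at coded ``point`` (triple or (n, 3) array)."""
    return model.predict(point)


def r_squared(model: QuadraticModel, design: DesignTable, y) -> float:
    """Recompute R^2 = 1 - SSE/SST of ``model`` on (design, y).

    Returns 0 (with a warning) for a zero-variance response.
    """
    y = np.asarray(y, dtype=float)
    resid = y - model_matrix(design.runs) @ model.coefficients
    sst = float(np.sum((y - y.mean()) ** 2))
    if _degenerate_sst(sst, y):
        warnings.warn("degenerate (constant) response; R^2 reported as 0", stacklevel=2)
        return 0.0
    return 1.0 - float(resid @ resid) / sst


@dataclass(frozen=True)
class AnovaTable:
    """Single-degree-of-freedom effect tests for the nine model terms.

    ``effects`` has one row per effect (index :data:`EFFECT_NAMES`) with
    columns ``ss`` (partial sum of squares), ``df``, ``f``, ``p`` and
    ``sign`` (sign of the fitted coefficient).
    """

    effects: pd.DataFrame
    residual_ss: float
    residual_df: int

    def significant(self, alpha: float = 0.05) -> list[str]:
        return list(self.effects.index[self.effects["p"] < alpha])

    def to_csv(self, path) -> None:
        out = self.effects.reset_index().rename(columns={"index": "effect"})
        out.to_csv(path, index=False)


def anova_effects(model: QuadraticModel, design: DesignTable, y) -> AnovaTable:
    """Partial-SS F tests of each effect against the residual mean square.

    The partial sum of squares for coefficient j is b_j^2 / [(X'X)^-1]_jj,
    which for the mutually orthogonal linear and interaction columns of the
    BBD reduces to b_j^2 * sum(column^2).  Each F statistic equals the
    square of the coefficient's t statistic.
    """
    y = np.asarray(y, dtype=float)
    if model.residual_df < 1:
        raise ValidationError("no residual degrees of freedom for ANOVA")
    M = model_matrix(design.runs)
    resid = y - M @ model.coefficients
    sse = float(resid @ resid)
    ms_resid = sse / model.residual_df
    xtx_inv = np.linalg.inv(M.T @ M)
    rows = []
    for j in range(1, 10):
        ss = float(model.coefficients[j] ** 2 / xtx_inv[j, j])
        f = ss / ms_resid
        p = float(stats.f.sf(f, 1, model.residual_df))
        rows.append(
            {"ss": ss, "df": 1, "f": f, "p": p, "sign": int(np.sign(model.coefficients[j]))}
        )
    effects = pd.DataFrame(rows, index=list(EFFECT_NAMES))
    return AnovaTable(effects=effects, residual_ss=sse, residual_df=model.residual_df)


def surface_slice(
    model: QuadraticModel,
    factor_pair: tuple[str, str] | tuple[int, int],
    fixed_levels: dict[str, float] | float = 0.0,
    grid_n: int = 21,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate the surface on a coded [-1, 1]^2 lattice over two factors.

    Returns ``(gx, gy, z)`` where ``z[i, j]`` is the prediction at
    ``(gx[i], gy[j])`` with the remaining factor held at its fixed level.
    """
    if grid_n < 2:
        raise ValidationError("grid_n must be >= 2")
    names = (
        [f.name for f in model.factors]
        if model.factors is not None
        else ["x1", "x2", "x3"]
    )

    def _index(key) -> int:
        if isinstance(key, int):
            if not 0 <= key < 3:
                raise ValidationError(f"factor index {key} out of range")
            return key
        try:
            return names.index(key)
        except ValueError:
            raise ValidationError(f"unknown factor name {key!r}") from None

    ia, ib = (_index(k) for k in factor_pair)
    if ia == ib:
        raise ValidationError("factor_pair must name two distinct factors")
    other = ({0, 1, 2} - {ia, ib}).pop()
    fixed = (
        fixed_levels.get(names[other], 0.0)
        if isinstance(fixed_levels, dict)
        else float(fixed_levels)
    )
    g = np.linspace(-1.0, 1.0, grid_n)
    pts = np.zeros((grid_n * grid_n, 3))
    gx, gy = np.meshgrid(g, g, indexing="ij")
    pts[:, ia] = gx.ravel()
    pts[:, ib] = gy.ravel()
    pts[:, other] = fixed
    z = (model_matrix(pts) @ model.coefficients).reshape(grid_n, grid_n)
    return g, g, z
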