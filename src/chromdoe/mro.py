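"""Derringer-style desirability functions and multiresponse optimization.

Each response y is mapped to an individual desirability d in [0, 1] by a
one-sided linear ramp (optionally powered by a shape exponent) between two
anchors; the overall desirability is the impact-weighted geometric mean

    D = (prod d_i^{w_i})^{1 / sum w_i}

which for equal impacts reduces to the plain geometric mean.  The operating
point is the argmax of D over the coded factor cube, located on a dense
lattice and refined by a bounded Nelder-Mead polish.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .doe import ResponseSet
from .errors import ValidationError
from .rsm import QuadraticModel, model_matrix

__all__ = [
    "DesirabilityGoal",
    "MROSolution",
    "desirability_value",
    "overall_desirability",
    "goals_from_observed",
    "optimize_desirability",
    "evaluate_grid",
]


@dataclass(frozen=True)
class DesirabilityGoal:
    """Desirability configuration for one response.

    ``direction`` is ``"maximize"`` or ``"minimize"``; the ramp runs from
    ``low_anchor`` (d = 0 when maximizing) to ``high_anchor`` (d = 1 when
    maximizing), mirrored when minimizing.  ``impact`` is the geometric-mean
    weight (conventionally 1-5); ``shape`` powers the linear ramp.
    """

    response_name: str
    direction: str
    low_anchor: float
    high_anchor: float
    impact: float = 1.0
    shape: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("maximize", "minimize"):
            raise ValidationError(f"unknown direction {self.direction!r}")
        if not self.low_anchor < self.high_anchor:
            raise ValidationError("low_anchor must be strictly below high_anchor")
        if self.impact <= 0 or self.shape <= 0:
            raise ValidationError("impact and shape must be positive")


def desirability_value(y, goal: DesirabilityGoal):
    """Individual desirability of response value(s) ``y`` under ``goal``."""
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValidationError("response values must be finite")
    ramp = (y - goal.low_anchor) / (goal.high_anchor - goal.low_anchor)
    d = np.clip(ramp, 0.0, 1.0) ** goal.shape
    if goal.direction == "minimize":
        d = np.clip(1.0 - ramp, 0.0, 1.0) ** goal.shape
    return float(d) if y.ndim == 0 else d


def overall_desirability(d, impacts) -> np.ndarray | float:
    """Impact-weighted geometric mean of individual desirabilities.

    ``d`` may be a vector (one value per response) or an (n, m) array of n
    candidate points; zero desirability in any response annihilates D.
    """
    d = np.asarray(d, dtype=float)
    w = np.asarray(impacts, dtype=float)
    if d.shape[-1] != w.shape[0]:
        raise ValidationError("d and impacts must have equal length")
    if np.any(w <= 0):
        raise ValidationError("impacts must be positive")
    if np.any((d < 0) | (d > 1)):
        raise ValidationError("individual desirabilities must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        logd = np.where(d > 0, np.log(np.where(d > 0, d, 1.0)), -np.inf)
    out = np.exp((logd * w).sum(axis=-1) / w.sum())
    out = np.where(np.isfinite(out), out, 0.0)
    return float(out) if d.ndim == 1 else out


def goals_from_observed(
    responses: ResponseSet,
    directions: dict[str, str],
    impacts: dict[str, float],
    shapes: dict[str, float] | None = None,
) -> list[DesirabilityGoal]:
    """Build goals with anchors at each response's observed min/max.

    This is the common package default when no explicit anchors are given:
    the worst observed value maps to d = 0 and the best to d = 1.
    """
    shapes = shapes or {}
    goals = []
    for name in directions:
        y = responses[name]
        goals.append(
            DesirabilityGoal(
                response_name=name,
                direction=directions[name],
                low_anchor=float(y.min()),
                high_anchor=float(y.max()),
                impact=impacts[name],
                shape=shapes.get(name, 1.0),
            )
        )
    return goals


@dataclass(frozen=True)
class MROSolution:
    """The optimized operating point."""

    coded_point: np.ndarray
    natural_point: np.ndarray
    response_names: tuple[str, ...]
    predicted_responses: np.ndarray
    individual_d: np.ndarray
    overall_D: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "coded_point": [float(v) for v in self.coded_point],
                "natural_point": [float(v) for v in self.natural_point],
                "responses": {
                    n: {"predicted": float(y), "desirability": float(d)}
                    for n, y, d in zip(
                        self.response_names, self.predicted_responses, self.individual_d
                    )
                },
                "overall_D": float(self.overall_D),
            },
            indent=2,
            sort_keys=True,
        )


def _desirability_of_points(points, models, goals, impacts):
    M = model_matrix(points)
    d = np.column_stack(
        [
            desirability_value(M @ m.coefficients, g)
            for m, g in zip(models, goals)
        ]
    )
    return overall_desirability(d, impacts)


def optimize_desirability(
    models: list[QuadraticModel],
    goals: list[DesirabilityGoal],
    grid_n: int = 51,
    polish: bool = True,
) -> MROSolution:
    """Maximize overall desirability of the model predictions over the cube.

    Evaluates D on a ``grid_n``^3 lattice (vectorized), takes the first
    argmax in row-major order, and optionally refines it with a bounded
    Nelder-Mead search clamped to [-1, 1]^3.  Fully deterministic.
    """
    if not goals:
        raise ValidationError("at least one goal is required")
    if len(models) != len(goals):
        raise ValidationError("models and goals must pair up one-to-one")
    by_name = {m.response_name: m for m in models}
    models = [by_name.get(g.response_name, m) for m, g in zip(models, goals)]
    if grid_n < 11:
        raise ValidationError("grid_n must be >= 11")
    impacts = np.array([g.impact for g in goals])
    g1 = np.linspace(-1.0, 1.0, grid_n)
    X1, X2, X3 = np.meshgrid(g1, g1, g1, indexing="ij")
    pts = np.column_stack([X1.ravel(), X2.ravel(), X3.ravel()])
    D = _desirability_of_points(pts, models, goals, impacts)
    best = int(np.argmax(D))
    best_point, best_D = pts[best], float(D[best])
    if best_D == 0.0:
        warnings.warn(
            "desirability is zero over the whole grid; returning first grid argmax",
            stacklevel=2,
        )
    elif polish:
        res = optimize.minimize(
            lambda p: -_desirability_of_points(p[None, :], models, goals, impacts)[0],
            best_point,
            method="Nelder-Mead",
            bounds=[(-1.0, 1.0)] * 3,
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
        )
        cand = np.clip(res.x, -1.0, 1.0)
        cand_D = float(_desirability_of_points(cand[None, :], models, goals, impacts)[0])
        if cand_D >= best_D:
            best_point, best_D = cand, cand_D

    predicted = np.array([float(m.predict(best_point)) for m in models])
    d_ind = np.array([desirability_value(y, g) for y, g in zip(predicted, goals)])
    factors = models[0].factors
    natural = (
        np.array([f.to_natural(v) for f, v in zip(factors, best_point)])
        if factors is not None
        else np.array(best_point, dtype=float)
    )
    return MROSolution(
        coded_point=np.asarray(best_point, dtype=float),
        natural_point=natural,
        response_names=tuple(g.response_name for g in goals),
        predicted_responses=predicted,
        individual_d=d_ind,
        overall_D=best_D,
    )


def evaluate_grid(
    models: list[QuadraticModel], goals: list[DesirabilityGoal], grid_n: int = 21
):
    """Overall desirability on the full lattice, for external 3-D plotting.

    Returns a DataFrame with coded coordinates and D at every node.
    """
    import pandas as pd

    impacts = np.array([g.impact for g in goals])
    g1 = np.linspace(-1.0, 1.0, grid_n)
    X1, X2, X3 = np.meshgrid(g1, g1, g1, indexing="ij")
    pts = np.column_stack([X1.ravel(), X2.ravel(), X3.ravel()])
    D = _desirability_of_points(pts, models, goals, impacts)
    return pd.DataFrame({"x1": pts[:, 0], "x2": pts[:, 1], "x3": pts[:, 2], "D": D})
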