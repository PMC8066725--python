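"""One-command study pipeline: fit all responses, screen effects, optimize.

``StudyConfig`` captures everything tunable about a study — factor ranges,
per-response desirability goals, optimizer settings, validation thresholds
— as a single JSON-serializable object; :func:`default_study_config`
mirrors the packaged flavonol study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .datasets import GOAL_DIRECTIONS, GOAL_IMPACTS
from .doe import DesignTable, ResponseSet
from .errors import FileFormatError, ValidationError
from .mro import DesirabilityGoal, MROSolution, optimize_desirability
from .rsm import COEF_NAMES, AnovaTable, QuadraticModel, anova_effects, fit_quadratic
from .validation import PrecisionReport, precision_report, robustness_report

__all__ = [
    "GoalConfig",
    "StudyConfig",
    "default_study_config",
    "OptimizationReport",
    "run_full_optimization",
    "ValidationReport",
    "replay_validation",
]


class GoalConfig(BaseModel):
    """Desirability settings for one response; anchors default to the
    observed min/max over the design runs when left unset."""

    response: str
    direction: str
    impact: float = Field(gt=0)
    low: float | None = None
    high: float | None = None
    shape: float = Field(default=1.0, gt=0)

    @field_validator("direction")
    @classmethod
    def _check_direction(cls, v: str) -> str:
        if v not in ("maximize", "minimize"):
            raise ValueError(f"unknown direction {v!r}")
        return v


class StudyConfig(BaseModel):
    """Configuration of a full design-fit-optimize study."""

    goals: list[GoalConfig]
    grid_n: int = Field(default=51, ge=11)
    polish: bool = True
    cv_threshold: float = Field(default=10.0, gt=0)
    alpha: float = Field(default=0.05, gt=0, lt=1)

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        try:
            return cls.model_validate(json.loads(Path(path).read_text()))
        except json.JSONDecodeError as exc:
            raise FileFormatError(f"{path}: invalid JSON at line {exc.lineno}") from exc


def default_study_config() -> StudyConfig:
    """Goals of the packaged study: maximize the four resolutions
    (impacts 4/3/3/4), minimize the run time (impact 5)."""
    return StudyConfig(
        goals=[
            GoalConfig(response=name, direction=GOAL_DIRECTIONS[name], impact=GOAL_IMPACTS[name])
            for name in GOAL_DIRECTIONS
        ]
    )


@dataclass(frozen=True)
class OptimizationReport:
    """Fitted models, effect tests and the optimized operating point."""

    models: dict[str, QuadraticModel]
    anova: dict[str, AnovaTable]
    solution: MROSolution

    def to_json(self) -> str:
        payload = {
            "models": {
                name: {
                    "coefficients": m.named_coefficients(),
                    "r2": float(m.r_squared),
                    "residual_df": int(m.residual_df),
                    "residual_ms": float(m.residual_ms),
                }
                for name, m in self.models.items()
            },
            "anova": {
                name: {
                    effect: {
                        "ss": float(row["ss"]),
                        "f": float(row["f"]),
                        "p": float(row["p"]),
                        "sign": int(row["sign"]),
                    }
                    for effect, row in a.effects.iterrows()
                }
                for name, a in self.anova.items()
            },
            "optimum": json.loads(self.solution.to_json()),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, directory) -> None:
        """Write report.json, models.csv, anova.csv and optimum.csv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "report.json").write_text(self.to_json())
        rows = []
        for name, m in self.models.items():
            row = {"response": name, **m.named_coefficients(), "r2": m.r_squared}
            rows.append(row)
        pd.DataFrame(rows, columns=["response", *COEF_NAMES, "r2"]).to_csv(
            directory / "models.csv", index=False
        )
        anova_rows = []
        for name, a in self.anova.items():
            sub = a.effects.reset_index().rename(columns={"index": "effect"})
            sub.insert(0, "response", name)
            anova_rows.append(sub)
        pd.concat(anova_rows).to_csv(directory / "anova.csv", index=False)
        sol = self.solution
        factor_names = (
            [f.name for f in next(iter(self.models.values())).factors]
            if next(iter(self.models.values())).factors
            else ["x1", "x2", "x3"]
        )
        pd.DataFrame(
            {
                "factor": factor_names,
                "coded": sol.coded_point,
                "natural": sol.natural_point,
            }
        ).to_csv(directory / "optimum.csv", index=False)


def run_full_optimization(
    config: StudyConfig, design: DesignTable, responses: ResponseSet
) -> OptimizationReport:
    """Fit every goal's response, run the effect ANOVA, and locate the
    desirability optimum.  Deterministic: identical inputs give an
    identical (byte-for-byte) JSON report."""
    missing = [g.response for g in config.goals if g.response not in responses.names]
    if missing:
        raise ValidationError(f"goals reference unknown responses: {missing}")
    models: dict[str, QuadraticModel] = {}
    anova: dict[str, AnovaTable] = {}
    goals: list[DesirabilityGoal] = []
    for g in config.goals:
        y = responses[g.response]
        model = fit_quadratic(design, y, response_name=g.response)
        models[g.response] = model
        anova[g.response] = anova_effects(model, design, y)
        goals.append(
            DesirabilityGoal(
                response_name=g.response,
                direction=g.direction,
                low_anchor=g.low if g.low is not None else float(y.min()),
                high_anchor=g.high if g.high is not None else float(y.max()),
                impact=g.impact,
                shape=g.shape,
            )
        )
    solution = optimize_desirability(
        list(models.values()), goals, grid_n=config.grid_n, polish=config.polish
    )
    return OptimizationReport(models=models, anova=anova, solution=solution)


@dataclass(frozen=True)
class ValidationReport:
    """Precision CVs plus robustness letter displays."""

    precision: PrecisionReport
    robustness: pd.DataFrame

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.precision.to_csv(directory / "precision.csv")
        self.robustness.to_csv(directory / "robustness.csv", index=False)


def _read_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FileFormatError(f"{path}: file is empty") from exc
    except Exception as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FileFormatError(f"{path}: missing columns {missing}")
    if frame.empty:
        raise FileFormatError(f"{path}: no data rows")
    return frame


def replay_validation(
    same_day_path,
    multi_day_path,
    robustness_path,
    cv_threshold: float = 10.0,
    alpha: float = 0.05,
) -> ValidationReport:
    """Recompute the validation tables from replicate and robustness CSVs.

    Replicate CSVs need columns compound, metric, value (day optional);
    the robustness CSV needs quantity, compound, parameter, level, value.
    """
    same_day = _read_csv(same_day_path, ("compound", "metric", "value"))
    multi_day = _read_csv(multi_day_path, ("compound", "metric", "value"))
    robust = _read_csv(
        robustness_path, ("quantity", "compound", "parameter", "level", "value")
    )
    return ValidationReport(
        precision=precision_report(same_day, multi_day, threshold=cv_threshold),
        robustness=robustness_report(robust, alpha=alpha),
    )
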