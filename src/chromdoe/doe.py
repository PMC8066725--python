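"""Three-factor Box-Behnken designs and factor coding.

A Box-Behnken design (BBD) for three continuous factors places runs at the
twelve edge midpoints of the factor cube (one factor at its center, the
other two at their low/high levels) plus replicated center points.  Factors
are handled in *coded* units, where the low/center/high levels map to
-1/0/+1; coded levels are stored as exact integers so design algebra
(column sums, orthogonality) is exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateFactorError,
    FileFormatError,
    UnsupportedDesignError,
    ValidationError,
)

__all__ = [
    "FactorSpec",
    "DesignTable",
    "ResponseSet",
    "generate_bbd",
    "to_coded",
    "to_natural",
    "read_design_responses",
    "write_design_responses",
]


@dataclass(frozen=True)
class FactorSpec:
    """A continuous factor with natural-unit bounds.

    Parameters
    ----------
    name : str
        Identifier used in column headers (``<name>_coded`` etc.).
    low, high : float
        Natural-unit values mapped to coded -1 and +1.
    center : float, optional
        Natural-unit value mapped to coded 0; defaults to the midpoint.
    units : str
        Display units (e.g. ``"mL/min"``).
    """

    name: str
    low: float
    high: float
    center: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.high == self.low:
            raise DegenerateFactorError(
                f"factor {self.name!r} has zero range (low == high == {self.low})"
            )
        if self.center is None:
            object.__setattr__(self, "center", 0.5 * (self.low + self.high))
        if not (self.low < self.center < self.high):
            raise ValidationError(
                f"factor {self.name!r} requires low < center < high, got "
                f"({self.low}, {self.center}, {self.high})"
            )

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def to_coded(self, value):
        """Map natural units onto the coded scale (low/center/high -> -1/0/+1)."""
        return (np.asarray(value, dtype=float) - self.center) / self.half_range

    def to_natural(self, coded):
        """Inverse of :meth:`to_coded`."""
        return self.center + np.asarray(coded, dtype=float) * self.half_range


def to_coded(value, factor: FactorSpec):
    """Functional form of :meth:`FactorSpec.to_coded`."""
    return factor.to_coded(value)


def to_natural(coded, factor: FactorSpec):
    """Functional form of :meth:`FactorSpec.to_natural`."""
    return factor.to_natural(coded)


@dataclass(frozen=True)
class DesignTable:
    """An ordered design: factor specs plus integer coded runs."""

    factors: tuple[FactorSpec, ...]
    runs: np.ndarray  # (n_runs, n_factors) int array with entries in {-1, 0, +1}
    run_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        runs = np.asarray(self.runs, dtype=int)
        if runs.ndim != 2 or runs.shape[1] != len(self.factors):
            raise ValidationError("runs must be a 2-D array with one column per factor")
        if not np.isin(runs, (-1, 0, 1)).all():
            raise ValidationError("coded levels must be -1, 0 or +1")
        object.__setattr__(self, "runs", runs)
        if self.run_ids is None:
            object.__setattr__(self, "run_ids", np.arange(1, len(runs) + 1))
        else:
            object.__setattr__(self, "run_ids", np.asarray(self.run_ids, dtype=int))

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def natural(self) -> np.ndarray:
        """Coded runs mapped to natural units, column by column."""
        cols = [f.to_natural(self.runs[:, j]) for j, f in enumerate(self.factors)]
        return np.column_stack(cols)

    def to_frame(self) -> pd.DataFrame:
        nat = self.natural()
        data: dict[str, np.ndarray] = {"run_id": self.run_ids}
        for j, f in enumerate(self.factors):
            data[f"{f.name}_coded"] = self.runs[:, j]
        for j, f in enumerate(self.factors):
            data[f"{f.name}_natural"] = nat[:, j]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ResponseSet:
    """Named response columns aligned row-for-row with a design."""

    names: tuple[str, ...]
    values: np.ndarray  # (n_runs, n_responses)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != len(self.names):
            raise ValidationError("values must have one column per response name")
        if not np.isfinite(values).all():
            raise ValidationError("responses contain non-finite values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError:
            raise ValidationError(f"unknown response {name!r}") from None
        return self.values[:, j]

    @property
    def n_runs(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names))


# Edge blocks in factor-pair order; within a block the off-center factors
# take the sign patterns (-,-), (-,+), (+,-), (+,+).
_PAIR_ORDER = ((0, 1), (0, 2), (1, 2))
_SIGNS = ((-1, -1), (-1, 1), (1, -1), (1, 1))


def generate_bbd(
    factors: tuple[FactorSpec, ...] | list[FactorSpec],
    n_center: int = 3,
    shuffle_seed: int | None = None,
) -> DesignTable:
    """Build the 3-factor Box-Behnken design.

    Twelve edge-midpoint runs (blocks in factor-pair order (1,2), (1,3),
    (2,3)) followed by ``n_center`` center points.  Pass ``shuffle_seed``
    to randomize the run order reproducibly; the default order is
    deterministic so that analyses are repeatable.
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise UnsupportedDesignError(
            f"only 3-factor Box-Behnken designs are supported, got {len(factors)} factors"
        )
    if n_center < 1:
        raise ValidationError("n_center must be >= 1")
    rows = []
    for i, j in _PAIR_ORDER:
        for si, sj in _SIGNS:
            row = [0, 0, 0]
            row[i], row[j] = si, sj
            rows.append(row)
    rows.extend([[0, 0, 0]] * n_center)
    runs = np.array(rows, dtype=int)
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        runs = runs[rng.permutation(len(runs))]
    return DesignTable(factors=factors, runs=runs)


def write_design_responses(
    path, design: DesignTable, responses: ResponseSet | None = None
) -> None:
    """Write the canonical design(+responses) CSV.

    Columns: ``run_id``, one ``<factor>_coded`` and one ``<factor>_natural``
    column per factor, then one column per response.
    """
    frame = design.to_frame()
    if responses is not None:
        if responses.n_runs != design.n_runs:
            raise ValidationError("responses are not aligned with the design rows")
        frame = pd.concat([frame, responses.to_frame()], axis=1)
    frame.to_csv(path, index=False)


def _infer_factor(name: str, coded: np.ndarray, natural: np.ndarray) -> FactorSpec:
    # natural = center + coded * half; recover (center, half) by least squares
    # over the observed (coded, natural) pairs and validate the fit is exact.
    A = np.column_stack([np.ones_like(coded), coded])
    (center, half), *_ = np.linalg.lstsq(A, natural, rcond=None)
    if half <= 0 or not np.allclose(A @ [center, half], natural, rtol=0, atol=1e-9):
        raise FileFormatError(
            f"coded and natural columns for factor {name!r} are inconsistent"
        )
    return FactorSpec(name=name, low=center - half, high=center + half, center=center)


def read_design_responses(path) -> tuple[DesignTable, ResponseSet | None]:
    """Read the canonical design(+responses) CSV written by
    :func:`write_design_responses`, recovering the factor specs from the
    paired coded/natural columns."""
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FileFormatError(f"could not parse {path}: {exc}") from exc
    if "run_id" not in frame.columns:
        raise FileFormatError(f"{path}: missing required column 'run_id'")
    coded_cols = [c for c in frame.columns if c.endswith("_coded")]
    names = [c[: -len("_coded")] for c in coded_cols]
    if not names:
        raise FileFormatError(f"{path}: no '<factor>_coded' columns found")
    factors = []
    for name in names:
        nat_col = f"{name}_natural"
        if nat_col not in frame.columns:
            raise FileFormatError(f"{path}: missing column {nat_col!r}")
        factors.append(
            _infer_factor(
                name,
                frame[f"{name}_coded"].to_numpy(dtype=float),
                frame[nat_col].to_numpy(dtype=float),
            )
        )
    runs = frame[coded_cols].to_numpy()
    if not np.isin(runs, (-1, 0, 1)).all():
        raise FileFormatError(f"{path}: coded levels outside {{-1, 0, +1}}")
    design = DesignTable(
        factors=tuple(factors),
        runs=runs.astype(int),
        run_ids=frame["run_id"].to_numpy(dtype=int),
    )
    resp_cols = [
        c
        for c in frame.columns
        if c != "run_id" and not c.endswith("_coded") and not c.endswith("_natural")
    ]
    responses = None
    if resp_cols:
        responses = ResponseSet(
            names=tuple(resp_cols), values=frame[resp_cols].to_numpy(dtype=float)
        )
    return design, responses


def bbd_edge_points() -> set[tuple[int, int, int]]:
    """All 3-factor BBD edge midpoints, by brute-force enumeration of the
    coded lattice (exactly one coordinate zero, the others at +/-1)."""
    return {
        p
        for p in itertools.product((-1, 0, 1), repeat=3)
        if sum(1 for v in p if v == 0) == 1
    }
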