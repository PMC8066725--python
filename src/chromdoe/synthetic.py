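"""Synthetic data generators for end-to-end testing without an instrument.

Two generators are provided:

* :func:`simulate_bbd_responses` draws noisy response tables from known
  quadratic ground-truth surfaces, so model fitting and optimization can
  be checked against exact coefficients.

* :func:`simulate_chromatogram` builds multi-Gaussian gradient
  chromatograms from a deliberately phenomenological retention model.  It
  reproduces the qualitative retention laws of reversed-phase gradient
  elution — retention times shrink with higher flow, stronger starting or
  ending solvent, and higher temperature — without attempting a physical
  solvent-strength calibration.  Closed forms (constants below):

      tM      = V0 / flow                                     dead time
      k_i     = K0 * exp(h_i - ss_i * %Bstart - se_i * %Bend) * c(T)
      c(T)    = exp(E_T * (1/T_K - 1/T_REF_K))                 Arrhenius-like
      tR_i    = tM * (1 + k_i)
      sigma_i = tR_i / sqrt(N(flow)),  N = N_REF * (flow/0.5)^N_FLOW_EXP

  This mirrors the linear-solvent-strength picture: log k falls linearly
  with the organic fraction, with compound-specific solvent slopes ss_i
  (start of the gradient) and se_i (end of the gradient).  The default
  slopes deliberately alternate around their trend, so strengthening
  either end of the gradient widens some adjacent-pair gaps while
  shrinking others -- the selectivity changes a method developer actually
  exploits -- and the two %B factors act through distinct spacing
  patterns rather than a single composite, so the extracted resolutions
  respond to each gradient setting.  Peaks are Gaussians of fixed plate-count width, with
  areas proportional to each compound's relative response, summed on a
  uniform 40-samples/s grid plus additive Gaussian baseline noise.  The
  mild increase of plate count with flow makes higher flow favourable to
  both resolution and run time, mirroring the behaviour of sub-2-um UHPLC
  columns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .doe import DesignTable, ResponseSet, generate_bbd, write_design_responses
from .errors import ValidationError
from .peaks import Chromatogram, chromatographic_report, detect_peaks, integrate_valley_to_valley
from .rsm import fit_quadratic, model_matrix

__all__ = [
    "TrueSurface",
    "MethodConditions",
    "CompoundSet",
    "default_compound_set",
    "simulate_bbd_responses",
    "retention_times",
    "simulate_chromatogram",
    "CaseStudyBundle",
    "generate_case_study",
]

# Retention-model constants (documented in the module docstring).
DEAD_VOLUME = 0.2  # mL; tM = 0.4 min at 0.5 mL/min
K0 = 0.5
SENS_START_PER_H = 0.007  # fallback solvent slope per %B(start), scaled by h
SENS_END_PER_H = 0.0024  # fallback solvent slope per %B(end), scaled by h
E_T = 800.0  # K; Arrhenius-like temperature sensitivity
T_REF_K = 328.15  # 55 degC
N_REF = 3000.0  # plates at 0.5 mL/min
N_FLOW_EXP = 0.6
SAMPLES_PER_MIN = 2400.0  # 40 pts/s
NOISE_FRACTION = 1e-3  # baseline sigma relative to the tallest peak


@dataclass(frozen=True)
class TrueSurface:
    """Ground-truth quadratic surface (coefficients in fitting order)."""

    response_name: str
    coefficients: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        if coef.shape != (10,):
            raise ValidationError("coefficients must be a length-10 vector")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        object.__setattr__(self, "coefficients", coef)


@dataclass(frozen=True)
class MethodConditions:
    """Operating conditions of one chromatographic run."""

    flow: float  # mL/min
    pctB_start: float
    pctB_end: float
    temperature: float = 55.0  # degC
    gradient_time: float = 5.0  # min

    def __post_init__(self) -> None:
        if self.flow <= 0:
            raise ValidationError("flow must be positive")
        if not 0 <= self.pctB_start < self.pctB_end <= 100:
            raise ValidationError("need 0 <= %B start < %B end <= 100")


@dataclass(frozen=True)
class CompoundSet:
    """Simulated compounds ordered by hydrophobicity (elution order)."""

    names: tuple[str, ...]
    hydrophobicity: np.ndarray  # dimensionless, strictly increasing
    relative_response: np.ndarray  # area factors
    sens_start: np.ndarray | None = None  # solvent slope per %B(start); > 0
    sens_end: np.ndarray | None = None  # solvent slope per %B(end); > 0

    def __post_init__(self) -> None:
        h = np.asarray(self.hydrophobicity, dtype=float)
        r = np.asarray(self.relative_response, dtype=float)
        if len(self.names) == 0 or h.shape != (len(self.names),) or r.shape != h.shape:
            raise ValidationError("names, hydrophobicity and relative_response must align")
        if len(np.unique(h)) != len(h):
            raise ValidationError("hydrophobicity values must be distinct")
        ss = (
            SENS_START_PER_H * h
            if self.sens_start is None
            else np.asarray(self.sens_start, dtype=float)
        )
        se = (
            SENS_END_PER_H * h
            if self.sens_end is None
            else np.asarray(self.sens_end, dtype=float)
        )
        for name, arr in (("sens_start", ss), ("sens_end", se)):
            if arr.shape != h.shape or np.any(arr <= 0):
                raise ValidationError(f"{name} must be positive and align with h")
        object.__setattr__(self, "hydrophobicity", h)
        object.__setattr__(self, "relative_response", r)
        object.__setattr__(self, "sens_start", ss)
        object.__setattr__(self, "sens_end", se)
        object.__setattr__(self, "names", tuple(self.names))

    def __len__(self) -> int:
        return len(self.names)


def default_compound_set() -> CompoundSet:
    """Seven synthetic compounds whose center-point chromatogram spans
    roughly 0.9-2.7 min, emulating a seven-flavonol elution pattern."""
    return CompoundSet(
        names=tuple(f"compound_{i}" for i in range(1, 8)),
        hydrophobicity=np.array([2.1426, 2.3070, 2.5051, 2.6629, 2.7409, 2.7788, 3.0134]),
        relative_response=np.array([0.50, 0.60, 1.00, 0.70, 0.70, 0.95, 0.65]),
        sens_start=np.array([0.020, 0.020, 0.024, 0.020, 0.024, 0.020, 0.024]),
        sens_end=np.array([0.0066, 0.0066, 0.0074, 0.0082, 0.0074, 0.0066, 0.0074]),
    )


def simulate_bbd_responses(
    surfaces: list[TrueSurface], design: DesignTable, seed: int
) -> ResponseSet:
    """Evaluate each ground-truth surface at the design points and add
    independent Gaussian noise; reproducible for a fixed seed."""
    rng = np.random.default_rng(seed)
    M = model_matrix(design.runs)
    cols = []
    for s in surfaces:
        noise = rng.normal(0.0, s.noise_sd, size=design.n_runs) if s.noise_sd > 0 else 0.0
        cols.append(M @ s.coefficients + noise)
    return ResponseSet(
        names=tuple(s.response_name for s in surfaces), values=np.column_stack(cols)
    )


def _retention_model(cond: MethodConditions, compounds: CompoundSet):
    t_m = DEAD_VOLUME / cond.flow
    c = np.exp(E_T * (1.0 / (cond.temperature + 273.15) - 1.0 / T_REF_K))
    log_k = (
        compounds.hydrophobicity
        - compounds.sens_start * cond.pctB_start
        - compounds.sens_end * cond.pctB_end
    )
    k = K0 * np.exp(log_k) * c
    t_r = t_m * (1.0 + k)
    plates = N_REF * (cond.flow / 0.5) ** N_FLOW_EXP
    sigma = t_r / np.sqrt(plates)
    return t_m, k, t_r, sigma


def retention_times(cond: MethodConditions, compounds: CompoundSet) -> np.ndarray:
    """Ground-truth retention times (min) under ``cond``."""
    return _retention_model(cond, compounds)[2]


def simulate_chromatogram(
    cond: MethodConditions,
    compounds: CompoundSet | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
    max_time: float = 6.0,
) -> Chromatogram:
    """Sum-of-Gaussians chromatogram at 40 samples/s with baseline noise.

    ``noise_sd`` defaults to ``NOISE_FRACTION`` of the tallest peak
    amplitude; pass 0 for a noiseless trace.  Compounds whose apex would
    fall beyond ``max_time`` trigger a truncation warning.
    """
    compounds = compounds or default_compound_set()
    t_m, k, t_r, sigma = _retention_model(cond, compounds)
    amplitude = compounds.relative_response / (sigma * np.sqrt(2.0 * np.pi))
    if np.any(t_r + 4.0 * sigma > max_time):
        warnings.warn(
            f"peaks extend beyond the {max_time} min cap; trace truncated", stacklevel=2
        )
    end = min(max_time, float((t_r + 8.0 * sigma).max()))
    n = int(np.ceil(end * SAMPLES_PER_MIN)) + 1
    time = np.arange(n) / SAMPLES_PER_MIN
    signal = np.zeros_like(time)
    for a, mu, s in zip(amplitude, t_r, sigma):
        signal += a * np.exp(-0.5 * ((time - mu) / s) ** 2)
    if noise_sd is None:
        noise_sd = NOISE_FRACTION * float(amplitude.max())
    if noise_sd > 0:
        signal = signal + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return Chromatogram(
        time=time,
        intensity=signal,
        metadata={
            "conditions": cond.__dict__.copy(),
            "true_tR": t_r.tolist(),
            "dead_time": t_m,
        },
    )


RESPONSE_NAMES = ("Rs_3_4", "Rs_4_5", "Rs_5_6", "Rs_6_7", "run_time")


def _extract_responses(chrom: Chromatogram) -> np.ndarray:
    """Resolutions among peaks 3-7 plus run time, as in the study design
    (the two earliest-eluting compounds are excluded from the responses)."""
    table = detect_peaks(
        chrom, min_height=0.05 * float(chrom.intensity.max()), min_separation=0.04
    )
    table = integrate_valley_to_valley(chrom, table)
    if len(table) != 7:
        raise ValidationError(
            f"expected 7 peaks in the simulated chromatogram, found {len(table)}"
        )
    report = chromatographic_report(table, t_m=chrom.metadata["dead_time"]).table
    rs = report["Rs"].to_numpy()[3:7]  # pairs (3,4) ... (6,7)
    run_time = float(table.apex_times()[-1])
    return np.append(rs, run_time)


@dataclass(frozen=True)
class CaseStudyBundle:
    """A complete simulated design study with ground truth attached."""

    design: DesignTable
    chromatograms: list[Chromatogram]
    responses: ResponseSet
    truth: dict = field(default_factory=dict)

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_design_responses(directory / "design_responses.csv", self.design, self.responses)
        chromdir = directory / "chromatograms"
        chromdir.mkdir(exist_ok=True)
        for i, chrom in enumerate(self.chromatograms, start=1):
            chrom.to_csv(chromdir / f"run_{i:02d}.csv")
        (directory / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True))


def generate_case_study(
    seed: int, noise_sd: float | None = None, compounds: CompoundSet | None = None
) -> CaseStudyBundle:
    """Simulate the full designed experiment over the study factor ranges.

    Builds the 15-run design on the study factors, simulates one
    chromatogram per run at 55 degC, extracts the four resolutions and the
    run time through the peak pipeline, and records ground truth: the
    retention constants, true retention times per run, and the desirability
    optimum of the noise-free pipeline (goals mirroring the study: maximize
    resolutions with impacts 4/3/3/4, minimize run time with impact 5).
    """
    from .datasets import GOAL_DIRECTIONS, GOAL_IMPACTS, study_factors
    from .mro import goals_from_observed, optimize_desirability

    compounds = compounds or default_compound_set()
    design = generate_bbd(study_factors(), n_center=3)
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=design.n_runs)
    natural = design.natural()

    def run_all(noise):
        chroms, values = [], []
        for row, run_seed in zip(natural, run_seeds):
            cond = MethodConditions(flow=row[0], pctB_start=row[1], pctB_end=row[2])
            chrom = simulate_chromatogram(
                cond, compounds, noise_sd=noise, seed=int(run_seed)
            )
            chroms.append(chrom)
            values.append(_extract_responses(chrom))
        return chroms, np.array(values)

    def optimum(values):
        responses = ResponseSet(names=RESPONSE_NAMES, values=values)
        models = [
            fit_quadratic(design, responses[name], response_name=name)
            for name in RESPONSE_NAMES
        ]
        goals = goals_from_observed(responses, GOAL_DIRECTIONS, GOAL_IMPACTS)
        return responses, optimize_desirability(models, goals, grid_n=51, polish=True)

    chroms, values = run_all(noise_sd)
    responses, _ = (ResponseSet(names=RESPONSE_NAMES, values=values), None)
    _, truth_values = run_all(0.0)
    _, truth_solution = optimum(truth_values)
    truth = {
        "constants": {
            "dead_volume_mL": DEAD_VOLUME,
            "k0": K0,
            "sens_start": compounds.sens_start.tolist(),
            "sens_end": compounds.sens_end.tolist(),
            "e_t": E_T,
            "plates_ref": N_REF,
            "plate_flow_exp": N_FLOW_EXP,
        },
        "true_tR": [c.metadata["true_tR"] for c in chroms],
        "optimum_coded": [float(v) for v in truth_solution.coded_point],
        "optimum_natural": [float(v) for v in truth_solution.natural_point],
        "optimum_D": float(truth_solution.overall_D),
        "seed": int(seed),
    }
    return CaseStudyBundle(
        design=design, chromatograms=chroms, responses=responses, truth=truth
    )
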