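"""Linear calibration, detection limits, and molecular-mass-ratio transfer.

When an analytical standard is unavailable, a structurally similar
reference compound's calibration is transferred by scaling the slope with
the ratio of neutral molecular masses (equal molar absorptivity assumed):
a heavier analog yields fewer moles per mg, hence a proportionally smaller
slope and larger LOD/LOQ.  Neutral masses are derived from observed
deprotonated ([M-H]-) m/z values by adding the proton mass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "PROTON_MASS",
    "CompoundMass",
    "CalibrationCurve",
    "QuantResult",
    "fit_calibration",
    "lod_loq_from_noise",
    "transfer_curve_by_mass",
    "quantify_extract",
]

PROTON_MASS = 1.00728  # Da


@dataclass(frozen=True)
class CompoundMass:
    """A compound identified by its deprotonated-ion m/z."""

    name: str
    mz_deprotonated: float

    def __post_init__(self) -> None:
        if self.mz_deprotonated <= 0:
            raise ValidationError("m/z must be positive")

    @property
    def neutral_mass(self) -> float:
        return self.mz_deprotonated + PROTON_MASS


@dataclass(frozen=True)
class CalibrationCurve:
    """area = slope * conc + intercept, with figures of merit in mg/L."""

    compound: str
    slope: float
    intercept: float
    r2: float = float("nan")
    lod: float = float("nan")
    loq: float = float("nan")
    conc_range: tuple[float, float] | None = None
    provenance: str = "fitted"  # "fitted" | "mass_transferred"

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError("calibration slope must be positive")

    def concentration(self, area: float) -> float:
        return (area - self.intercept) / self.slope

    def with_limits(self, noise_signal: float) -> "CalibrationCurve":
        lod, loq = lod_loq_from_noise(noise_signal, self.slope)
        return replace(self, lod=lod, loq=loq)


@dataclass(frozen=True)
class QuantResult:
    """Quantified content of one compound in one extract."""

    compound: str
    conc_extract: float  # mg/L in the measured extract
    content: float  # mg per 10 g dry weight
    below_lod: bool = False
    below_loq: bool = False
    above_range: bool = False


def fit_calibration(conc, area, compound: str = "") -> CalibrationCurve:
    """OLS line through calibration points (replicates allowed).

    ``r2`` is the squared Pearson correlation of area with concentration.
    """
    conc = np.asarray(conc, dtype=float)
    area = np.asarray(area, dtype=float)
    if conc.shape != area.shape or conc.ndim != 1:
        raise ValidationError("conc and area must be equal-length 1-D arrays")
    if len(np.unique(conc)) < 2:
        raise ValidationError("need at least 2 distinct concentrations")
    res = stats.linregress(conc, area)
    return CalibrationCurve(
        compound=compound,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        conc_range=(float(conc.min()), float(conc.max())),
        provenance="fitted",
    )


def lod_loq_from_noise(noise_signal: float, slope: float) -> tuple[float, float]:
    """LOD and LOQ (mg/L) from a noise signal in area units.

    LOD = 3 * noise / slope and LOQ = 10 * noise / slope, so LOQ/LOD is
    exactly 10/3.
    """
    if noise_signal <= 0 or slope <= 0:
        raise ValidationError("noise signal and slope must be positive")
    return 3.0 * noise_signal / slope, 10.0 * noise_signal / slope


def transfer_curve_by_mass(
    ref: CalibrationCurve, ref_mass: CompoundMass, target_mass: CompoundMass
) -> CalibrationCurve:
    """Transfer a fitted calibration to a standard-free analog.

    slope scales by ref_mass/target_mass (neutral masses); LOD/LOQ scale
    inversely; the intercept is shared.  Transferring back recovers the
    original curve.
    """
    if ref.provenance != "fitted":
        raise ValidationError("can only transfer from a directly fitted curve")
    ratio = ref_mass.neutral_mass / target_mass.neutral_mass
    return replace(
        ref,
        compound=target_mass.name,
        slope=ref.slope * ratio,
        lod=ref.lod / ratio,
        loq=ref.loq / ratio,
        provenance="mass_transferred",
    )


def quantify_extract(
    area: float,
    curve: CalibrationCurve,
    extract_volume: float = 0.025,
    sample_dry_mass: float = 0.2,
) -> QuantResult:
    """Convert a peak area to mg of compound per 10 g of dry sample.

    Defaults mirror a 25 mL volumetric extract of 0.2 g lyophilized
    material.  Concentrations below the LOD are floored at zero and
    flagged; values above the calibrated range are flagged.
    """
    if extract_volume <= 0 or sample_dry_mass <= 0:
        raise ValidationError("extract volume and dry mass must be positive")
    if area < 0:
        raise ValidationError("area must be non-negative")
    conc = curve.concentration(area)
    below_lod = bool(np.isfinite(curve.lod) and conc < curve.lod) or conc <= 0
    below_loq = bool(np.isfinite(curve.loq) and conc < curve.loq) or conc <= 0
    above = bool(curve.conc_range is not None and conc > curve.conc_range[1])
    conc = max(conc, 0.0)
    content = conc * extract_volume / sample_dry_mass * 10.0
    return QuantResult(
        compound=curve.compound,
        conc_extract=conc if not below_lod else 0.0,
        content=content if not below_lod else 0.0,
        below_lod=below_lod,
        below_loq=below_loq,
        above_range=above,
    )
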