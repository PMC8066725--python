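"""Chromatogram handling and figures of merit.

Times are minutes throughout; intensities are absorbance units (AU).
Peak boundaries follow the manual "valley-to-valley" convention: the
boundary between two peaks is the minimum-intensity sample between their
apexes, the baseline under a peak is the straight segment joining its two
boundary points, and the base width W_b is the boundary-to-boundary span.

Figures of merit:

* resolution          Rs = 2 (tR_B - tR_A) / (W_b,A + W_b,B)
* retention factor    k  = (tR - tM) / tM          (target window 1 < k < 10)
* selectivity         alpha = k_B / k_A
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _find_peaks

from .errors import FileFormatError, ValidationError

__all__ = [
    "Chromatogram",
    "Peak",
    "PeakTable",
    "detect_peaks",
    "integrate_valley_to_valley",
    "resolution",
    "retention_factor",
    "selectivity",
    "estimate_dead_time",
    "chromatographic_report",
]


@dataclass(frozen=True)
class Chromatogram:
    """A time-intensity trace at a single detection wavelength."""

    time: np.ndarray  # minutes, strictly increasing
    intensity: np.ndarray  # AU
    wavelength_nm: float = 360.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if t.shape != i.shape or t.ndim != 1 or len(t) < 2:
            raise ValidationError("time and intensity must be equal-length 1-D arrays (n >= 2)")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", i)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_min": self.time, "intensity_au": self.intensity}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, wavelength_nm: float = 360.0) -> "Chromatogram":
        try:
            frame = pd.read_csv(path)
        except Exception as exc:
            raise FileFormatError(f"could not parse {path}: {exc}") from exc
        for col in ("time_min", "intensity_au"):
            if col not in frame.columns:
                raise FileFormatError(f"{path}: missing column {col!r}")
        return cls(
            time=frame["time_min"].to_numpy(dtype=float),
            intensity=frame["intensity_au"].to_numpy(dtype=float),
            wavelength_nm=wavelength_nm,
        )


@dataclass
class Peak:
    """A detected peak; boundary fields are filled by integration."""

    apex_tR: float
    height: float
    start_t: float | None = None
    end_t: float | None = None
    area: float = float("nan")
    base_width: float = float("nan")

    def __post_init__(self) -> None:
        if self.start_t is not None and self.end_t is not None:
            if not (self.start_t < self.apex_tR < self.end_t) and not np.isclose(
                self.start_t, self.apex_tR
            ) and not np.isclose(self.end_t, self.apex_tR):
                raise ValidationError("peak boundaries must bracket the apex")


@dataclass
class PeakTable:
    """Peaks in elution order with an optional column dead time (min)."""

    peaks: list[Peak]
    dead_time: float | None = None

    def __post_init__(self) -> None:
        apexes = [p.apex_tR for p in self.peaks]
        if any(b <= a for a, b in zip(apexes, apexes[1:])):
            raise ValidationError("peak apexes must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i) -> Peak:
        return self.peaks[i]

    def apex_times(self) -> np.ndarray:
        return np.array([p.apex_tR for p in self.peaks])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "apex_tR_min": [p.apex_tR for p in self.peaks],
                "start_min": [p.start_t for p in self.peaks],
                "end_min": [p.end_t for p in self.peaks],
                "height_au": [p.height for p in self.peaks],
                "area": [p.area for p in self.peaks],
                "base_width_min": [p.base_width for p in self.peaks],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def detect_peaks(
    chrom: Chromatogram, min_height: float, min_separation: float = 0.0
) -> PeakTable:
    """Find apexes as strict local maxima above ``min_height``.

    Apexes must also rise by ``min_height`` above their surroundings
    (topographic prominence), which rejects noise ripples riding on peak
    flanks.  Candidates closer than ``min_separation`` minutes are greedily
    thinned, keeping the taller apex.  A flat or empty trace yields an
    empty table.
    """
    if min_height <= 0:
        raise ValidationError("min_height must be positive")
    idx, _ = _find_peaks(chrom.intensity, height=min_height, prominence=min_height)
    if len(idx) == 0:
        return PeakTable(peaks=[])
    t, h = chrom.time[idx], chrom.intensity[idx]
    keep: list[int] = []
    for j in np.argsort(-h, kind="stable"):  # tallest first
        if all(abs(t[j] - t[k]) >= min_separation for k in keep):
            keep.append(j)
    keep.sort(key=lambda j: t[j])
    peaks = [Peak(apex_tR=float(t[j]), height=float(h[j])) for j in keep]
    table = PeakTable(peaks=peaks)
    table._apex_indices = [int(idx[j]) for j in keep]  # sample indices for integration
    return table


def integrate_valley_to_valley(chrom: Chromatogram, table: PeakTable) -> PeakTable:
    """Fill areas and base widths using valley-to-valley boundaries.

    The boundary between consecutive apexes is the minimum-intensity sample
    between them; the outermost boundaries are the trace ends (with an
    edge-peak warning when an apex sits on a trace end).  The area is the
    trapezoidal integral of intensity minus the straight baseline joining
    the boundary points, clipped at zero.
    """
    if len(table) == 0:
        return PeakTable(peaks=[])
    t, y = chrom.time, chrom.intensity
    apex_idx = getattr(table, "_apex_indices", None)
    if apex_idx is None:
        apex_idx = [int(np.argmin(np.abs(t - p.apex_tR))) for p in table]
    bounds = [0]
    for a, b in zip(apex_idx, apex_idx[1:]):
        bounds.append(a + int(np.argmin(y[a : b + 1])))
    bounds.append(len(t) - 1)
    if apex_idx[0] == 0 or apex_idx[-1] == len(t) - 1:
        warnings.warn("peak apex at trace edge; integrating to the edge", stacklevel=2)
    out = []
    for peak, a, lo, hi in zip(table, apex_idx, bounds, bounds[1:]):
        seg_t, seg_y = t[lo : hi + 1], y[lo : hi + 1]
        baseline = np.interp(seg_t, [t[lo], t[hi]], [y[lo], y[hi]])
        area = float(np.trapezoid(np.clip(seg_y - baseline, 0.0, None), seg_t))
        apex_base = float(np.interp(t[a], [t[lo], t[hi]], [y[lo], y[hi]]))
        out.append(
            Peak(
                apex_tR=peak.apex_tR,
                height=float(y[a] - apex_base),
                start_t=float(t[lo]),
                end_t=float(t[hi]),
                area=area,
                base_width=float(t[hi] - t[lo]),
            )
        )
    return PeakTable(peaks=out, dead_time=table.dead_time)


def resolution(peak_a: Peak, peak_b: Peak) -> float:
    """Rs = 2 (tR_B - tR_A) / (W_b,A + W_b,B) for adjacent peaks A, B."""
    if peak_a.apex_tR > peak_b.apex_tR:
        raise ValidationError("peak_a must elute before peak_b")
    wsum = peak_a.base_width + peak_b.base_width
    if not wsum > 0:
        raise ValidationError("peak base widths must be positive")
    return 2.0 * (peak_b.apex_tR - peak_a.apex_tR) / wsum


def retention_factor(t_r: float, t_m: float) -> float:
    """k = (tR - tM) / tM; warns outside the usual 1 < k < 10 window."""
    if t_m <= 0:
        raise ValidationError("dead time must be positive")
    if t_r < t_m:
        raise ValidationError("retention time before the dead time gives negative k")
    k = (t_r - t_m) / t_m
    if not 1.0 < k < 10.0:
        warnings.warn(f"retention factor {k:.3g} outside the 1-10 guideline window",
                      stacklevel=2)
    return k


def selectivity(k_a: float, k_b: float) -> float:
    """alpha = k_B / k_A for adjacent peaks."""
    if k_a <= 0:
        raise ValidationError("the earlier peak's retention factor must be positive")
    return k_b / k_a


def estimate_dead_time(first_tr: float, k_ref: float) -> float:
    """Dead time implied by a known retention factor: tM = tR / (1 + k)."""
    if k_ref <= 0 or first_tr <= 0:
        raise ValidationError("retention time and reference k must be positive")
    return first_tr / (1.0 + k_ref)


@dataclass(frozen=True)
class ChromReport:
    """Per-peak figures of merit plus the analysis run time."""

    table: pd.DataFrame
    run_time: float
    dead_time: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def chromatographic_report(table: PeakTable, t_m: float | None = None) -> ChromReport:
    """Tabulate tR, W_b, adjusted tR, k, alpha and Rs for each peak.

    ``alpha`` and ``Rs`` compare each peak with its predecessor, so the
    first peak has no entries.  The run time is the last apex time.
    """
    if len(table) == 0:
        raise ValidationError("peak table is empty")
    t_m = t_m if t_m is not None else table.dead_time
    if t_m is None:
        raise ValidationError("a dead time is required (pass t_m or set table.dead_time)")
    rows = []
    prev: Peak | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-peak k-window warnings handled by caller
        for i, p in enumerate(table, start=1):
            k = retention_factor(p.apex_tR, t_m)
            row = {
                "peak": i,
                "tR_min": p.apex_tR,
                "base_width_min": p.base_width,
                "t_prime_R_min": p.apex_tR - t_m,
                "k": k,
                "alpha": np.nan,
                "Rs": np.nan,
            }
            if prev is not None:
                row["alpha"] = selectivity((prev.apex_tR - t_m) / t_m, k)
                if np.isfinite(prev.base_width) and np.isfinite(p.base_width):
                    row["Rs"] = resolution(prev, p)
            rows.append(row)
            prev = p
    return ChromReport(
        table=pd.DataFrame(rows),
        run_time=float(table.apex_times()[-1]),
        dead_time=float(t_m),
    )
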