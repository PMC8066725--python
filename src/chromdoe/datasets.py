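"""Packaged study data.

The canonical 15-run design-and-response table of the flavonol separation
study (three factors: flow rate, %B at the start and %B at the end of the
gradient; responses: four critical-pair resolutions and the run time), the
seven flavonol [M-H]- masses used for calibration transfer, the reference
chromatographic-property table (retention factors and selectivities of the
final method), and the reference calibration figures for quercetin
3-O-glucoside, the one commercially available standard.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .calibration import CalibrationCurve, CompoundMass
from .doe import DesignTable, FactorSpec, ResponseSet, read_design_responses

__all__ = [
    "study_factors",
    "load_design_responses",
    "compound_masses",
    "retention_reference",
    "reference_calibration",
    "GOAL_DIRECTIONS",
    "GOAL_IMPACTS",
    "RESPONSE_NAMES",
]

RESPONSE_NAMES = ("Rs_3_4", "Rs_4_5", "Rs_5_6", "Rs_6_7", "run_time")

#: optimization directions used in the study
GOAL_DIRECTIONS = {
    "Rs_3_4": "maximize",
    "Rs_4_5": "maximize",
    "Rs_5_6": "maximize",
    "Rs_6_7": "maximize",
    "run_time": "minimize",
}

#: impact weights: run time highest (5); critical pairs that dipped below
#: Rs 1.5 intermediate (4); comfortably resolved pairs lower (3)
GOAL_IMPACTS = {"Rs_3_4": 4.0, "Rs_4_5": 3.0, "Rs_5_6": 3.0, "Rs_6_7": 4.0, "run_time": 5.0}

#: reference compound for calibration transfer
REFERENCE_COMPOUND = "quercetin 3-O-glucoside"


def _data_path(name: str):
    return resources.files("chromdoe.data") / name


def study_factors() -> tuple[FactorSpec, FactorSpec, FactorSpec]:
    """The three study factors with their natural-unit levels."""
    return (
        FactorSpec(name="flow", low=0.4, high=0.6, units="mL/min"),
        FactorSpec(name="pctB_start", low=0.0, high=10.0, units="%B"),
        FactorSpec(name="pctB_end", low=50.0, high=100.0, units="%B"),
    )


def load_design_responses() -> tuple[DesignTable, ResponseSet]:
    """The 15-run Box-Behnken design with its measured responses."""
    with resources.as_file(_data_path("bbd_design_responses.csv")) as path:
        design, responses = read_design_responses(path)
    assert responses is not None
    # replace the factors inferred from the CSV with the canonical specs
    # (identical levels, but carrying units)
    design = DesignTable(
        factors=study_factors(), runs=design.runs, run_ids=design.run_ids
    )
    return design, responses


def compound_masses() -> dict[str, CompoundMass]:
    """The seven flavonols keyed by name, with observed [M-H]- m/z."""
    with resources.as_file(_data_path("compound_masses.csv")) as path:
        frame = pd.read_csv(path)
    return {
        row["name"]: CompoundMass(name=row["name"], mz_deprotonated=row["mz_deprotonated"])
        for _, row in frame.iterrows()
    }


def retention_reference() -> pd.DataFrame:
    """Retention times, retention factors and selectivities of the final
    method (alpha is blank for the first-eluting peak)."""
    with resources.as_file(_data_path("chromatographic_properties.csv")) as path:
        return pd.read_csv(path)


def reference_calibration() -> CalibrationCurve:
    """The fitted quercetin 3-O-glucoside curve: slope 8610.35 area units
    per mg/L, intercept 8282.83, six levels spanning 0.1-200 mg/L, LOD
    0.0257 mg/L from the 3x signal-to-noise rule.  The LOQ carries the
    exact 10/3 ratio to the LOD (0.08567, reported rounded as 0.0857)."""
    return CalibrationCurve(
        compound=REFERENCE_COMPOUND,
        slope=8610.35,
        intercept=8282.83,
        r2=0.9997,
        lod=0.0257,
        loq=0.0257 * 10.0 / 3.0,
        conc_range=(0.1, 200.0),
        provenance="fitted",
    )
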