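"""Fluorescence readout: MEF standardization, normalization and logic calls.

Plate-reader fluorescence is reported in arbitrary units that differ between
instruments and gain settings.  Readings are standardized to µM equivalent
fluorescein (MEF) with a conversion factor fitted to a fluorescein dilution
series: replicates are averaged per concentration, the blank average is
subtracted, concentrations with any reader-saturated replicate are excluded,
and a least-squares line restricted to the linear range (0-3.125 µM by
default) gives arbitrary-units-per-µM.

A reaction is called ON when its MEF strictly exceeds a visibility threshold
(0.5 µM fluorescein by default); evaluating all 2^n ligand conditions of a
circuit at a read time yields its truth table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circuit_spec import CircuitSpec, enumerate_conditions, truth_value
from .kinetic_network import KineticParams, compile_network
from .ode_engine import (
    SimulationResult,
    SolverSettings,
    activation_time,
    default_grid,
    simulate,
)

ON_THRESHOLD_MEF = 0.5  #: visible ON threshold, µM fluorescein
LINEAR_RANGE_MAX_UM = 3.125  #: top of the fluorescein linear range


@dataclass
class CalibrationCurve:
    """Linear a.u. → MEF conversion from a fluorescein standard series."""

    conversion_factor: float  #: arbitrary units per µM fluorescein
    intercept: float  #: blank reading, arbitrary units
    linear_range_max: float = LINEAR_RANGE_MAX_UM
    excluded_saturated: list[float] = field(default_factory=list)

    def __post_init__(self):
        if self.conversion_factor <= 0:
            raise ValueError("conversion_factor must be > 0")


def _tidy_standards(standards: pd.DataFrame) -> pd.DataFrame:
    df = standards.copy()
    if "concentration_uM" not in df.columns:
        raise ValueError("standards table needs a 'concentration_uM' column")
    if "reading_au" not in df.columns:
        rep_cols = [c for c in df.columns if c.startswith("rep")]
        if not rep_cols:
            raise ValueError("standards table needs 'reading_au' or rep* columns")
        df = df.melt(
            id_vars=[c for c in df.columns if c not in rep_cols],
            value_vars=rep_cols,
            var_name="replicate",
            value_name="reading_au",
        )
    if "saturated" not in df.columns:
        df["saturated"] = False
    return df


def fit_mef_calibration(
    standards: pd.DataFrame, linear_range_max: float = LINEAR_RANGE_MAX_UM
) -> CalibrationCurve:
    """Fit the MEF conversion factor from a fluorescein standard plate.

    ``standards`` is a table with columns ``concentration_uM``, replicate
    readings (either tidy ``reading_au`` or wide ``rep*`` columns) and an
    optional boolean ``saturated`` flag.  A concentration with any saturated
    replicate is dropped entirely; the remaining replicates are averaged, the
    blank (0 µM) average is subtracted everywhere, and the slope is fitted by
    least squares over concentrations within the linear range.
    """
    tidy = _tidy_standards(standards)
    sat = tidy.groupby("concentration_uM")["saturated"].any()
    excluded = sorted(sat[sat].index.tolist())
    means = (
        tidy[~tidy["concentration_uM"].isin(excluded)]
        .groupby("concentration_uM")["reading_au"]
        .mean()
    )
    if means.empty:
        raise ValueError("all standard concentrations are saturated")
    if 0.0 not in means.index:
        raise ValueError("standards must include a blank (0 µM)")
    blank = float(means.loc[0.0])
    in_range = means[means.index <= linear_range_max]
    if len(in_range) < 3:
        raise ValueError(
            f"need >= 3 usable concentrations within the linear range, "
            f"got {len(in_range)}"
        )
    conc = in_range.index.to_numpy(dtype=float)
    au = in_range.to_numpy(dtype=float) - blank
    slope = float(np.polyfit(conc, au, 1)[0])
    if slope <= 0:
        raise ValueError("standard series has non-positive slope")
    return CalibrationCurve(
        conversion_factor=slope,
        intercept=blank,
        linear_range_max=linear_range_max,
        excluded_saturated=excluded,
    )


def to_mef(raw, cal: CalibrationCurve):
    """Convert arbitrary-unit readings to MEF (µM fluorescein)."""
    return (np.asarray(raw, dtype=float) - cal.intercept) / cal.conversion_factor


def normalize_trace(trace, max_mef: float):
    """Baseline-subtracted normalization used for model/data comparison:

    f(x) = (MEF_t=x − MEF_t=0) / (MaxMEF − MEF_t=0),

    where MaxMEF is the maximum MEF among all compared conditions.
    """
    trace = np.asarray(trace, dtype=float)
    if max_mef <= trace[0]:
        raise ValueError("max_mef must exceed the baseline MEF")
    return (trace - trace[0]) / (max_mef - trace[0])


def call_on_off(mef_at_read: float, on_threshold_mef: float = ON_THRESHOLD_MEF) -> str:
    """ON iff MEF strictly exceeds the visibility threshold."""
    return "ON" if mef_at_read > on_threshold_mef else "OFF"


@dataclass
class TruthTable:
    """Evaluated ON/OFF calls over all input conditions of one circuit."""

    circuit_name: str
    ligand_names: tuple[str, ...]
    read_time: float
    on_level: float
    on_threshold_mef: float
    inputs: list[tuple[int, ...]]
    mef: list[float]
    calls: list[str]
    intended_logic: str | None
    expected: list[str]

    @property
    def matches_intended(self) -> bool:
        return self.calls == self.expected

    def to_dict(self) -> dict:
        return {
            "circuit": self.circuit_name,
            "ligands": list(self.ligand_names),
            "read_time_min": self.read_time,
            "on_level_uM": self.on_level,
            "on_threshold_mef": self.on_threshold_mef,
            "intended_logic": self.intended_logic,
            "matches_intended": self.matches_intended,
            "rows": [
                {"inputs": list(i), "mef": m, "call": c, "expected": e}
                for i, m, c, e in zip(self.inputs, self.mef, self.calls, self.expected)
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_markdown(self) -> str:
        head = " | ".join([*self.ligand_names, "MEF", "call", "expected"])
        sep = " | ".join(["---"] * (len(self.ligand_names) + 3))
        rows = [
            " | ".join([*(str(b) for b in i), f"{m:.3f}", c, e])
            for i, m, c, e in zip(self.inputs, self.mef, self.calls, self.expected)
        ]
        return "\n".join([head, sep, *rows])


def _mef_at(result: SimulationResult, read_time: float) -> float:
    return float(np.interp(read_time, result.t_grid, result.mef()))


def evaluate_truth_table(
    circuit: CircuitSpec,
    params: KineticParams | None = None,
    read_time: float = 120.0,
    on_level: float = 10.0,
    on_threshold_mef: float = ON_THRESHOLD_MEF,
    settings: SolverSettings | None = None,
) -> TruthTable:
    """Simulate every enumerated ligand condition and call ON/OFF at read time.

    The expected column is derived from the circuit's ``intended_logic`` label
    applied to the circuit's ordered ligand list.
    """
    params = params or KineticParams()
    if settings is None:
        settings = SolverSettings(
            rtol=1e-8, atol=1e-11, t_grid=default_grid(max(read_time, 120.0))
        )
    inputs: list[tuple[int, ...]] = []
    mefs: list[float] = []
    calls: list[str] = []
    expected: list[str] = []
    for cond in enumerate_conditions(circuit, on_level):
        bits = tuple(int(cond[l] > 0) for l in circuit.ligand_names)
        net = compile_network(circuit, params, cond)
        res = simulate(net, settings)
        m = _mef_at(res, read_time)
        inputs.append(bits)
        mefs.append(m)
        calls.append(call_on_off(m, on_threshold_mef))
        if circuit.intended_logic is not None:
            expected.append(
                "ON" if truth_value(circuit.intended_logic, bits) else "OFF"
            )
        else:
            expected.append(calls[-1])
    return TruthTable(
        circuit_name=circuit.name,
        ligand_names=circuit.ligand_names,
        read_time=read_time,
        on_level=on_level,
        on_threshold_mef=on_threshold_mef,
        inputs=inputs,
        mef=mefs,
        calls=calls,
        intended_logic=circuit.intended_logic,
        expected=expected,
    )


def time_to_detection(
    result: SimulationResult, on_threshold_mef: float = ON_THRESHOLD_MEF
) -> float | None:
    """First time (min) the MEF trace becomes visibly ON; None if never."""
    return activation_time(result, "F", on_threshold_mef)
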