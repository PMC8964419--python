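"""Kinetic comparator and analog-to-digital converter (ADC) design.

A DNA *threshold gate* shares its invader with the fluorescent signal gate but
carries a longer (saturating, 8-nt) toehold, so it consumes the invader two
orders of magnitude faster than the slowed (4-nt) signal gate.  Fluorescence
therefore stays dark until the threshold gate is exhausted: the reaction acts
as a kinetic comparator whose activation time grows with the threshold-gate
concentration.

An ADC is a strip of otherwise identical sensing reactions with increasing
threshold-gate concentrations θ₁ < θ₂ < … < θ_J.  Read at a fixed time, a
sample turns ON a prefix of the strip (a thermometer code) whose length
encodes the ligand-concentration bin.  ``design_thresholds`` calibrates each
θ_j by bisection so that tube j switches between consecutive breakpoint
concentrations; the finished design is audited for thermometer behaviour
before being returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .circuit_spec import (
    CircuitSpec,
    GateSpec,
    from_document,
    to_document,
)
from .kinetic_network import KineticParams, compile_network
from .ode_engine import SolverSettings, default_grid, simulate
from .readout import ON_THRESHOLD_MEF, call_on_off

THRESHOLD_GATE_TOEHOLD_NT = 8


class ThresholdBracketError(RuntimeError):
    """The signal never reaches the ON threshold for any threshold-gate amount."""


class DesignAuditError(RuntimeError):
    """A candidate ADC design failed its thermometer-behaviour audit."""

    def __init__(self, message: str, report: dict):
        super().__init__(message)
        self.report = report


def with_threshold(circuit: CircuitSpec, theta: float) -> CircuitSpec:
    """Return the circuit with a threshold gate at ``theta`` µM added.

    The gate consumes the signal gate's invader through a saturating toehold
    and is unlabeled: it produces no fluorescence, only waste.
    """
    if theta < 0:
        raise ValueError("threshold-gate concentration must be >= 0")
    if theta == 0:
        return circuit
    invader = circuit.signal_gate().invader_names[0]
    gate = GateSpec(
        "threshold", "threshold", (invader,), THRESHOLD_GATE_TOEHOLD_NT,
        concentration=theta,
    )
    return replace(circuit, gates=circuit.gates + (gate,))


def _fast_settings(read_time: float) -> SolverSettings:
    return SolverSettings(rtol=1e-7, atol=1e-10, t_grid=default_grid(max(read_time, 1.0)))


def mef_at_read(
    circuit: CircuitSpec,
    input_conc: float,
    theta: float,
    read_time: float,
    params: KineticParams | None = None,
    settings: SolverSettings | None = None,
) -> float:
    """End-point MEF of the (single-ligand) circuit with a threshold gate."""
    (ligand,) = circuit.ligand_names
    net = compile_network(
        with_threshold(circuit, theta), params, {ligand: float(input_conc)}
    )
    res = simulate(net, settings or _fast_settings(read_time))
    return float(np.interp(read_time, res.t_grid, res.mef()))


def critical_threshold(
    circuit: CircuitSpec,
    input_conc: float,
    read_time: float = 100.0,
    params: KineticParams | None = None,
    on_threshold_mef: float = ON_THRESHOLD_MEF,
    rel_tol: float = 1e-3,
) -> float:
    """Threshold-gate concentration at which MEF(read_time) equals the ON level.

    Solved by bracketing and bisection to a relative tolerance of ``rel_tol``.
    Returns 0 when the reaction is OFF even without a threshold gate.  Raises
    :class:`ThresholdBracketError` if no gate amount within 2^20× the signal
    gate switches the reaction OFF (the input drives the signal past the ON
    level regardless — no finite threshold brackets the crossing).
    """
    params = params or KineticParams()
    settings = _fast_settings(read_time)

    def f(theta: float) -> float:
        return (
            mef_at_read(circuit, input_conc, theta, read_time, params, settings)
            - on_threshold_mef
        )

    if f(0.0) <= 0:
        return 0.0
    hi = circuit.signal_gate().concentration or 1.0
    for _ in range(20):
        if f(hi) < 0:
            break
        hi *= 2.0
    else:
        raise ThresholdBracketError(
            f"no threshold-gate amount up to {hi:g} µM turns the reaction OFF "
            f"at input {input_conc:g} µM"
        )
    return float(brentq(f, 0.0, hi, rtol=rel_tol, xtol=rel_tol * hi * 1e-3))


@dataclass
class ADCDesign:
    """A calibrated thermometer-coded tube strip for one sensor circuit."""

    base_circuit: CircuitSpec
    thresholds: tuple[float, ...]  #: θ_j, µM of threshold gate per tube
    breakpoints: tuple[float, ...]  #: ligand concentrations separating bins, µM
    read_time: float = 100.0
    on_threshold_mef: float = ON_THRESHOLD_MEF

    def __post_init__(self):
        if len(self.thresholds) != len(self.breakpoints) or not self.thresholds:
            raise ValueError("need one threshold per breakpoint (J >= 1)")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must increase strictly")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must increase strictly")

    def to_json(self) -> str:
        return json.dumps(
            {
                "base_circuit": to_document(self.base_circuit),
                "thresholds_uM": list(self.thresholds),
                "breakpoints_uM": list(self.breakpoints),
                "read_time_min": self.read_time,
                "on_threshold_mef": self.on_threshold_mef,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ADCDesign":
        doc = json.loads(text)
        return cls(
            base_circuit=from_document(doc["base_circuit"]),
            thresholds=tuple(doc["thresholds_uM"]),
            breakpoints=tuple(doc["breakpoints_uM"]),
            read_time=doc.get("read_time_min", 100.0),
            on_threshold_mef=doc.get("on_threshold_mef", ON_THRESHOLD_MEF),
        )


@dataclass
class TubePattern:
    """Per-tube ON/OFF calls and the decoded ligand-concentration interval."""

    calls: tuple[str, ...]
    mef: tuple[float, ...]
    decoded_interval: tuple[float | None, float | None]
    is_thermometer: bool

    @property
    def n_on(self) -> int:
        return sum(c == "ON" for c in self.calls)

    def describe(self, unit: str = "µM") -> str:
        lo, hi = self.decoded_interval
        if not self.is_thermometer:
            return "invalid (non-thermometer) pattern: " + ",".join(self.calls)
        if lo is None:
            return f"< {hi:g} {unit}"
        if hi is None:
            return f">= {lo:g} {unit}"
        return f"{lo:g} - {hi:g} {unit}"


def simulate_adc(
    design: ADCDesign, input_conc: float, params: KineticParams | None = None
) -> TubePattern:
    """Simulate every tube of the strip at one input and decode the pattern."""
    params = params or KineticParams()
    settings = _fast_settings(design.read_time)
    mefs = tuple(
        mef_at_read(design.base_circuit, input_conc, theta, design.read_time,
                    params, settings)
        for theta in design.thresholds
    )
    calls = tuple(call_on_off(m, design.on_threshold_mef) for m in mefs)
    n_on = sum(c == "ON" for c in calls)
    thermometer = all(c == "ON" for c in calls[:n_on]) and all(
        c == "OFF" for c in calls[n_on:]
    )
    bounds = (None, *design.breakpoints, None)
    decoded = (bounds[n_on], bounds[n_on + 1]) if thermometer else (None, None)
    return TubePattern(calls, mefs, decoded, thermometer)


def audit_monotonicity(
    design: ADCDesign,
    input_grid: Sequence[float],
    params: KineticParams | None = None,
) -> dict:
    """Check thermometer coding and monotone ON-counts over an input grid."""
    rows = []
    ok = True
    prev = -1
    for conc in input_grid:
        pat = simulate_adc(design, float(conc), params)
        good = pat.is_thermometer and pat.n_on >= prev
        ok = ok and good
        prev = max(prev, pat.n_on)
        rows.append(
            {"input_uM": float(conc), "calls": pat.calls, "n_on": pat.n_on,
             "thermometer": pat.is_thermometer, "ok": good}
        )
    return {"ok": ok, "rows": rows}


def design_thresholds(
    circuit: CircuitSpec,
    breakpoints: Sequence[float],
    read_time: float = 100.0,
    params: KineticParams | None = None,
    on_threshold_mef: float = ON_THRESHOLD_MEF,
    blank_level: float | None = None,
) -> ADCDesign:
    """Calibrate one threshold-gate concentration per breakpoint.

    Tube j is calibrated at the geometric midpoint of (c_{j-1}, c_j) — the
    dose-response is log-scaled, so the geometric mean places both adjacent
    breakpoints safely inside the tube's ON and OFF regions.  c₀ defaults to
    breakpoints[0]/4 (the highest input still considered blank-like).  The
    finished design is audited at every breakpoint (expected ON-counts
    1..J) before being returned; failure raises :class:`DesignAuditError`
    carrying the audit report.
    """
    params = params or KineticParams()
    breakpoints = tuple(float(b) for b in breakpoints)
    if not breakpoints or np.any(np.diff(breakpoints) <= 0):
        raise ValueError("breakpoints must be a strictly increasing, non-empty list")
    c0 = breakpoints[0] / 4.0 if blank_level is None else float(blank_level)
    if c0 >= breakpoints[0]:
        raise ValueError("blank level must sit below the first breakpoint")
    edges = (c0, *breakpoints)
    thetas = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = float(np.sqrt(lo * hi)) if lo > 0 else hi / 2.0
        thetas.append(
            critical_threshold(circuit, mid, read_time, params, on_threshold_mef)
        )
    if np.any(np.diff(thetas) <= 0):
        raise DesignAuditError(
            "calibrated thresholds are not strictly increasing "
            f"(sensor response may not be monotone): {thetas}",
            {"thresholds": thetas},
        )
    design = ADCDesign(
        base_circuit=circuit,
        thresholds=tuple(thetas),
        breakpoints=breakpoints,
        read_time=read_time,
        on_threshold_mef=on_threshold_mef,
    )
    audit = audit_monotonicity(design, breakpoints, params)
    counts = [row["n_on"] for row in audit["rows"]]
    if not audit["ok"] or counts != list(range(1, len(breakpoints) + 1)):
        raise DesignAuditError(
            f"audit failed: ON-counts at breakpoints are {counts}, expected "
            f"{list(range(1, len(breakpoints) + 1))}",
            audit,
        )
    return design
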