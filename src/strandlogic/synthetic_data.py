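"""Synthetic plate-reader data for every pipeline stage.

Generators emulate the experimental data layout the package consumes: kinetic
fluorescence reads at 1-min intervals for 2 h at 37 °C with three replicates,
fluorescein calibration plates (two-fold serial dilution from a 50 µM stock,
12 samples including the buffer blank, nine replicates each), and end-point
dose-response series.  The underlying "truth" is the package's own ODE model;
measurement noise is a stylized plate-reader model with a multiplicative
(gain/pipetting) and an additive (read) component, clipped at a configurable
detector ceiling.

All generators are pure functions of their inputs and a seed: regeneration
with the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circuit_spec import CircuitSpec
from .kinetic_network import KineticParams, compile_network
from .ode_engine import SolverSettings, default_grid, simulate


@dataclass(frozen=True)
class NoiseModel:
    """Stylized plate-reader noise: reading = clean·(1+cv·ε₁) + sd·ε₂.

    ``additive_sd`` is in the units of the trace (MEF for kinetics, a.u. for
    standards); ``saturation_ceiling`` (a.u.) clips standard-plate readings.
    """

    additive_sd: float = 0.05
    multiplicative_cv: float = 0.02
    saturation_ceiling: float = 20000.0

    def __post_init__(self):
        if self.additive_sd < 0 or self.multiplicative_cv < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        clean = np.asarray(clean, dtype=float)
        noisy = clean * (1.0 + self.multiplicative_cv * rng.standard_normal(clean.shape))
        return noisy + self.additive_sd * rng.standard_normal(clean.shape)


NOISELESS = NoiseModel(additive_sd=0.0, multiplicative_cv=0.0)


def _clean_mef(
    circuit: CircuitSpec,
    params: KineticParams | None,
    condition: Mapping[str, float],
    t_grid: np.ndarray,
) -> np.ndarray:
    net = compile_network(circuit, params, condition)
    settings = SolverSettings(rtol=1e-8, atol=1e-11, t_grid=t_grid)
    return simulate(net, settings).mef()


def generate_trace(
    circuit: CircuitSpec,
    params: KineticParams | None = None,
    condition: Mapping[str, float] | None = None,
    noise: NoiseModel = NoiseModel(),
    interval: float = 1.0,
    duration: float = 120.0,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated noisy kinetic reads of one circuit condition.

    Returns a tidy table (time_min, replicate, mef) sampled on a 1-min grid by
    default; the clean trajectory is shared, noise is drawn per replicate.
    """
    rng = np.random.default_rng(seed)
    t_grid = default_grid(duration, interval)
    clean = _clean_mef(circuit, params, condition or {}, t_grid)
    frames = []
    for rep in range(1, replicates + 1):
        frames.append(
            pd.DataFrame(
                {"time_min": t_grid, "replicate": rep, "mef": noise.apply(clean, rng)}
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_standards(
    stock_uM: float = 50.0,
    n_samples: int = 12,
    replicates: int = 9,
    conversion_factor: float = 1000.0,
    intercept: float = 120.0,
    dilution_factor: float = 2.0,
    noise: NoiseModel = NoiseModel(additive_sd=20.0, multiplicative_cv=0.02),
    seed: int = 0,
) -> pd.DataFrame:
    """Fluorescein standard plate: serial dilutions from a stock plus a blank.

    ``n_samples`` counts the blank, so the default produces eleven two-fold
    dilutions of the 50 µM stock plus the buffer blank, each with nine
    replicate readings.  Readings are intercept + conversion_factor·conc with
    noise, clipped at the detector ceiling; clipped readings are flagged in
    the ``saturated`` column.
    """
    if conversion_factor <= 0:
        raise ValueError("conversion_factor must be > 0")
    rng = np.random.default_rng(seed)
    concs = [stock_uM / dilution_factor**i for i in range(n_samples - 1)] + [0.0]
    rows = []
    for conc in concs:
        clean = np.full(replicates, intercept + conversion_factor * conc)
        noisy = noise.apply(clean, rng)
        clipped = np.minimum(noisy, noise.saturation_ceiling)
        for rep, (val, raw) in enumerate(zip(clipped, noisy), start=1):
            rows.append(
                {
                    "concentration_uM": conc,
                    "replicate": rep,
                    "reading_au": float(val),
                    "saturated": bool(raw >= noise.saturation_ceiling),
                }
            )
    return pd.DataFrame(rows)


def generate_dose_response(
    circuit: CircuitSpec,
    ligand_grid: Sequence[float],
    read_time: float = 60.0,
    params: KineticParams | None = None,
    noise: NoiseModel = NoiseModel(),
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """End-point MEF of a single-ligand circuit over a concentration series."""
    if len(ligand_grid) == 0:
        raise ValueError("ligand_grid must be non-empty")
    (ligand,) = circuit.ligand_names
    rng = np.random.default_rng(seed)
    t_grid = default_grid(read_time)
    rows = []
    for conc in ligand_grid:
        clean = _clean_mef(circuit, params, {ligand: float(conc)}, t_grid)[-1]
        noisy = noise.apply(np.full(replicates, clean), rng)
        for rep, val in enumerate(noisy, start=1):
            rows.append(
                {
                    "ligand": ligand,
                    "concentration_uM": float(conc),
                    "replicate": rep,
                    "mef": float(val),
                }
            )
    return pd.DataFrame(rows)
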