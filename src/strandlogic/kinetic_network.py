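"""Compile circuit descriptions into mass-action reaction networks.

The mechanistic model has three reaction families:

* **aTF binding** — a free transcription-factor dimer reversibly occupies the
  operator of its template (blocking transcription) and is reversibly
  inactivated by a lumped cooperative ligand-binding step; ligand-bound aTF
  cannot bind the operator.
* **in vitro transcription (IVT)** — free template catalytically produces its
  transcript at a pseudo-first-order rate ``k_tx`` (T7 RNA polymerase and NTPs
  are in large excess over nM templates on the 2-h timescale, so no resource
  depletion is modelled).
* **TMSD** — invader strands react with gates at a rate set by the exponential
  toehold-length law, optionally slowed by a mismatch penalty and a
  per-transcript secondary-structure penalty.  AND gates open by reversible
  toehold exchange with the first invader and release their output
  irreversibly with the second; a clamp-dependent leak pathway lets the first
  invader alone release output at a strongly suppressed rate.  RNA NOT gates
  and DNA threshold gates consume their invader irreversibly to inert waste.

Units: concentrations µM, time minutes, bimolecular rates µM⁻¹·min⁻¹.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Mapping

import numpy as np

from .circuit_spec import CircuitSpec, GateSpec, validate_or_raise


@dataclass(frozen=True)
class TFBindingParams:
    """Operator and ligand binding constants of one aTF.

    k_on_* are in µM⁻¹·min⁻¹ (the lumped ligand step of a stoichiometry-2 aTF
    is µM⁻²·min⁻¹), k_off_* in min⁻¹.
    """

    k_on_op: float
    k_off_op: float
    k_on_lig: float
    k_off_lig: float


def _default_tf_binding() -> dict[str, TFBindingParams]:
    # Calibrated per-aTF constants.  TetR represses tetO with low-nM affinity
    # and binds anhydrotetracycline/tetracycline nearly irreversibly; SmtB is
    # modelled with a weaker (0.3 µM) effective zinc affinity, which spreads
    # the zinc dose-response over the 2-10 µM window.  TtgR is given
    # TetR-like operator kinetics and a 0.1 µM naringenin affinity.
    return {
        "TetR": TFBindingParams(k_on_op=300.0, k_off_op=0.6, k_on_lig=60.0, k_off_lig=6e-4),
        "SmtB": TFBindingParams(k_on_op=300.0, k_off_op=1.2, k_on_lig=60.0, k_off_lig=18.0),
        "TtgR": TFBindingParams(k_on_op=300.0, k_off_op=0.6, k_on_lig=60.0, k_off_lig=6.0),
    }


@dataclass(frozen=True)
class KineticParams:
    """All rate constants and design-feature laws of the model.

    The zero-argument constructor gives the package's calibrated defaults:
    literature-scale magnitudes (saturated TMSD near 1e6 M⁻¹s⁻¹, tight nM
    operator binding, fast transcription) refined against the standard sensor
    conditions (50 nM template, 5 µM TetR dimer, 5 µM signal gate) so that the
    packaged circuit library computes its truth tables.
    """

    k_tx: float = 10.0  #: transcripts per free template per min
    k_on_op: float = 300.0  #: fallback aTF-operator on-rate, µM⁻¹·min⁻¹
    k_off_op: float = 0.6  #: fallback aTF-operator off-rate, min⁻¹
    k_on_lig: float = 60.0  #: fallback aTF-ligand on-rate
    k_off_lig: float = 6e-4  #: fallback aTF-ligand off-rate
    k_tmsd_max: float = 60.0  #: saturated strand-displacement rate, µM⁻¹·min⁻¹
    decade_per_nt: float = 1.0  #: rate decades lost per nt of toehold below saturation
    n_sat: int = 6  #: toehold length (nt) at which displacement saturates
    mismatch_penalty: float = 0.005  #: rate factor for displacement across a mismatch
    clamp_leak0: float = 0.6  #: AND-gate leak rate at zero clamp, µM⁻¹·min⁻¹
    clamp_decay_per_bp: float = 0.6  #: leak decades suppressed per clamp bp
    k_rev_toehold_exchange: float = 60.0  #: reverse rate of the AND first step, min⁻¹
    structure_penalty: Mapping[str, float] = field(default_factory=dict)
    tf_binding: Mapping[str, TFBindingParams] = field(default_factory=_default_tf_binding)

    def __post_init__(self):
        for name in ("k_tx", "k_on_op", "k_off_op", "k_on_lig", "k_off_lig",
                     "k_tmsd_max", "decade_per_nt", "clamp_leak0",
                     "clamp_decay_per_bp", "k_rev_toehold_exchange"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.mismatch_penalty <= 1:
            raise ValueError("mismatch_penalty must be in (0, 1]")
        for t, v in self.structure_penalty.items():
            if not 0 < v <= 1:
                raise ValueError(f"structure_penalty[{t!r}] must be in (0, 1]")
        if self.n_sat < 1:
            raise ValueError("n_sat must be >= 1")

    def binding_for(self, tf_name: str) -> TFBindingParams:
        """Per-aTF binding constants, falling back to the global defaults."""
        got = self.tf_binding.get(tf_name)
        if got is not None:
            return got
        return TFBindingParams(self.k_on_op, self.k_off_op, self.k_on_lig, self.k_off_lig)

    # -- JSON round trip (explicit units in the document) -------------------

    def to_json(self) -> str:
        doc = asdict(self)
        doc["structure_penalty"] = dict(self.structure_penalty)
        doc["tf_binding"] = {k: asdict(v) for k, v in self.tf_binding.items()}
        doc["units"] = {
            "concentration": "uM",
            "time": "min",
            "bimolecular_rate": "1/uM/min",
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "KineticParams":
        doc = json.loads(text)
        doc.pop("units", None)
        doc["tf_binding"] = {
            k: TFBindingParams(**v) for k, v in doc.get("tf_binding", {}).items()
        }
        return cls(**doc)


def toehold_rate(toehold_nt: int, params: KineticParams) -> float:
    """Displacement rate constant (µM⁻¹·min⁻¹) for a toehold of given length.

    k(n) = k_tmsd_max · 10^(−decade_per_nt · max(0, n_sat − n)): exponential
    growth with toehold length up to saturation at ``n_sat`` nucleotides.
    """
    if toehold_nt < 1:
        raise ValueError("toehold_nt must be >= 1")
    return params.k_tmsd_max * 10.0 ** (
        -params.decade_per_nt * max(0, params.n_sat - toehold_nt)
    )


# ---------------------------------------------------------------------------
# network types


ROLES = (
    "template", "template_TF_complex", "TF_free", "TF_ligand_complex", "ligand",
    "transcript", "dna_gate", "rna_gate", "intermediate", "released_output",
    "fluorophore_free", "waste",
)


@dataclass
class Species:
    """One chemical species: name, mechanistic role, initial concentration (µM)
    and the conserved entities (strands, protein, ligand) it contains."""

    name: str
    role: str
    initial_concentration: float = 0.0
    contains: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class Reaction:
    """An elementary mass-action reaction (reactants listed with multiplicity)."""

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: float
    label: str

    @property
    def order(self) -> int:
        return len(self.reactants)


@dataclass
class ConservedTotal:
    """A linear combination of species that the network leaves invariant."""

    label: str
    weights: dict[str, float]
    value: float


@dataclass
class ReactionNetwork:
    """Species + reactions compiled from one circuit under one input condition."""

    circuit_name: str
    condition: dict[str, float]
    species: list[Species]
    reactions: list[Reaction]

    def index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species])

    def stoichiometry_matrix(self) -> np.ndarray:
        """Species × reactions net-stoichiometry matrix."""
        idx = self.index()
        n_mat = np.zeros((len(self.species), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for name in r.reactants:
                n_mat[idx[name], j] -= 1
            for name in r.products:
                n_mat[idx[name], j] += 1
        return n_mat

    def species_by_role(self, role: str) -> list[Species]:
        return [s for s in self.species if s.role == role]

    def to_table(self):
        """Flat reaction table (reactants, products, rate constant) as a DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "label": [r.label for r in self.reactions],
                "reactants": [" + ".join(r.reactants) for r in self.reactions],
                "products": [" + ".join(r.products) for r in self.reactions],
                "rate_constant": [r.rate_constant for r in self.reactions],
            }
        )


# ---------------------------------------------------------------------------
# compilation


class _Builder:
    def __init__(self):
        self.species: dict[str, Species] = {}
        self.reactions: list[Reaction] = []

    def add_species(self, name, role, init=0.0, contains=None) -> str:
        if name in self.species:
            sp = self.species[name]
            sp.initial_concentration += init
        else:
            self.species[name] = Species(name, role, init, dict(contains or {}))
        return name

    def add_reaction(self, reactants, products, k, label):
        self.reactions.append(Reaction(tuple(reactants), tuple(products), float(k), label))


def compile_network(
    circuit: CircuitSpec,
    params: KineticParams | None = None,
    condition: Mapping[str, float] | None = None,
) -> ReactionNetwork:
    """Compile a validated circuit into an explicit reaction network.

    ``condition`` maps ligand names to initial concentrations (µM); omitted
    ligands start at zero.  Intermediates, transcripts and released strands
    start at zero; templates, aTFs, ligands and DNA gates start at their
    specified concentrations.
    """
    params = params or KineticParams()
    validate_or_raise(circuit)
    condition = dict(condition or {})
    b = _Builder()

    transcripts = {t.transcript_name for t in circuit.templates}
    not_gate_names = {g.name for g in circuit.gates if g.kind == "not_rna"}

    # --- sensing layer ----------------------------------------------------
    for tf in circuit.tfs:
        b.add_species(tf.name, "TF_free", tf.dimer_total, {f"prot:{tf.name}": 1})
    for lig in circuit.ligand_names:
        b.add_species(lig, "ligand", condition.get(lig, 0.0), {f"lig:{lig}": 1})
    for tf in circuit.tfs:
        bp = params.binding_for(tf.name)
        cplx = f"{tf.name}:{tf.ligand_name}"
        b.add_species(
            cplx, "TF_ligand_complex", 0.0,
            {f"prot:{tf.name}": 1, f"lig:{tf.ligand_name}": tf.ligand_stoichiometry},
        )
        lig_side = [tf.ligand_name] * tf.ligand_stoichiometry
        b.add_reaction([tf.name, *lig_side], [cplx], bp.k_on_lig, f"lig_bind:{tf.name}")
        b.add_reaction([cplx], [tf.name, *lig_side], bp.k_off_lig, f"lig_release:{tf.name}")

    # --- templates and transcription ---------------------------------------
    for t in circuit.templates:
        b.add_species(t.name, "template", t.concentration, {f"dna:{t.name}": 1})
        role = "rna_gate" if t.transcript_name in not_gate_names else "transcript"
        b.add_species(t.transcript_name, role, 0.0, {})
        if t.operator_id is not None:
            tf = circuit.tf_for_operator(t.operator_id)
            bp = params.binding_for(tf.name)
            bound = f"{t.name}:{tf.name}"
            b.add_species(
                bound, "template_TF_complex", 0.0,
                {f"dna:{t.name}": 1, f"prot:{tf.name}": 1},
            )
            b.add_reaction([tf.name, t.name], [bound], bp.k_on_op, f"op_bind:{t.name}")
            b.add_reaction([bound], [tf.name, t.name], bp.k_off_op, f"op_release:{t.name}")
        b.add_reaction(
            [t.name], [t.name, t.transcript_name],
            params.k_tx * t.tx_efficiency_factor, f"tx:{t.name}",
        )

    # --- gates --------------------------------------------------------------
    def tmsd_k(gate: GateSpec, invader: str, toehold: int) -> float:
        k = toehold_rate(toehold, params)
        if gate.penalized(invader):
            k *= params.mismatch_penalty
        if invader in transcripts:
            k *= params.structure_penalty.get(invader, 1.0)
        return k

    def strand_tag(invader: str) -> dict[str, float]:
        """Conserved-entity content of an invader strand (DNA outputs only)."""
        return {} if invader in transcripts else {f"strand:{invader}": 1}

    for g in circuit.gates:
        if g.kind == "not_rna":
            # species already created as this template's transcript
            inv = g.invader_names[0]
            waste = b.add_species(f"{g.name}~waste:{inv}", "waste", 0.0, strand_tag(inv))
            b.add_reaction([inv, g.name], [waste], tmsd_k(g, inv, g.toehold_nt),
                           f"tmsd_not:{g.name}")
            continue

        if g.kind == "signal":
            b.add_species(
                g.name, "dna_gate", g.concentration,
                {f"fluor:{g.name}": 1, f"quench:{g.name}": 1},
            )
            fluor = b.add_species("F", "fluorophore_free", 0.0, {f"fluor:{g.name}": 1})
            for inv in g.invader_names:
                waste = b.add_species(
                    f"{g.name}~waste:{inv}", "waste", 0.0,
                    {f"quench:{g.name}": 1, **strand_tag(inv)},
                )
                b.add_reaction([inv, g.name], [fluor, waste],
                               tmsd_k(g, inv, g.toehold_nt), f"tmsd_signal:{g.name}:{inv}")
        elif g.kind == "threshold":
            b.add_species(g.name, "dna_gate", g.concentration, {f"scaffold:{g.name}": 1})
            inv = g.invader_names[0]
            waste = b.add_species(
                f"{g.name}~waste:{inv}", "waste", 0.0,
                {f"scaffold:{g.name}": 1, **strand_tag(inv)},
            )
            b.add_reaction([inv, g.name], [waste], tmsd_k(g, inv, g.toehold_nt),
                           f"tmsd_threshold:{g.name}")
        elif g.kind == "or_gate":
            out = g.output_name
            b.add_species(
                g.name, "dna_gate", g.concentration,
                {f"scaffold:{g.name}": 1, f"strand:{out}": 1},
            )
            b.add_species(out, "released_output", 0.0, {f"strand:{out}": 1})
            inv = g.invader_names[0]
            waste = b.add_species(
                f"{g.name}~waste:{inv}", "waste", 0.0,
                {f"scaffold:{g.name}": 1, **strand_tag(inv)},
            )
            b.add_reaction([inv, g.name], [out, waste], tmsd_k(g, inv, g.toehold_nt),
                           f"tmsd_or:{g.name}")
        elif g.kind == "and_gate":
            out = g.output_name
            inv1, inv2 = g.invader_names
            b.add_species(
                g.name, "dna_gate", g.concentration,
                {f"scaffold:{g.name}": 1, f"strand:{out}": 1},
            )
            b.add_species(out, "released_output", 0.0, {f"strand:{out}": 1})
            opened = b.add_species(
                f"{g.name}~open", "intermediate", 0.0,
                {f"scaffold:{g.name}": 1, f"strand:{out}": 1, **strand_tag(inv1)},
            )
            waste2 = b.add_species(
                f"{g.name}~waste:{inv2}", "waste", 0.0,
                {f"scaffold:{g.name}": 1, **strand_tag(inv1), **strand_tag(inv2)},
            )
            waste_leak = b.add_species(
                f"{g.name}~waste_leak", "waste", 0.0,
                {f"scaffold:{g.name}": 1, **strand_tag(inv1)},
            )
            b.add_reaction([inv1, g.name], [opened], tmsd_k(g, inv1, g.toehold_nt),
                           f"tmsd_and_open:{g.name}")
            b.add_reaction([opened], [inv1, g.name], params.k_rev_toehold_exchange,
                           f"tmsd_and_close:{g.name}")
            b.add_reaction([inv2, opened], [out, waste2],
                           tmsd_k(g, inv2, g.toehold2_nt), f"tmsd_and_fire:{g.name}")
            k_leak = params.clamp_leak0 * 10.0 ** (-params.clamp_decay_per_bp * g.clamp_bp)
            if k_leak > 0:
                b.add_reaction([inv1, g.name], [out, waste_leak], k_leak,
                               f"leak_and:{g.name}")
        else:  # pragma: no cover - unreachable after validation
            raise ValueError(f"unknown gate kind {g.kind!r}")

    return ReactionNetwork(
        circuit_name=circuit.name,
        condition=condition,
        species=list(b.species.values()),
        reactions=b.reactions,
    )


def conservation_vectors(net: ReactionNetwork) -> list[ConservedTotal]:
    """Conserved linear combinations implied by strand/protein/ligand identity.

    Covers each template DNA (free + aTF-bound), each aTF (free + ligand-bound
    + operator-bound), each ligand (free + stoichiometry-weighted complex),
    the fluorophore and quencher strands of the signal gate, each DNA gate
    scaffold across its states, and each released-output strand.  Every vector
    lies in the left null space of the stoichiometry matrix.
    """
    entities: dict[str, dict[str, float]] = {}
    for sp in net.species:
        for ent, w in sp.contains.items():
            entities.setdefault(ent, {})[sp.name] = w
    init = {s.name: s.initial_concentration for s in net.species}
    out = []
    for ent in sorted(entities):
        weights = entities[ent]
        value = sum(init[name] * w for name, w in weights.items())
        out.append(ConservedTotal(ent, weights, value))
    return out
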