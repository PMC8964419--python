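"""Declarative circuit descriptions for transcription-coupled strand-displacement reactions.

A circuit couples three layers in a single cell-free reaction:

* a **sensing layer** — allosteric transcription factors (aTFs such as TetR or
  SmtB) that repress T7 transcription of a DNA template until their cognate
  small-molecule ligand (anhydrotetracycline/tetracycline, zinc, ...) binds;
* an **information-processing layer** — single-stranded RNA invaders produced
  by transcription react with DNA/RNA gates by toehold-mediated strand
  displacement (TMSD): OR gates translate an invader into a shared output
  strand, AND gates require two invaders, RNA NOT gates sequester an invader,
  threshold gates silently consume it;
* an **output layer** — a fluorophore/quencher DNA signal gate whose quencher
  strand is displaced to produce fluorescence.

This module defines the declarative types for such circuits, validation,
YAML/JSON (de)serialization, input-condition enumeration, and a built-in
library of twelve two-ligand logic circuits covering seven Boolean functions
(NOT, OR, AND, NOR, IMPLY, NIMPLY, NAND) plus the single-sensor circuits used
for dose-response and analog-to-digital (ADC) work.

Units are normalized package-wide: concentrations in µM (template inputs are
accepted in nM and converted on parse), time in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import yaml

SCHEMA_VERSION = 1

GATE_KINDS = ("signal", "threshold", "or_gate", "and_gate", "not_rna")

#: The seven Boolean functions implemented by the packaged library, plus the
#: trivial single-input BUFFER used by plain sensor circuits.
LOGIC_LABELS = ("NOT", "OR", "AND", "NOR", "IMPLY", "NIMPLY", "NAND", "BUFFER")

#: Canonical ligand identifiers used by the packaged library.
TET = "tetracycline"
ZN = "zinc"
ATC = "aTc"


class CircuitError(ValueError):
    """Raised for an invalid circuit document. ``path`` locates the offending field."""

    def __init__(self, message: str, path: str = ""):
        self.path = path
        super().__init__(f"{path}: {message}" if path else message)


@dataclass(frozen=True)
class LigandInput:
    """A small-molecule input at a fixed concentration (µM) for one condition."""

    name: str
    concentration: float

    def __post_init__(self):
        if self.concentration < 0:
            raise CircuitError("ligand concentration must be >= 0", f"ligand[{self.name}]")


@dataclass(frozen=True)
class TranscriptionFactorSpec:
    """An allosteric transcription factor (aTF) repressing one operator.

    ``dimer_total`` is the total dimer concentration in µM.
    ``ligand_stoichiometry`` is the number of ligand molecules consumed per
    dimer in the lumped inactivation step (1 or 2); the packaged circuits use 1
    because a single bound ligand suffices to release the operator.
    """

    name: str
    operator_id: str
    dimer_total: float
    ligand_name: str
    ligand_stoichiometry: int = 2


@dataclass(frozen=True)
class TemplateSpec:
    """A double-stranded DNA transcription template.

    ``concentration`` is stored in µM (documents give templates in nM; the
    parser converts).  ``operator_id`` of ``None`` marks an unregulated
    template.  ``tx_efficiency_factor`` is a dimensionless multiplier on the
    transcription rate constant accommodating sequence-to-sequence variation in
    T7 RNA polymerase efficiency.
    """

    name: str
    transcript_name: str
    operator_id: str | None
    concentration: float
    tx_efficiency_factor: float = 1.0


@dataclass(frozen=True)
class GateSpec:
    """One strand-displacement gate.

    ``kind`` is one of :data:`GATE_KINDS`.  ``concentration`` is the initial
    duplex concentration in µM for DNA gates and ``None`` for ``not_rna``
    gates, which are transcribed in situ (a template's ``transcript_name`` must
    equal the gate name).  ``toehold_nt`` sets the displacement rate via the
    exponential toehold law; ``toehold2_nt`` is the toehold revealed for the
    second invader of an AND gate.  ``clamp_bp`` (AND only) is the clamp length
    suppressing single-invader leak.  ``has_mismatch_driver`` marks every
    invader→gate reaction of this gate as crossing a deliberate mismatch
    (slowed by the mismatch penalty); ``mismatch_invaders`` restricts the
    penalty to the named invaders.
    """

    name: str
    kind: str
    invader_names: tuple[str, ...]
    toehold_nt: int
    concentration: float | None = None
    clamp_bp: int = 0
    toehold2_nt: int = 3
    has_mismatch_driver: bool = False
    mismatch_invaders: tuple[str, ...] = ()
    output_name: str | None = None

    def penalized(self, invader: str) -> bool:
        """Whether the reaction of ``invader`` with this gate crosses a mismatch."""
        return self.has_mismatch_driver or invader in self.mismatch_invaders


@dataclass(frozen=True)
class CircuitSpec:
    """A complete declarative circuit: templates, aTFs, gates and ligand inputs."""

    name: str
    templates: tuple[TemplateSpec, ...]
    tfs: tuple[TranscriptionFactorSpec, ...]
    gates: tuple[GateSpec, ...]
    ligand_names: tuple[str, ...]
    intended_logic: str | None = None

    def tf_for_operator(self, operator_id: str) -> TranscriptionFactorSpec:
        matches = [tf for tf in self.tfs if tf.operator_id == operator_id]
        if len(matches) != 1:
            raise CircuitError(
                f"operator {operator_id!r} bound by {len(matches)} aTFs", self.name
            )
        return matches[0]

    def signal_gate(self) -> GateSpec:
        sig = [g for g in self.gates if g.kind == "signal"]
        if len(sig) != 1:
            raise CircuitError(f"expected exactly 1 signal gate, found {len(sig)}", self.name)
        return sig[0]


# ---------------------------------------------------------------------------
# validation


def validate(circuit: CircuitSpec) -> list[str]:
    """Return a list of diagnostics (empty for a valid circuit).

    Checks cross-references, sign constraints, gate arities, the
    one-aTF-per-operator rule, unique production of every strand, and
    acyclicity of the gate dependency graph terminating at one signal gate.
    """
    diags: list[str] = []
    c = circuit

    def bad(path: str, msg: str):
        diags.append(f"{path}: {msg}")

    seen = set()
    for i, t in enumerate(c.templates):
        p = f"templates[{i}]({t.name})"
        if t.name in seen:
            bad(p, "duplicate template name")
        seen.add(t.name)
        if t.concentration < 0:
            bad(p, "negative concentration")
        if t.tx_efficiency_factor <= 0:
            bad(p, "tx_efficiency_factor must be > 0")

    operators: dict[str, int] = {}
    for i, tf in enumerate(c.tfs):
        p = f"tfs[{i}]({tf.name})"
        operators[tf.operator_id] = operators.get(tf.operator_id, 0) + 1
        if tf.dimer_total < 0:
            bad(p, "negative dimer_total")
        if tf.ligand_stoichiometry not in (1, 2):
            bad(p, "ligand_stoichiometry must be 1 or 2")
        if tf.ligand_name not in c.ligand_names:
            bad(p, f"ligand {tf.ligand_name!r} not among circuit ligands")
    for op, n in operators.items():
        if n > 1:
            bad("tfs", f"operator {op!r} bound by {n} aTFs")
    for i, t in enumerate(c.templates):
        if t.operator_id is not None and t.operator_id not in operators:
            bad(f"templates[{i}]({t.name})", f"dangling operator reference {t.operator_id!r}")

    # strand producers: transcripts and gate outputs
    producers: dict[str, list[str]] = {}
    for t in c.templates:
        producers.setdefault(t.transcript_name, []).append(f"template {t.name}")
    for g in c.gates:
        if g.output_name is not None:
            producers.setdefault(g.output_name, []).append(f"gate {g.name}")
    or_gate_names = {g.name for g in c.gates if g.kind == "or_gate"}
    for strand, made_by in producers.items():
        # OR gates may share an output strand (that is how OR logic converges);
        # any other multiple production is a wiring error.
        all_or = all(
            m.startswith("gate ") and m[len("gate "):] in or_gate_names for m in made_by
        )
        if len(made_by) > 1 and not all_or:
            bad("circuit", f"strand {strand!r} produced by more than one element: {made_by}")

    gate_names = set()
    n_signal = 0
    for i, g in enumerate(c.gates):
        p = f"gates[{i}]({g.name})"
        if g.name in gate_names:
            bad(p, "duplicate gate name")
        gate_names.add(g.name)
        if g.kind not in GATE_KINDS:
            bad(p, f"unknown gate kind {g.kind!r}")
            continue
        if g.toehold_nt < 1:
            bad(p, "toehold_nt must be >= 1")
        if g.clamp_bp < 0:
            bad(p, "clamp_bp must be >= 0")
        if g.kind == "signal":
            n_signal += 1
            if not 1 <= len(g.invader_names) <= 2:
                bad(p, "signal gate takes 1 or 2 invaders")
        elif g.kind == "and_gate":
            if len(g.invader_names) != 2:
                bad(p, "and_gate takes exactly 2 invaders")
            if g.output_name is None:
                bad(p, "and_gate requires an output strand")
        elif g.kind == "or_gate":
            if len(g.invader_names) != 1:
                bad(p, "or_gate takes exactly 1 invader")
            if g.output_name is None:
                bad(p, "or_gate requires an output strand")
        else:  # threshold, not_rna
            if len(g.invader_names) != 1:
                bad(p, f"{g.kind} takes exactly 1 invader")
        if g.kind == "not_rna":
            if g.concentration is not None:
                bad(p, "not_rna gates are transcribed in situ; concentration must be omitted")
            if g.name not in producers:
                bad(p, "not_rna gate is not produced by any template")
        else:
            if g.concentration is None or g.concentration < 0:
                bad(p, "DNA gates need a concentration >= 0")
        for inv in g.invader_names:
            if inv not in producers:
                bad(p, f"dangling invader reference {inv!r}")
        for inv in g.mismatch_invaders:
            if inv not in g.invader_names:
                bad(p, f"mismatch_invaders entry {inv!r} is not an invader of this gate")
    if n_signal != 1:
        bad("gates", f"expected exactly 1 signal gate, found {n_signal}")

    # acyclicity of strand flow: strand -> consuming gate -> output strand
    produced_by_gate = {g.output_name: g.name for g in c.gates if g.output_name}
    edges: dict[str, set[str]] = {g.name: set() for g in c.gates}
    for g in c.gates:
        for inv in g.invader_names:
            src = produced_by_gate.get(inv)
            if src is not None:
                edges[g.name].add(src)  # g depends on src
    state: dict[str, int] = {}

    def cyclic(n: str) -> bool:
        state[n] = 1
        for m in edges[n]:
            s = state.get(m, 0)
            if s == 1 or (s == 0 and cyclic(m)):
                return True
        state[n] = 2
        return False

    for g in c.gates:
        if state.get(g.name, 0) == 0 and cyclic(g.name):
            bad("gates", "gate dependency graph contains a cycle")
            break

    return diags


def validate_or_raise(circuit: CircuitSpec) -> CircuitSpec:
    diags = validate(circuit)
    if diags:
        raise CircuitError("; ".join(diags), circuit.name)
    return circuit


# ---------------------------------------------------------------------------
# (de)serialization


def _gate_to_doc(g: GateSpec) -> dict:
    doc: dict = {
        "name": g.name,
        "kind": g.kind,
        "invaders": list(g.invader_names),
        "toehold_nt": g.toehold_nt,
    }
    if g.kind != "not_rna":
        doc["concentration_uM"] = g.concentration
    if g.kind == "and_gate":
        doc["toehold2_nt"] = g.toehold2_nt
        doc["clamp_bp"] = g.clamp_bp
    if g.output_name is not None:
        doc["output"] = g.output_name
    if g.has_mismatch_driver:
        doc["has_mismatch_driver"] = True
    if g.mismatch_invaders:
        doc["mismatch_invaders"] = list(g.mismatch_invaders)
    return doc


def to_document(circuit: CircuitSpec) -> dict:
    """Plain-dict form of a circuit (canonical JSON schema, templates in nM)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "name": circuit.name,
        "intended_logic": circuit.intended_logic,
        "ligands": list(circuit.ligand_names),
        "tfs": [
            {
                "name": tf.name,
                "operator": tf.operator_id,
                "dimer_total_uM": tf.dimer_total,
                "ligand": tf.ligand_name,
                "ligand_stoichiometry": tf.ligand_stoichiometry,
            }
            for tf in circuit.tfs
        ],
        "templates": [
            {
                "name": t.name,
                "transcript": t.transcript_name,
                "operator": t.operator_id,
                "concentration_uM": t.concentration,
                "tx_efficiency_factor": t.tx_efficiency_factor,
            }
            for t in circuit.templates
        ],
        "gates": [_gate_to_doc(g) for g in circuit.gates],
    }


def serialize_circuit(circuit: CircuitSpec) -> str:
    """Canonical JSON serialization."""
    return json.dumps(to_document(circuit), indent=2)


def _req(doc: Mapping, key: str, path: str):
    if key not in doc:
        raise CircuitError(f"missing required key {key!r}", path)
    return doc[key]


def from_document(doc: Mapping) -> CircuitSpec:
    """Build and validate a :class:`CircuitSpec` from a plain mapping."""
    if not isinstance(doc, Mapping):
        raise CircuitError("circuit document must be a mapping")
    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise CircuitError(f"unsupported schema_version {version}", "schema_version")

    tfs = []
    for i, d in enumerate(doc.get("tfs", []) or []):
        p = f"tfs[{i}]"
        tfs.append(
            TranscriptionFactorSpec(
                name=_req(d, "name", p),
                operator_id=_req(d, "operator", p),
                dimer_total=float(_req(d, "dimer_total_uM", p)),
                ligand_name=_req(d, "ligand", p),
                ligand_stoichiometry=int(d.get("ligand_stoichiometry", 2)),
            )
        )
    templates = []
    for i, d in enumerate(doc.get("templates", []) or []):
        p = f"templates[{i}]"
        if "concentration_nM" in d:
            conc = float(d["concentration_nM"]) * 1e-3
        elif "concentration_uM" in d:
            conc = float(d["concentration_uM"])
        else:
            raise CircuitError("missing concentration_nM (or concentration_uM)", p)
        if conc < 0:
            raise CircuitError("negative concentration", p)
        templates.append(
            TemplateSpec(
                name=_req(d, "name", p),
                transcript_name=_req(d, "transcript", p),
                operator_id=d.get("operator"),
                concentration=conc,
                tx_efficiency_factor=float(d.get("tx_efficiency_factor", 1.0)),
            )
        )
    gates = []
    for i, d in enumerate(doc.get("gates", []) or []):
        p = f"gates[{i}]"
        kind = _req(d, "kind", p)
        if kind not in GATE_KINDS:
            raise CircuitError(f"unknown gate kind {kind!r}", p)
        conc = d.get("concentration_uM")
        if conc is not None:
            conc = float(conc)
            if conc < 0:
                raise CircuitError("negative concentration", p)
        gates.append(
            GateSpec(
                name=_req(d, "name", p),
                kind=kind,
                invader_names=tuple(_req(d, "invaders", p)),
                toehold_nt=int(_req(d, "toehold_nt", p)),
                concentration=conc,
                clamp_bp=int(d.get("clamp_bp", 0)),
                toehold2_nt=int(d.get("toehold2_nt", 3)),
                has_mismatch_driver=bool(d.get("has_mismatch_driver", False)),
                mismatch_invaders=tuple(d.get("mismatch_invaders", ())),
                output_name=d.get("output"),
            )
        )
    circuit = CircuitSpec(
        name=_req(doc, "name", "circuit"),
        templates=tuple(templates),
        tfs=tuple(tfs),
        gates=tuple(gates),
        ligand_names=tuple(doc.get("ligands", ()) or ()),
        intended_logic=doc.get("intended_logic"),
    )
    return validate_or_raise(circuit)


def parse_circuit(config_text: str) -> CircuitSpec:
    """Parse a YAML (or JSON, a YAML subset) circuit document and validate it."""
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:  # pragma: no cover - syntax error path
        raise CircuitError(f"unparseable circuit document: {exc}") from exc
    return from_document(doc)


# ---------------------------------------------------------------------------
# input conditions


def enumerate_conditions(
    circuit: CircuitSpec, on_level: float = 10.0
) -> list[dict[str, float]]:
    """All 2**n ligand conditions of a circuit in canonical binary order.

    Each condition maps every circuit ligand to 0 or ``on_level`` µM; the last
    ligand toggles fastest, so two ligands enumerate as
    (0,0), (0,on), (on,0), (on,on).
    """
    if on_level <= 0:
        raise ValueError("on_level must be > 0")
    n = len(circuit.ligand_names)
    conditions = []
    for mask in range(2**n):
        cond = {}
        for j, lig in enumerate(circuit.ligand_names):
            bit = (mask >> (n - 1 - j)) & 1
            cond[lig] = on_level if bit else 0.0
        conditions.append(cond)
    return conditions


def truth_value(label: str, inputs: Sequence[bool]) -> bool:
    """Boolean value of a logic label on ordered inputs.

    IMPLY and NIMPLY are directional and read the circuit's ligand order:
    ``IMPLY`` on (A, B) is ¬A ∨ B; ``NIMPLY`` is A ∧ ¬B.
    """
    a = list(bool(x) for x in inputs)
    if label == "BUFFER":
        (x,) = a
        return x
    if label == "NOT":
        (x,) = a
        return not x
    if label == "OR":
        return any(a)
    if label == "AND":
        return all(a)
    if label == "NOR":
        return not any(a)
    if label == "NAND":
        return not all(a)
    if label == "IMPLY":
        x, y = a
        return (not x) or y
    if label == "NIMPLY":
        x, y = a
        return x and not y
    raise ValueError(f"unknown logic label {label!r}")


# ---------------------------------------------------------------------------
# packaged circuit library
#
# Working concentrations follow the calibrated defaults of the package: 50 nM
# for regulated sensor templates, 5 µM signal/OR/AND gates, 5 µM TetR dimer and
# 1 µM SmtB dimer.  Unregulated invader templates run at 10 nM so that an RNA
# NOT gate transcribed at 100-300 nM can outpace and sequester their invader;
# NOT-gate templates are overexpressed relative to their target invader
# template for the same reason.

SENSOR_TEMPLATE_NM = 50.0
UNREG_TEMPLATE_NM = 10.0
NOT_TEMPLATE_TET_NM = 100.0
NOT_TEMPLATE_ZN_NM = 300.0
GATE_UM = 5.0
TETR_DIMER_UM = 5.0
SMTB_DIMER_UM = 1.0

SIGNAL_TOEHOLD_NT = 8  #: toehold of the standard fluorophore/quencher gate
ADC_SIGNAL_TOEHOLD_NT = 4  #: slowed signal gate used with threshold gates
THRESHOLD_TOEHOLD_NT = 8
OR_TOEHOLD_NT = 8
NOT_TOEHOLD_NT = 8
AND_TOEHOLD_NT = 5
AND_TOEHOLD2_NT = 3
AND_CLAMP_BP = 7


def _tetr(stoich: int = 1) -> TranscriptionFactorSpec:
    return TranscriptionFactorSpec("TetR", "tetO", TETR_DIMER_UM, TET, stoich)


def _tetr_atc(stoich: int = 1) -> TranscriptionFactorSpec:
    return TranscriptionFactorSpec("TetR", "tetO", TETR_DIMER_UM, ATC, stoich)


def _smtb(stoich: int = 1) -> TranscriptionFactorSpec:
    return TranscriptionFactorSpec("SmtB", "smtO", SMTB_DIMER_UM, ZN, stoich)


def _template(name, transcript, operator, n_m, eff=1.0) -> TemplateSpec:
    return TemplateSpec(name, transcript, operator, n_m * 1e-3, eff)


def _signal(invaders, toehold=SIGNAL_TOEHOLD_NT, mismatch=(), conc=GATE_UM) -> GateSpec:
    return GateSpec(
        "signal",
        "signal",
        tuple(invaders),
        toehold,
        concentration=conc,
        mismatch_invaders=tuple(mismatch),
    )


def tetr_sensor(ligand: str = ATC, signal_toehold: int = SIGNAL_TOEHOLD_NT) -> CircuitSpec:
    """TetR-regulated single-sensor circuit (50 nM template, 5 µM dimer, 5 µM gate)."""
    tf = _tetr() if ligand == TET else _tetr_atc()
    return validate_or_raise(
        CircuitSpec(
            name="tetr_sensor",
            templates=(_template("T_tet", "InvadeR_tet", "tetO", SENSOR_TEMPLATE_NM),),
            tfs=(tf,),
            gates=(_signal(["InvadeR_tet"], toehold=signal_toehold),),
            ligand_names=(ligand,),
            intended_logic="BUFFER",
        )
    )


def zinc_sensor(signal_toehold: int = ADC_SIGNAL_TOEHOLD_NT) -> CircuitSpec:
    """SmtB-regulated zinc sensor with the slowed (4-nt toehold) signal gate.

    This is the base circuit of the kinetic comparator and the ADC tube strip;
    threshold gates are added per tube by the designer.
    """
    return validate_or_raise(
        CircuitSpec(
            name="zinc_sensor",
            templates=(_template("T_zn", "InvadeR_zn", "smtO", SENSOR_TEMPLATE_NM),),
            tfs=(_smtb(),),
            gates=(_signal(["InvadeR_zn"], toehold=signal_toehold),),
            ligand_names=(ZN,),
            intended_logic="BUFFER",
        )
    )


def unregulated_sensor(template_nM: float = UNREG_TEMPLATE_NM) -> CircuitSpec:
    """Constitutive invader template plus signal gate — no aTF layer."""
    return validate_or_raise(
        CircuitSpec(
            name="unregulated_sensor",
            templates=(_template("T_u", "InvadeR_u", None, template_nM),),
            tfs=(),
            gates=(_signal(["InvadeR_u"]),),
            ligand_names=(),
            intended_logic=None,
        )
    )


def _not_gate_tet() -> tuple[TemplateSpec, GateSpec]:
    """TetR-regulated RNA NOT gate sequestering the unregulated invader."""
    t = _template("T_not_tet", "NOTg_tet", "tetO", NOT_TEMPLATE_TET_NM)
    g = GateSpec("NOTg_tet", "not_rna", ("InvadeR_u",), NOT_TOEHOLD_NT)
    return t, g


def _not_gate_zn(invader: str = "InvadeR_u") -> tuple[TemplateSpec, GateSpec]:
    t = _template("T_not_zn", "NOTg_zn", "smtO", NOT_TEMPLATE_ZN_NM)
    g = GateSpec("NOTg_zn", "not_rna", (invader,), NOT_TOEHOLD_NT)
    return t, g


def _build_library() -> dict[str, CircuitSpec]:
    lib: dict[str, CircuitSpec] = {}

    def add(c: CircuitSpec):
        lib[c.name] = validate_or_raise(c)

    u10 = _template("T_u", "InvadeR_u", None, UNREG_TEMPLATE_NM)
    t_tet = _template("T_tet", "InvadeR_tet", "tetO", SENSOR_TEMPLATE_NM)
    t_zn = _template("T_zn", "InvadeR_zn", "smtO", SENSOR_TEMPLATE_NM)

    # -- NOT(tet): unregulated invader, TetR-driven RNA NOT gate.  The invader
    # carries a deliberate mismatch against the signal gate so sequestration
    # wins the kinetic competition.
    nt_t, nt_g = _not_gate_tet()
    add(
        CircuitSpec(
            "NOT_tet",
            templates=(u10, nt_t),
            tfs=(_tetr(),),
            gates=(nt_g, _signal(["InvadeR_u"], mismatch=["InvadeR_u"])),
            ligand_names=(TET,),
            intended_logic="NOT",
        )
    )

    nz_t, nz_g = _not_gate_zn()
    add(
        CircuitSpec(
            "NOT_zn",
            templates=(u10, nz_t),
            tfs=(_smtb(),),
            gates=(nz_g, _signal(["InvadeR_u"], mismatch=["InvadeR_u"])),
            ligand_names=(ZN,),
            intended_logic="NOT",
        )
    )

    # -- OR: each ligand-induced invader feeds its own DNA OR gate; both OR
    # gates release the same output strand, which invades the signal gate.
    or_tet = GateSpec("OR_tet", "or_gate", ("InvadeR_tet",), OR_TOEHOLD_NT,
                      concentration=GATE_UM, output_name="Out")
    or_zn = GateSpec("OR_zn", "or_gate", ("InvadeR_zn",), OR_TOEHOLD_NT,
                     concentration=GATE_UM, output_name="Out")
    add(
        CircuitSpec(
            "OR",
            templates=(t_tet, t_zn),
            tfs=(_tetr(), _smtb()),
            gates=(or_tet, or_zn, _signal(["Out"])),
            ligand_names=(TET, ZN),
            intended_logic="OR",
        )
    )

    # -- AND: a two-invader DNA gate; the first invader opens the gate by
    # reversible toehold exchange, the second releases the output.  A 7-bp
    # clamp suppresses single-invader leak.
    and_g = GateSpec(
        "AND_g", "and_gate", ("InvadeR_tet", "InvadeR_zn"), AND_TOEHOLD_NT,
        concentration=GATE_UM, clamp_bp=AND_CLAMP_BP, toehold2_nt=AND_TOEHOLD2_NT,
        output_name="Out",
    )
    add(
        CircuitSpec(
            "AND",
            templates=(t_tet, t_zn),
            tfs=(_tetr(), _smtb()),
            gates=(and_g, _signal(["Out"])),
            ligand_names=(TET, ZN),
            intended_logic="AND",
        )
    )

    # -- NOR: two RNA NOT gates sequestering one shared unregulated invader.
    add(
        CircuitSpec(
            "NOR",
            templates=(u10, nt_t, nz_t),
            tfs=(_tetr(), _smtb()),
            gates=(nt_g, nz_g, _signal(["InvadeR_u"], mismatch=["InvadeR_u"])),
            ligand_names=(TET, ZN),
            intended_logic="NOR",
        )
    )

    # -- NAND = NOT A OR NOT B: two unregulated invaders, each with its own OR
    # gate and its own regulated RNA NOT gate.  The OR-gate path carries the
    # mismatch so each NOT gate preferentially captures its invader.
    u1 = _template("T_u1", "InvadeR_u1", None, UNREG_TEMPLATE_NM)
    u2 = _template("T_u2", "InvadeR_u2", None, UNREG_TEMPLATE_NM)
    nand_not_tet_t = _template("T_not_tet", "NOTg_tet", "tetO", NOT_TEMPLATE_TET_NM)
    nand_not_tet_g = GateSpec("NOTg_tet", "not_rna", ("InvadeR_u1",), NOT_TOEHOLD_NT)
    nand_not_zn_t = _template("T_not_zn", "NOTg_zn", "smtO", NOT_TEMPLATE_ZN_NM)
    nand_not_zn_g = GateSpec("NOTg_zn", "not_rna", ("InvadeR_u2",), NOT_TOEHOLD_NT)
    nand_or1 = GateSpec("OR_1", "or_gate", ("InvadeR_u1",), OR_TOEHOLD_NT,
                        concentration=GATE_UM, output_name="Out",
                        has_mismatch_driver=True)
    nand_or2 = GateSpec("OR_2", "or_gate", ("InvadeR_u2",), OR_TOEHOLD_NT,
                        concentration=GATE_UM, output_name="Out",
                        has_mismatch_driver=True)
    add(
        CircuitSpec(
            "NAND",
            templates=(u1, u2, nand_not_tet_t, nand_not_zn_t),
            tfs=(_tetr(), _smtb()),
            gates=(nand_not_tet_g, nand_not_zn_g, nand_or1, nand_or2, _signal(["Out"])),
            ligand_names=(TET, ZN),
            intended_logic="NAND",
        )
    )

    # -- IMPLY A→B (¬A ∨ B): an unregulated invader reaches the signal gate
    # directly (across a mismatch) and is sequestered by the A-regulated NOT
    # gate; the B-induced invader passes through an OR gate whose output has no
    # mismatch with the signal gate.
    def imply(name, lig_a, lig_b, with_or: bool) -> CircuitSpec:
        if lig_a == ZN:
            not_t, not_g = _not_gate_zn()
            tf_a = _smtb()
        else:
            not_t, not_g = _not_gate_tet()
            tf_a = _tetr()
        if lig_b == TET:
            t_b = t_tet
            tf_b = _tetr()
            inv_b = "InvadeR_tet"
        else:
            t_b = t_zn
            tf_b = _smtb()
            inv_b = "InvadeR_zn"
        gates: list[GateSpec] = [not_g]
        if with_or:
            gates.append(
                GateSpec("OR_b", "or_gate", (inv_b,), OR_TOEHOLD_NT,
                         concentration=GATE_UM, output_name="Out")
            )
            gates.append(_signal(["InvadeR_u", "Out"], mismatch=["InvadeR_u"]))
        else:
            gates.append(_signal(["InvadeR_u", inv_b], mismatch=["InvadeR_u", inv_b]))
        return CircuitSpec(
            name,
            templates=(u10, not_t, t_b),
            tfs=(tf_a, tf_b),
            gates=tuple(gates),
            ligand_names=(lig_a, lig_b),
            intended_logic="IMPLY",
        )

    add(imply("IMPLY_zn_tet", ZN, TET, with_or=True))
    add(imply("IMPLY_tet_zn", TET, ZN, with_or=True))
    add(imply("IMPLY_zn_tet_no_or", ZN, TET, with_or=False))
    add(imply("IMPLY_tet_zn_no_or", TET, ZN, with_or=False))

    # -- NIMPLY A∧¬B: an AND gate pairs the A-induced invader with an
    # unregulated invader that the B-regulated NOT gate sequesters.
    def nimply(name, lig_a, lig_b) -> CircuitSpec:
        if lig_b == ZN:
            not_t, not_g = _not_gate_zn()
            tf_b = _smtb()
        else:
            not_t, not_g = _not_gate_tet()
            tf_b = _tetr()
        if lig_a == TET:
            t_a = t_tet
            tf_a = _tetr()
            inv_a = "InvadeR_tet"
        else:
            t_a = t_zn
            tf_a = _smtb()
            inv_a = "InvadeR_zn"
        gate = GateSpec(
            "AND_g", "and_gate", ("InvadeR_u", inv_a), AND_TOEHOLD_NT,
            concentration=GATE_UM, clamp_bp=AND_CLAMP_BP, toehold2_nt=AND_TOEHOLD2_NT,
            output_name="Out",
        )
        return CircuitSpec(
            name,
            templates=(u10, not_t, t_a),
            tfs=(tf_a, tf_b),
            gates=(not_g, gate, _signal(["Out"])),
            ligand_names=(lig_a, lig_b),
            intended_logic="NIMPLY",
        )

    add(nimply("NIMPLY_zn_tet", ZN, TET))
    add(nimply("NIMPLY_tet_zn", TET, ZN))

    return lib


_LIBRARY = _build_library()

LIBRARY_NAMES: tuple[str, ...] = tuple(_LIBRARY)


def library_circuit(name: str) -> CircuitSpec:
    """One of the twelve packaged logic circuits, by name.

    Raises ``KeyError`` listing the available names for an unknown name.
    """
    try:
        return _LIBRARY[name]
    except KeyError:
        raise KeyError(
            f"unknown circuit {name!r}; available: {', '.join(LIBRARY_NAMES)}"
        ) from None
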