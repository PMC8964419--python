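"""Circuit document parsing, validation, serialization and the packaged library."""

import pytest

from strandlogic import circuit_spec as cs

MINIMAL_SENSOR_YAML = """
schema_version: 1
name: minimal
ligands: []
templates:
  - {name: T_u, transcript: InvadeR, concentration_nM: 50}
gates:
  - {name: signal, kind: signal, invaders: [InvadeR], toehold_nt: 8, concentration_uM: 5}
"""

AND_YAML = """
schema_version: 1
name: and_demo
intended_logic: AND
ligands: [tetracycline, zinc]
tfs:
  - {name: TetR, operator: tetO, dimer_total_uM: 5, ligand: tetracycline, ligand_stoichiometry: 1}
  - {name: SmtB, operator: smtO, dimer_total_uM: 1, ligand: zinc, ligand_stoichiometry: 1}
templates:
  - {name: T_tet, transcript: InvadeR_tet, operator: tetO, concentration_nM: 50}
  - {name: T_zn, transcript: InvadeR_zn, operator: smtO, concentration_nM: 50}
gates:
  - {name: AND_g, kind: and_gate, invaders: [InvadeR_tet, InvadeR_zn], toehold_nt: 5,
     toehold2_nt: 3, clamp_bp: 7, concentration_uM: 5, output: Out}
  - {name: signal, kind: signal, invaders: [Out], toehold_nt: 8, concentration_uM: 5}
"""


class TestParsing:
    def test_minimal_unregulated_sensor(self):
        c = cs.parse_circuit(MINIMAL_SENSOR_YAML)
        assert c.tfs == ()
        assert len(c.templates) == 1
        assert c.templates[0].concentration == pytest.approx(0.05)  # nM -> µM
        assert c.signal_gate().invader_names == ("InvadeR",)

    def test_two_ligand_and_document(self):
        c = cs.parse_circuit(AND_YAML)
        assert len(c.tfs) == 2
        kinds = sorted(g.kind for g in c.gates)
        assert kinds == ["and_gate", "signal"]
        assert c.intended_logic == "AND"

    def test_dangling_invader_reference_names_it(self):
        bad = MINIMAL_SENSOR_YAML.replace("invaders: [InvadeR]", "invaders: [ghost]")
        with pytest.raises(cs.CircuitError, match="ghost"):
            cs.parse_circuit(bad)

    def test_unknown_gate_kind(self):
        bad = MINIMAL_SENSOR_YAML.replace("kind: signal", "kind: xor_gate")
        with pytest.raises(cs.CircuitError, match="xor_gate"):
            cs.parse_circuit(bad)

    def test_negative_concentration(self):
        bad = MINIMAL_SENSOR_YAML.replace("concentration_nM: 50", "concentration_nM: -1")
        with pytest.raises(cs.CircuitError, match="negative"):
            cs.parse_circuit(bad)

    def test_operator_without_tf_is_dangling(self):
        bad = MINIMAL_SENSOR_YAML.replace(
            "transcript: InvadeR, concentration_nM: 50",
            "transcript: InvadeR, operator: tetO, concentration_nM: 50",
        )
        with pytest.raises(cs.CircuitError, match="tetO"):
            cs.parse_circuit(bad)


class TestLibrary:
    def test_twelve_circuits_seven_logic_functions(self):
        assert len(cs.LIBRARY_NAMES) == 12
        labels = {cs.library_circuit(n).intended_logic for n in cs.LIBRARY_NAMES}
        assert labels == {"NOT", "OR", "AND", "NOR", "IMPLY", "NIMPLY", "NAND"}

    def test_unknown_name_lists_available(self):
        with pytest.raises(KeyError, match="NOR"):
            cs.library_circuit("XOR")

    @pytest.mark.parametrize("name", cs.LIBRARY_NAMES)
    def test_library_validates_clean_and_round_trips(self, name):
        c = cs.library_circuit(name)
        assert cs.validate(c) == []
        assert cs.parse_circuit(cs.serialize_circuit(c)) == c

    def test_nor_structure(self):
        c = cs.library_circuit("NOR")
        nots = [g for g in c.gates if g.kind == "not_rna"]
        assert len(nots) == 2
        # both NOT gates sequester the same unregulated invader
        assert {g.invader_names[0] for g in nots} == {"InvadeR_u"}
        unreg = [t for t in c.templates if t.operator_id is None]
        assert len(unreg) == 1 and unreg[0].transcript_name == "InvadeR_u"

    def test_nand_structure(self):
        c = cs.library_circuit("NAND")
        assert len(c.templates) == 4
        assert sum(t.operator_id is None for t in c.templates) == 2
        assert sum(g.kind == "or_gate" for g in c.gates) == 2
        assert sum(g.kind == "not_rna" for g in c.gates) == 2

    def test_imply_directionality(self):
        a = cs.library_circuit("IMPLY_zn_tet")
        b = cs.library_circuit("IMPLY_tet_zn")
        assert a.ligand_names == (cs.ZN, cs.TET)
        assert b.ligand_names == (cs.TET, cs.ZN)
        assert a.intended_logic == b.intended_logic == "IMPLY"


class TestConditions:
    def test_two_ligand_enumeration_order(self):
        c = cs.library_circuit("AND")
        conds = cs.enumerate_conditions(c, on_level=10.0)
        as_bits = [tuple(int(v > 0) for v in cond.values()) for cond in conds]
        assert as_bits == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_single_and_zero_ligand_counts(self):
        assert len(cs.enumerate_conditions(cs.library_circuit("NOT_tet"))) == 2
        assert len(cs.enumerate_conditions(cs.unregulated_sensor())) == 1

    def test_on_level_must_be_positive(self):
        with pytest.raises(ValueError):
            cs.enumerate_conditions(cs.library_circuit("AND"), on_level=0.0)


class TestTruthValues:
    @pytest.mark.parametrize(
        "label,table",
        [
            ("OR", {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 1}),
            ("AND", {(0, 0): 0, (0, 1): 0, (1, 0): 0, (1, 1): 1}),
            ("NOR", {(0, 0): 1, (0, 1): 0, (1, 0): 0, (1, 1): 0}),
            ("NAND", {(0, 0): 1, (0, 1): 1, (1, 0): 1, (1, 1): 0}),
            ("IMPLY", {(0, 0): 1, (0, 1): 1, (1, 0): 0, (1, 1): 1}),
            ("NIMPLY", {(0, 0): 0, (0, 1): 0, (1, 0): 1, (1, 1): 0}),
        ],
    )
    def test_two_input_tables(self, label, table):
        for bits, want in table.items():
            assert cs.truth_value(label, bits) is bool(want)

    def test_not_and_buffer(self):
        assert cs.truth_value("NOT", (0,)) and not cs.truth_value("NOT", (1,))
        assert cs.truth_value("BUFFER", (1,)) and not cs.truth_value("BUFFER", (0,))
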