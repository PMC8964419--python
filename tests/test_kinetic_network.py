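"""Network compilation: toehold law, reaction emission, conservation structure."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from strandlogic import circuit_spec as cs
from strandlogic.kinetic_network import (
    KineticParams,
    compile_network,
    conservation_vectors,
    toehold_rate,
)
from strandlogic.ode_engine import SolverSettings, default_grid, simulate


class TestToeholdRate:
    def test_saturates_at_n_sat(self, params):
        assert toehold_rate(params.n_sat, params) == params.k_tmsd_max
        assert toehold_rate(params.n_sat + 4, params) == params.k_tmsd_max

    def test_two_decades_between_8_and_4_nt(self, params):
        assert toehold_rate(8, params) / toehold_rate(4, params) == pytest.approx(100.0)

    def test_degenerate_law_is_flat(self):
        p = KineticParams(decade_per_nt=0.0)
        assert toehold_rate(4, p) == p.k_tmsd_max

    def test_rejects_sub_single_nt(self, params):
        with pytest.raises(ValueError):
            toehold_rate(0, params)

    @hyp_settings(max_examples=50, derandomize=True)
    @given(
        n=st.integers(1, 14),
        decade=st.floats(0.0, 3.0, allow_nan=False),
        n_sat=st.integers(1, 10),
    )
    def test_monotone_non_decreasing(self, n, decade, n_sat):
        p = KineticParams(decade_per_nt=decade, n_sat=n_sat)
        assert toehold_rate(n + 1, p) >= toehold_rate(n, p)


def left_null_residual(net) -> float:
    n_mat = net.stoichiometry_matrix()
    idx = net.index()
    worst = 0.0
    for cons in conservation_vectors(net):
        w = np.zeros(len(net.species))
        for name, weight in cons.weights.items():
            w[idx[name]] = weight
        worst = max(worst, float(np.max(np.abs(w @ n_mat))))
    return worst


class TestCompile:
    def test_minimal_sensor_two_reactions(self, params):
        net = compile_network(cs.unregulated_sensor(), params)
        assert len(net.reactions) == 2
        labels = {r.label.split(":")[0] for r in net.reactions}
        assert labels == {"tx", "tmsd_signal"}
        cons_labels = {c.label for c in conservation_vectors(net)}
        assert "fluor:signal" in cons_labels
        assert "dna:T_u" in cons_labels

    def test_repressed_tetr_sensor_keeps_template_bound(self, params):
        """At 0 ligand, sub-nM operator affinity and 5 µM TetR leave >=99% of
        the template in the aTF-bound state once binding equilibrates."""
        c = cs.tetr_sensor()
        net = compile_network(c, params, {cs.ATC: 0.0})
        res = simulate(net, SolverSettings(rtol=1e-9, atol=1e-12, t_grid=default_grid(30)))
        free = res.trace("T_tet")[-1]
        total = c.templates[0].concentration
        assert free / total < 0.01

    def test_and_gate_reversible_step_and_leak(self, params):
        net = compile_network(cs.library_circuit("AND"), params)
        labels = [r.label for r in net.reactions]
        assert labels.count("tmsd_and_open:AND_g") == 1
        assert labels.count("tmsd_and_close:AND_g") == 1
        assert labels.count("leak_and:AND_g") == 1

    def test_zero_clamp_leak_removes_leak_reaction(self):
        p = KineticParams(clamp_leak0=0.0)
        net = compile_network(cs.library_circuit("AND"), p)
        assert not any(r.label.startswith("leak_and") for r in net.reactions)

    @pytest.mark.parametrize("name", cs.LIBRARY_NAMES)
    def test_conservation_vectors_are_left_null(self, name, params):
        net = compile_network(cs.library_circuit(name), params,
                              {l: 10.0 for l in cs.library_circuit(name).ligand_names})
        assert left_null_residual(net) < 1e-12

    @pytest.mark.parametrize("name", cs.LIBRARY_NAMES)
    def test_dna_totals_catalytic_transcription(self, name, params):
        """Transcripts appear de novo only via transcription (the reversible
        AND first step may re-release a bound invader), and transcription is
        catalytic in template: no reaction changes any template-DNA total."""
        c = cs.library_circuit(name)
        net = compile_network(c, params)
        idx = net.index()
        n_mat = net.stoichiometry_matrix()
        transcript_names = {t.transcript_name for t in c.templates}
        for j, r in enumerate(net.reactions):
            for tname in transcript_names:
                if n_mat[idx[tname], j] > 0:
                    assert r.label.startswith(("tx:", "tmsd_and_close:"))
            for t in c.templates:
                row = n_mat[idx[t.name], j]
                if r.label == f"tx:{t.name}":
                    assert row == 0  # catalytic

    def test_ideal_reduction_all_tmsd_irreversible(self):
        """With the mismatch penalty off and no clamp leak, every non-AND TMSD
        reaction runs at the pure toehold rate."""
        p = KineticParams(mismatch_penalty=1.0, clamp_leak0=0.0)
        for name in ("NOT_tet", "OR", "NAND"):
            net = compile_network(cs.library_circuit(name), p)
            for r in net.reactions:
                if r.label.startswith(("tmsd_signal", "tmsd_or", "tmsd_not")):
                    assert r.rate_constant == toehold_rate(8, p)

    def test_structure_penalty_scales_invader_tmsd_only(self, params):
        from dataclasses import replace

        p = replace(params, structure_penalty={"InvadeR_u": 0.25})
        net = compile_network(cs.library_circuit("NOT_tet"), p)
        base = compile_network(cs.library_circuit("NOT_tet"), params)
        for r_pen, r_base in zip(net.reactions, base.reactions):
            ratio = r_pen.rate_constant / r_base.rate_constant
            if r_base.label.startswith(("tmsd_signal", "tmsd_not")):
                assert ratio == pytest.approx(0.25)
            else:  # transcription is untouched by the structure penalty
                assert ratio == 1.0


class TestParams:
    def test_json_round_trip(self, params):
        assert KineticParams.from_json(params.to_json()) == params

    def test_rejects_negative_rates_and_bad_penalty(self):
        with pytest.raises(ValueError):
            KineticParams(k_tx=-1.0)
        with pytest.raises(ValueError):
            KineticParams(mismatch_penalty=0.0)

    def test_unknown_tf_falls_back_to_global(self, params):
        b = params.binding_for("NoSuchTF")
        assert b.k_on_op == params.k_on_op and b.k_off_lig == params.k_off_lig
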