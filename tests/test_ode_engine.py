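"""ODE engine against closed-form kinetics oracles and conservation audits."""

import math

import numpy as np
import pytest

from strandlogic import circuit_spec as cs
from strandlogic.kinetic_network import (
    Reaction,
    ReactionNetwork,
    Species,
    compile_network,
)
from strandlogic.ode_engine import (
    SolverSettings,
    activation_time,
    check_conservation,
    closed_form_bimolecular,
    default_grid,
    first_crossing,
    simulate,
)


def bimolecular_net(a0, b0, k) -> ReactionNetwork:
    return ReactionNetwork(
        circuit_name="A+B->C",
        condition={},
        species=[
            Species("A", "transcript", a0, {}),
            Species("B", "dna_gate", b0, {"g": 1}),
            Species("C", "waste", 0.0, {"g": 1}),
        ],
        reactions=[Reaction(("A", "B"), ("C",), k, "bi")],
    )


class TestClosedForm:
    def test_boundary_cases(self):
        assert closed_form_bimolecular(2.0, 1.0, 3.0, 0.0) == 2.0
        assert closed_form_bimolecular(2.0, 1.0, 0.0, 50.0) == 2.0

    def test_equal_start_half_life(self):
        assert closed_form_bimolecular(1.0, 1.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_unequal_start_limits(self):
        # excess B drives A to zero; excess A leaves a0-b0
        assert closed_form_bimolecular(1.0, 5.0, 2.0, 1e3) == pytest.approx(0.0, abs=1e-12)
        assert closed_form_bimolecular(5.0, 1.0, 2.0, 1e3) == pytest.approx(4.0)

    def test_rejects_negative_input(self):
        with pytest.raises(ValueError):
            closed_form_bimolecular(-1.0, 1.0, 1.0, 1.0)


class TestSimulateOracles:
    def test_second_order_equal_start(self):
        net = bimolecular_net(1.0, 1.0, 0.7)
        res = simulate(net, SolverSettings(rtol=1e-10, atol=1e-13))
        expect = [closed_form_bimolecular(1.0, 1.0, 0.7, t) for t in res.t_grid]
        assert np.allclose(res.trace("A"), expect, rtol=1e-6)

    def test_pseudo_first_order_limit(self):
        a0, b0, k = 1e-3, 5.0, 0.5
        net = bimolecular_net(a0, b0, k)
        res = simulate(net, SolverSettings(rtol=1e-10, atol=1e-15, t_grid=default_grid(10)))
        exact = [closed_form_bimolecular(a0, b0, k, t) for t in res.t_grid]
        assert np.allclose(res.trace("A"), exact, rtol=1e-6)
        # exponential decay holds to the (a0/b0 ~ 2e-4) depletion error
        expect = a0 * np.exp(-k * b0 * res.t_grid)
        assert np.allclose(res.trace("A"), expect, rtol=1e-3)

    def test_zero_template_network_stays_dark(self, params):
        c = cs.unregulated_sensor(template_nM=0.0)
        res = simulate(compile_network(c, params))
        assert np.all(res.mef() == 0.0)

    def test_gateless_transcript_accumulates_linearly(self, params):
        """With the signal gate at zero the transcript grows at
        k_tx·[template]: no degradation is modelled."""
        from dataclasses import replace

        c = cs.unregulated_sensor()
        gates = tuple(replace(g, concentration=0.0) for g in c.gates)
        net = compile_network(replace(c, gates=gates), params)
        res = simulate(net, SolverSettings(rtol=1e-10, atol=1e-13))
        v = params.k_tx * c.templates[0].concentration
        assert np.allclose(res.trace("InvadeR_u"), v * res.t_grid, rtol=1e-7)

    def test_grid_refinement_converged(self, params):
        net = compile_network(cs.tetr_sensor(), params, {cs.ATC: 10.0})
        coarse = simulate(net, SolverSettings(rtol=1e-8, atol=1e-11, max_step=8.0))
        fine = simulate(net, SolverSettings(rtol=1e-8, atol=1e-11, max_step=4.0))
        assert abs(fine.mef()[-1] - coarse.mef()[-1]) / fine.mef()[-1] < 1e-3


class TestActivationTime:
    def test_flat_zero_never_crosses(self):
        t = default_grid(120)
        assert first_crossing(t, np.zeros_like(t), 0.5) is None

    def test_linear_trace_interpolates(self):
        t = default_grid(120)
        assert first_crossing(t, t / 100.0, 0.5) == pytest.approx(50.0)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            first_crossing(np.arange(3.0), np.arange(3.0), -0.1)

    def test_works_on_simulation_result(self, params, fast_settings):
        net = compile_network(cs.tetr_sensor(), params, {cs.ATC: 10.0})
        res = simulate(net, fast_settings)
        at = activation_time(res, "F", 0.5)
        assert at is not None and 0 < at < 120


class TestConservation:
    def test_library_circuit_drift_below_1e8(self, params):
        net = compile_network(cs.library_circuit("OR"), params,
                              {cs.TET: 10.0, cs.ZN: 10.0})
        res = simulate(net)  # default tight tolerances
        rep = check_conservation(res, net, tol=1e-8)
        assert rep["ok"], rep

    def test_empty_network_trivial_report(self):
        net = ReactionNetwork("empty", {}, [], [])
        res = simulate(net, SolverSettings(t_grid=default_grid(5)))
        rep = check_conservation(res, net)
        assert rep["per_total"] == {} and rep["ok"]

    def test_corrupted_stoichiometry_is_flagged(self):
        # drop C's membership bookkeeping is fine; instead break mass balance:
        # A + B -> C with C never produced means the "g" total visibly drains.
        net = ReactionNetwork(
            "broken",
            {},
            species=[
                Species("A", "transcript", 1.0, {}),
                Species("B", "dna_gate", 1.0, {"g": 1}),
                Species("C", "waste", 0.0, {"g": 1}),
            ],
            reactions=[Reaction(("A", "B"), ("A",), 1.0, "bad")],
        )
        res = simulate(net, SolverSettings(t_grid=default_grid(10)))
        rep = check_conservation(res, net)
        assert not rep["ok"] and rep["max_drift"] > 1e-3


class TestSolverSettings:
    def test_grid_must_start_at_zero_and_increase(self):
        with pytest.raises(ValueError):
            SolverSettings(t_grid=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            SolverSettings(t_grid=np.array([0.0, 2.0, 2.0]))

    def test_tolerances_positive(self):
        with pytest.raises(ValueError):
            SolverSettings(rtol=0.0)
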