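"""CRN construction and mass-action integration."""

import numpy as np
import pytest

from asekit import make_fixture
from asekit.circuit import (
    ASEReactionSpec,
    CircuitSpec,
    FiringMode,
    InputDecl,
    Reporter,
)
from asekit.kinetics import (
    KineticModel,
    build_crn,
    conservation_residuals,
    endpoint_signals,
    simulate,
)

S0 = 50e-9


def constitutive_circuit():
    """A zero-switch gate pair: exchange runs at full rate with no input."""
    return CircuitSpec(
        inputs=[InputDecl("a")],
        reactions=[
            ASEReactionSpec("r0", [], FiringMode.REQUIRE_ANY, Reporter("Out"))
        ],
        outputs=["Out"],
    )


def second_order_endpoint(k, t, c0=S0):
    """Closed form for A + B -> P with [A]0 = [B]0 = c0: x = k c0^2 t / (1 + k c0 t)."""
    return k * c0 * c0 * t / (1 + k * c0 * t)


class TestBuildCRN:
    def test_and_fixture_network_shape(self, and_circuit):
        crn = build_crn(and_circuit, input_state={"a": 5.0, "b": 5.0})
        # one switch per gate: 2 states per gate, 1 product, 1 waste,
        # 2 inputs + 2 bound sinks
        assert len(crn.species) == 10
        n_act = sum(
            1 for r in crn.reactions if crn.species[r.reactants[0]].startswith("I[")
        )
        n_exch = len(crn.reactions) - n_act
        assert (n_act, n_exch) == (2, 4)

    def test_zero_switch_reaction_is_single_constitutive_exchange(self):
        model = KineticModel()
        crn = build_crn(constitutive_circuit(), model)
        assert len(crn.reactions) == 1
        assert crn.reactions[0].rate == model.k_exchange

    @staticmethod
    def _exchange_reactions(crn):
        return [
            r for r in crn.reactions if crn.species[r.products[0]].startswith("P[")
        ]

    def test_only_eligible_pair_gets_fast_rate(self, and_circuit):
        model = KineticModel()
        crn = build_crn(and_circuit, model)
        exch = self._exchange_reactions(crn)
        fast = [r for r in exch if r.rate == model.k_exchange]
        slow = [r for r in exch if r.rate == model.k_leak]
        assert len(fast) == 1 and len(slow) == 3  # only (S activated, W activated)

    def test_enhancement_scales_with_extra_switches(self):
        model = KineticModel(enhancement_alpha=1.5)
        for n, expected_extra in ((4, 1), (6, 2)):  # configs with 3 and 4 switches
            crn = build_crn(make_fixture(f"fig1_config_{n}"), model)
            top = max(r.rate for r in self._exchange_reactions(crn))
            assert top == pytest.approx(model.k_exchange * 1.5**expected_extra)

    def test_state_explosion_guard(self):
        from asekit.circuit import Junction, Site, SwitchPlacement

        placements = [
            SwitchPlacement(f"sw{i}", "a", "r0", Junction.J1, Site.TOP, i) for i in range(11)
        ] + [SwitchPlacement("swx", "a", "r0", Junction.J2, Site.TOP, 0)]
        spec = CircuitSpec(
            inputs=[InputDecl("a")],
            reactions=[
                ASEReactionSpec("r0", placements, FiringMode.REQUIRE_ALL, Reporter("Out"))
            ],
            outputs=["Out"],
        )
        with pytest.raises(ValueError, match="state-explosion"):
            build_crn(spec)


class TestSimulate:
    def test_constitutive_endpoint_matches_closed_form(self):
        model = KineticModel()
        crn = build_crn(constitutive_circuit(), model)
        tc = simulate(crn, model)
        expected = second_order_endpoint(model.k_exchange, model.t_end)
        assert tc.reporter_signal["Out"][-1] == pytest.approx(expected, rel=1e-6)
        assert expected > 0.9 * S0  # k*S0*t = 18 >> 1

    def test_fully_blocked_pair_leaks_far_below_threshold(self, and_circuit):
        model = KineticModel()
        crn = build_crn(and_circuit, model, {"a": 0.0, "b": 0.0})
        tc = simulate(crn, model)
        expected = second_order_endpoint(model.k_leak, model.t_end)
        assert tc.reporter_signal["Out"][-1] == pytest.approx(expected, rel=1e-4)
        assert tc.reporter_signal["Out"][-1] < 0.5 * S0 * 0.01

    def test_zero_leak_zero_input_gives_identically_zero_product(self, and_circuit):
        model = KineticModel(k_leak=0.0)
        crn = build_crn(and_circuit, model, {"a": 0.0, "b": 0.0})
        tc = simulate(crn, model)
        assert np.allclose(tc.reporter_signal["Out"], 0.0, atol=1e-20)

    def test_doubling_k_exchange_never_decreases_endpoint(self, or_circuit):
        ends = []
        for k in (2e4, 4e4):
            model = KineticModel(k_exchange=k)
            crn = build_crn(or_circuit, model, {"a": 5.0, "b": 0.0})
            ends.append(simulate(crn, model).reporter_signal["Out"][-1])
        assert ends[1] >= ends[0]

    def test_reporter_signal_nondecreasing(self, fourinput_circuit):
        model = KineticModel()
        crn = build_crn(fourinput_circuit, model, {"a": 5.0, "b": 5.0, "c": 0.0, "d": 0.0})
        tc = simulate(crn, model, n_points=100)
        for sig in tc.reporter_signal.values():
            assert (np.diff(sig) >= -1e-15).all()

    def test_strand_groups_conserved(self, fourinput_circuit):
        model = KineticModel()
        crn = build_crn(fourinput_circuit, model, {"a": 5.0, "b": 0.0, "c": 5.0, "d": 5.0})
        tc = simulate(crn, model, n_points=60)
        residuals = conservation_residuals(crn, tc)
        assert max(residuals.values()) < 1e-9


class TestKineticSignatures:
    """Qualitative signatures of the six single-input gate configurations."""

    @pytest.mark.parametrize("n", [1, 2])
    def test_single_blocked_junction_is_input_independent(self, n):
        model = KineticModel()
        fx = make_fixture(f"fig1_config_{n}")
        sigs = []
        for mult in (0.0, 5.0):
            crn = build_crn(fx, model, {"I1": mult})
            sigs.append(simulate(crn, model, n_points=100).reporter_signal["Out"])
        rel_diff = np.max(np.abs(sigs[0] - sigs[1])) / np.max(sigs[1])
        assert rel_diff < 0.01

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_both_blocked_crosses_threshold_only_with_input(self, n):
        model = KineticModel()
        fx = make_fixture(f"fig1_config_{n}")
        ends = {}
        for mult in (0.0, 5.0):
            crn = build_crn(fx, model, {"I1": mult})
            ends[mult] = simulate(crn, model).reporter_signal["Out"][-1]
        assert ends[5.0] > 0.5 * S0  # ON state converts most of the gates
        assert ends[0.0] / ends[5.0] < 0.5  # normalized OFF stays below threshold

    def test_half_max_time_nonincreasing_in_switch_count(self):
        model = KineticModel(enhancement_alpha=1.5)

        def t_half(n):
            crn = build_crn(make_fixture(f"fig1_config_{n}"), model, {"I1": 5.0})
            tc = simulate(crn, model, n_points=600)
            sig = tc.reporter_signal["Out"]
            return tc.time[np.argmax(sig >= 0.5 * sig[-1])]

        halves = [t_half(n) for n in (3, 4, 6)]  # 2, 3, 4 switches
        assert halves[0] >= halves[1] >= halves[2]
        assert halves[2] < halves[0]  # strictly faster with more switches


class TestEndpointSignals:
    def test_and_maximal_at_both_on(self, and_circuit):
        raw = endpoint_signals(and_circuit)
        assert raw.shape == (4, 1)
        assert np.argmax(raw[:, 0]) == 3

    def test_or_three_high_one_low(self, or_circuit):
        raw = endpoint_signals(or_circuit)[:, 0]
        assert (raw[1:] > 0.9 * raw.max()).all()
        assert raw[0] < 0.01 * raw.max()

    def test_signals_bounded_by_gate_concentration(self, fourinput_circuit):
        raw = endpoint_signals(fourinput_circuit)
        assert (raw >= 0).all() and (raw <= S0 * (1 + 1e-9)).all()
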