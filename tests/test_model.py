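"""Deterministic core: weighted-sum update, enumeration, basins, ergodic sets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netwin import (
    CONTROL_PROFILE,
    EnumerationCapError,
    Link,
    NetworkDefinition,
    NetworkSchemaError,
    NetworkState,
    Perturbation,
    SimulationConfig,
    StatusProfile,
    Target,
    basin_of_apoptosis,
    enumerate_initial_states,
    ergodic_set,
    simulate,
    step,
)
from netwin.model import free_nodes, initial_state_matrix, stochastic_batch_run


class TestNetworkDefinition:
    def test_toy_roundtrip_shape(self, toy):
        assert toy.n_nodes == 3
        assert len(toy.links) == 2
        assert toy.death_readout == "Z"
        assert toy.input_nodes == ()

    def test_p53_fixture_has_16_nodes(self, p53):
        assert p53.n_nodes == 16
        assert p53.death_readout == "CASP3"
        assert p53.input_nodes == ("DNA_damage",)

    @pytest.mark.parametrize(
        "nodes,links,msg",
        [
            (
                (("A", 0, "output"),),
                (Link("Q", "A", 1),),
                "not a declared node",
            ),
            (
                (("A", 0, "output"), ("B", 0, "internal")),
                (Link("B", "A", 0),),
                "nonzero",
            ),
            ((("A", 0, "internal"),), (), "output"),
            (
                (("A", 0, "output"), ("A", 1, "internal")),
                (),
                "duplicate node",
            ),
        ],
    )
    def test_schema_violations_raise(self, nodes, links, msg):
        with pytest.raises(NetworkSchemaError, match=msg):
            NetworkDefinition(nodes, links)


class TestStep:
    def test_weighted_sum_hand_evaluation(self, toy):
        # Z's next bit: X*1 + Y*(-1) + 0 > 0
        state = NetworkState((1, 0, 0))
        nxt = step(toy, CONTROL_PROFILE, state)
        assert nxt.bits[toy.index("Z")] == 1

    def test_suppressed_link_contributes_zero(self, toy):
        state = NetworkState((1, 0, 0))
        nxt = step(toy, CONTROL_PROFILE, state, suppressed_links=[("X", "Z")])
        assert nxt.bits[toy.index("Z")] == 0

    def test_suppressed_node_forced_off(self, toy):
        nxt = step(toy, CONTROL_PROFILE, NetworkState((1, 1, 1)), suppressed_nodes=["X"])
        assert nxt.bits[toy.index("X")] == 0

    def test_status_clamps_win_over_logic(self, toy):
        profile = StatusProfile.from_dict({"X": "I", "Y": "A"})
        nxt = step(toy, profile, NetworkState((1, 0, 0)))
        assert nxt.bits[toy.index("X")] == 0
        assert nxt.bits[toy.index("Y")] == 1


class TestSimulate:
    def test_toy_reaches_death_fixed_point(self, toy, config):
        res = simulate(toy, CONTROL_PROFILE, NetworkState((0, 0, 0)), config)
        assert res.activity["Z"] == 1.0
        assert res.death is True

    def test_suppressing_driver_prevents_death(self, toy, config):
        total = config.transient_steps + config.steady_steps
        schedule = [(["X"], [])] * total
        res = simulate(toy, CONTROL_PROFILE, NetworkState((1, 1, 1)), config, schedule)
        assert res.activity["Z"] == 0.0
        assert res.death is False

    def test_p53_trajectories_converge_within_transient(self, p53, dd_on):
        # fixed-point or cycle-average activities must be identical whether we
        # average over the steady window or a window delayed by 100 more steps
        cfg_late = SimulationConfig(
            transient_steps=200, steady_steps=100, input_clamp={"DNA_damage": 1}, seed=1
        )
        state = NetworkState(tuple(1 if n == "DNA_damage" else 0 for n in p53.names))
        early = simulate(p53, CONTROL_PROFILE, state, dd_on)
        late = simulate(p53, CONTROL_PROFILE, state, cfg_late)
        assert early.activity == pytest.approx(late.activity)

    def test_activity_bounds_and_determinism(self, p53, dd_on):
        state = NetworkState(tuple(0 for _ in p53.names))
        r1 = simulate(p53, CONTROL_PROFILE, state, dd_on)
        r2 = simulate(p53, CONTROL_PROFILE, state, dd_on)
        assert r1 == r2
        assert all(0.0 <= a <= 1.0 for a in r1.activity.values())


class TestEnumeration:
    def test_toy_full_space(self, toy, config):
        S = enumerate_initial_states(toy, CONTROL_PROFILE, config)
        assert S.shape == (8, 3)
        assert len({tuple(r) for r in S}) == 8

    def test_clamping_halves_the_space(self, toy, config):
        profile = StatusProfile.from_dict({"X": "A"})
        S = enumerate_initial_states(toy, profile, config)
        assert S.shape == (4, 3)
        assert (S[:, toy.index("X")] == 1).all()

    def test_p53_control_has_15_free_nodes(self, p53, dd_on):
        assert len(free_nodes(p53, CONTROL_PROFILE)) == 15
        S = enumerate_initial_states(p53, CONTROL_PROFILE, dd_on)
        assert S.shape == (2**15, 16)

    def test_cap_exceeded_instructs_sampling(self, p53, dd_on):
        tight = SimulationConfig(enumeration_cap=10, input_clamp={"DNA_damage": 1})
        with pytest.raises(EnumerationCapError, match="sampled"):
            enumerate_initial_states(p53, CONTROL_PROFILE, tight)
        S = initial_state_matrix(p53, CONTROL_PROFILE, tight)
        assert S.shape == (tight.n_samples, 16)


class TestBasin:
    def test_constitutive_driver_gives_full_basin(self, toy, config):
        assert basin_of_apoptosis(toy, CONTROL_PROFILE, config) == 1.0

    def test_inactivated_driver_gives_empty_basin(self, toy, config):
        profile = StatusProfile.from_dict({"X": "I"})
        assert basin_of_apoptosis(toy, profile, config) == 0.0

    def test_p53_control_unstimulated_basin_below_half(self, p53, dd_off):
        assert basin_of_apoptosis(p53, CONTROL_PROFILE, dd_off) == 0.0

    def test_basin_is_deterministic(self, p53, dd_on):
        b1 = basin_of_apoptosis(p53, CONTROL_PROFILE, dd_on)
        b2 = basin_of_apoptosis(p53, CONTROL_PROFILE, dd_on)
        assert b1 == b2 <= 0.5


class TestErgodicSet:
    def test_dose_zero_equals_deterministic_attractor(self, toy, config):
        pert = Perturbation.single(Target.of_node("X"), dose=0.0)
        states = ergodic_set(toy, CONTROL_PROFILE, pert, NetworkState((0, 0, 0)), config)
        assert states == {(1, 0, 1)}

    def test_dose_one_forces_target_off_everywhere(self, toy, config):
        pert = Perturbation.single(Target.of_node("X"), dose=1.0)
        states = ergodic_set(toy, CONTROL_PROFILE, pert, NetworkState((1, 1, 1)), config)
        assert all(s[toy.index("X")] == 0 for s in states)

    def test_intermediate_dose_spans_both_attractors(self, toy):
        cfg = SimulationConfig(seed=3, steady_steps=200)
        pert = Perturbation.single(Target.of_node("X"), dose=0.5)
        states = ergodic_set(toy, CONTROL_PROFILE, pert, NetworkState((0, 0, 0)), cfg)
        z = {s[toy.index("Z")] for s in states}
        assert z == {0, 1}


class TestStochasticInvariants:
    def test_dose1_node_suppression_equals_I_status(self, p53, dd_on):
        """Full inhibition and constitutive inactivation are the same dynamics."""
        profile = StatusProfile.from_dict({"AKT": "I"})
        S0 = initial_state_matrix(p53, profile, dd_on)
        from netwin.model import _Compiled, _deterministic_output_activity

        ctx = _Compiled(p53, profile, dd_on.input_clamp)
        det = _deterministic_output_activity(ctx, S0.copy(), dd_on)
        pert = Perturbation.single(Target.of_node("AKT"), dose=1.0)
        rng = np.random.default_rng(0)
        stoch = stochastic_batch_run(p53, CONTROL_PROFILE, S0.copy(), pert, dd_on, rng)
        np.testing.assert_array_equal(det, stoch)

    def test_dose0_schedule_is_bitwise_unperturbed(self, toy, config):
        pert = Perturbation.single(Target.of_node("X"), dose=0.0)
        S0 = initial_state_matrix(toy, CONTROL_PROFILE, config)
        rng = np.random.default_rng(5)
        stoch = stochastic_batch_run(toy, CONTROL_PROFILE, S0.copy(), pert, config, rng)
        from netwin.model import _Compiled, _deterministic_output_activity

        ctx = _Compiled(toy, CONTROL_PROFILE, config.input_clamp)
        det = _deterministic_output_activity(ctx, S0.copy(), config)
        np.testing.assert_array_equal(det, stoch)


@settings(max_examples=20, deadline=None)
@given(bits=st.lists(st.integers(0, 1), min_size=3, max_size=3))
def test_step_is_total_on_valid_states(bits):
    """The synchronous update is defined for every binary state."""
    from netwin.fixtures import toy_network

    toy = toy_network()
    nxt = step(toy, CONTROL_PROFILE, NetworkState(tuple(bits)))
    assert set(nxt.bits) <= {0, 1}
    # X has basal 1 and no inputs: always ON next step
    assert nxt.bits[0] == 1
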