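"""Engine semantics: validation, enabling, stepping, integration accuracy."""

import math

import numpy as np
import pytest

from terpnet.engine import (
    ArcSpec,
    DivergenceError,
    GenericUpdate,
    NetworkSpec,
    PlaceSpec,
    SimState,
    TransitionSpec,
    effective_speed,
    is_enabled,
    simulate,
    step,
    validate_network,
)


def source_decay_net(k=10.0, d=0.1, m0=0.0, bound=1e9):
    """One place fed by a zeroth-order source and drained first-order."""
    return NetworkSpec(
        places=[PlaceSpec("X", initial=m0)],
        transitions=[
            TransitionSpec("src", speed="k"),
            TransitionSpec("sink", speed="d * X"),
        ],
        arcs=[ArcSpec("normal", "src", "X"), ArcSpec("normal", "X", "sink")],
        parameters={"k": k, "d": d},
        overflow_bound=bound,
    )


# -- validation -------------------------------------------------------------


def test_validate_flags_non_bipartite_arc():
    net = NetworkSpec(
        places=[PlaceSpec("A"), PlaceSpec("B")],
        transitions=[TransitionSpec("t", speed="1")],
        arcs=[ArcSpec("normal", "A", "B")],
    )
    report = validate_network(net)
    assert len(report.violations) == 1
    assert "non-bipartite" in report.violations[0]


def test_validate_flags_negative_initial():
    net = NetworkSpec(places=[PlaceSpec("A", initial=-1.0)])
    report = validate_network(net)
    assert len(report.violations) == 1
    assert "negative initial" in report.violations[0]


@pytest.mark.parametrize(
    "net, fragment",
    [
        (NetworkSpec(transitions=[TransitionSpec("t", speed="1")],
                     arcs=[ArcSpec("normal", "ghost", "t")]), "dangling"),
        (NetworkSpec(places=[PlaceSpec("A")],
                     transitions=[TransitionSpec("t", kind="generic", speed="1",
                                                 update=GenericUpdate("True", "A", "1"))]),
         "speed on generic"),
        (NetworkSpec(places=[PlaceSpec("A")],
                     transitions=[TransitionSpec("t", speed="1")],
                     arcs=[ArcSpec("normal", "t", "A", threshold=-2.0)]),
         "negative constant threshold"),
        (NetworkSpec(places=[PlaceSpec("A")],
                     transitions=[TransitionSpec("t", speed="k_missing * A")],
                     arcs=[ArcSpec("normal", "A", "t")]), "k_missing"),
        (NetworkSpec(places=[PlaceSpec("A", kind="discrete", initial=1)]), "discrete"),
    ],
)
def test_validate_flags_each_violation(net, fragment):
    report = validate_network(net)
    assert not report.ok
    assert any(fragment in v for v in report.violations)


def test_validate_accepts_source_decay_motif():
    assert validate_network(source_decay_net()).ok


# -- enabling and speeds ----------------------------------------------------


def inhibited_net(threshold=80.0):
    return NetworkSpec(
        places=[PlaceSpec("I"), PlaceSpec("X")],
        transitions=[TransitionSpec("t", speed="5")],
        arcs=[ArcSpec("normal", "t", "X"),
              ArcSpec("inhibitory", "I", "t", threshold=threshold)],
    )


@pytest.mark.parametrize("inhibitor, expected", [
    (85.0, False),   # at/above the 80-unit threshold: suppressed
    (80.0, False),   # boundary is inclusive for inhibition
    (79.9, True),    # strictly below: enabled
])
def test_inhibitory_threshold_is_strict(inhibitor, expected):
    net = inhibited_net(80.0)
    state = SimState(0.0, {"I": inhibitor, "X": 0.0})
    assert is_enabled("t", state, net) is expected


def test_transition_without_input_arcs_is_enabled():
    net = NetworkSpec(places=[PlaceSpec("X")],
                      transitions=[TransitionSpec("t", speed="1")],
                      arcs=[ArcSpec("normal", "t", "X")])
    assert is_enabled("t", SimState(0.0, {"X": 0.0}), net)


def test_effective_speed_gates_to_zero_when_disabled():
    net = inhibited_net(80.0)
    assert effective_speed("t", SimState(0.0, {"I": 90.0, "X": 0.0}), net) == 0.0
    assert effective_speed("t", SimState(0.0, {"I": 0.0, "X": 0.0}), net) == 5.0


def test_mass_action_speed_value():
    net = NetworkSpec(
        places=[PlaceSpec("S", initial=50.0), PlaceSpec("P")],
        transitions=[TransitionSpec("t", speed="k * S")],
        arcs=[ArcSpec("normal", "S", "t"), ArcSpec("normal", "t", "P")],
        parameters={"k": 0.1},
    )
    assert effective_speed("t", SimState(0.0, {"S": 50.0, "P": 0.0}), net) == 5.0


def test_unresolvable_transition_is_hard_error():
    net = source_decay_net()
    with pytest.raises(KeyError):
        is_enabled("ghost", SimState(0.0, {"X": 0.0}), net)


# -- stepping ---------------------------------------------------------------


def test_step_source_accumulation():
    net = source_decay_net(k=10.0, d=0.0)
    out = step(SimState(0.0, {"X": 0.0}), net, dt=0.1)
    assert out.marking["X"] == pytest.approx(1.0)
    assert out.time == pytest.approx(0.1)


def test_step_applies_stoichiometric_weight_two():
    """A weight-2 substrate arc consumes twice the flux (NADPH in the
    HMG-CoA reductase reaction)."""
    net = NetworkSpec(
        places=[PlaceSpec("HMG", initial=10.0), PlaceSpec("NADPH", initial=100.0),
                PlaceSpec("MEV", initial=0.0)],
        transitions=[TransitionSpec("r3", speed="k * HMG * NADPH")],
        arcs=[ArcSpec("normal", "HMG", "r3"),
              ArcSpec("normal", "NADPH", "r3", weight=2.0),
              ArcSpec("normal", "r3", "MEV")],
        parameters={"k": 0.001},
    )
    s0 = SimState(0.0, {"HMG": 10.0, "NADPH": 100.0, "MEV": 0.0})
    v = 0.001 * 10.0 * 100.0
    out = step(s0, net, dt=0.1)
    assert out.marking["NADPH"] == pytest.approx(100.0 - 2 * v * 0.1)
    assert out.marking["HMG"] == pytest.approx(10.0 - v * 0.1)
    assert out.marking["MEV"] == pytest.approx(v * 0.1)


def test_starvation_guard_zeroes_overdrawing_transition():
    """Demand 1.0 against marking 0.5: the transition idles, marking unchanged."""
    net = NetworkSpec(
        places=[PlaceSpec("X", initial=0.5), PlaceSpec("Y")],
        transitions=[TransitionSpec("t", speed="10")],
        arcs=[ArcSpec("normal", "X", "t"), ArcSpec("normal", "t", "Y")],
    )
    out = step(SimState(0.0, {"X": 0.5, "Y": 0.0}), net, dt=0.1)
    assert out.marking["X"] == 0.5
    assert out.marking["Y"] == 0.0


def test_starvation_guard_is_simultaneous_over_competitors():
    """Two consumers whose combined demand overdraws a place both idle."""
    net = NetworkSpec(
        places=[PlaceSpec("X", initial=1.0), PlaceSpec("A"), PlaceSpec("B")],
        transitions=[TransitionSpec("ta", speed="6"), TransitionSpec("tb", speed="6")],
        arcs=[ArcSpec("normal", "X", "ta"), ArcSpec("normal", "ta", "A"),
              ArcSpec("normal", "X", "tb"), ArcSpec("normal", "tb", "B")],
    )
    out = step(SimState(0.0, {"X": 1.0, "A": 0.0, "B": 0.0}), net, dt=0.1)
    assert out.marking == {"X": 1.0, "A": 0.0, "B": 0.0}


def test_generic_update_fires_at_new_time():
    net = NetworkSpec(
        places=[PlaceSpec("flag", kind="generic", initial=False), PlaceSpec("X")],
        transitions=[
            TransitionSpec("src", speed="1"),
            TransitionSpec("g", kind="generic",
                           update=GenericUpdate("time >= 0.1", "flag", "True")),
        ],
        arcs=[ArcSpec("normal", "src", "X")],
    )
    s1 = step(SimState(0.0, {"flag": False, "X": 0.0}), net, dt=0.1)
    assert s1.marking["flag"] is True


# -- simulate ---------------------------------------------------------------


def test_steady_state_matches_k_over_d():
    net = source_decay_net(k=10.0, d=0.1)
    trace = simulate(net, t_end=150.0, dt=0.01, sample_every=1.0)
    assert trace.terminal("X") == pytest.approx(100.0, rel=0.01)


def test_pure_decay_matches_closed_forms():
    net = source_decay_net(k=0.0, d=0.1, m0=10.0)
    dt = 0.01
    trace = simulate(net, t_end=10.0, dt=dt, sample_every=1.0)
    # exact oracle of the Euler recursion
    discrete = 10.0 * (1 - 0.1 * dt) ** 1000
    assert trace.terminal("X") == pytest.approx(discrete, abs=1e-9)
    # continuous solution within the first-order Euler error bound
    exact = 10.0 * math.exp(-1.0)
    assert abs(trace.terminal("X") - exact) < 10.0 * 0.1 * dt  # ~ m0*d*dt scale


def test_halving_dt_moves_solution_first_order():
    net = source_decay_net(k=5.0, d=0.2, m0=3.0)
    coarse = simulate(net, 20.0, dt=0.1, sample_every=1.0)
    fine = simulate(net, 20.0, dt=0.05, sample_every=1.0)
    diff = np.max(np.abs(coarse["X"] - fine["X"]))
    scale = np.max(np.abs(fine["X"]))
    assert diff / scale < 0.01


def test_t_end_zero_returns_initial_marking_only():
    net = source_decay_net(m0=2.5)
    trace = simulate(net, t_end=0.0, dt=0.1, sample_every=1.0)
    assert trace.times.tolist() == [0.0]
    assert trace["X"].tolist() == [2.5]


def test_sampling_includes_endpoints_and_is_strictly_increasing():
    net = source_decay_net()
    trace = simulate(net, t_end=5.5, dt=0.1, sample_every=1.0)
    assert trace.times[0] == 0.0
    assert trace.times[-1] == pytest.approx(5.5)
    assert np.all(np.diff(trace.times) > 0)


def test_divergence_aborts_and_names_place():
    net = source_decay_net(k=10.0, d=0.0, bound=5.0)
    with pytest.raises(DivergenceError, match="'X'"):
        simulate(net, t_end=10.0, dt=0.1, sample_every=1.0)


def test_simulation_is_deterministic():
    net = source_decay_net(k=3.0, d=0.07, m0=1.0)
    a = simulate(net, 30.0, dt=0.05, sample_every=1.0)
    b = simulate(net, 30.0, dt=0.05, sample_every=1.0)
    assert np.array_equal(a["X"], b["X"])
    assert np.array_equal(a.times, b.times)
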