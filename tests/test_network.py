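"""Engine unit and property tests, checked against a straight-line scalar
re-implementation of the update equation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from awarenet.network import (
    Connection,
    NetworkError,
    NetworkModel,
    StateSpec,
    Trace,
    aggregate_input,
    euler_step,
    logistic_threshold,
    simulate,
)


from oracle_helpers import oracle_step


# ---------------------------------------------------------------------------
# logistic threshold function
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "sigma,tau,x,expected",
    [
        (2.0, 0.5, 0.0, 0.0),           # the two sigmoid terms cancel at x=0
        (6.0, 1.0, -0.3, 0.0),          # zero branch for non-positive input
        (2.0, 0.5, 0.5, 0.3160602794142789),  # frozen closed-form value
        (2.0, 0.5, 50.0, 1.0),          # saturates at 1
    ],
)
def test_logistic_threshold_values(sigma, tau, x, expected):
    assert logistic_threshold(sigma, tau, x) == pytest.approx(expected, abs=1e-6)


def test_logistic_threshold_monotone_and_bounded():
    xs = np.linspace(1e-6, 10, 500)
    ys = logistic_threshold(3.0, 0.7, xs)
    assert np.all(np.diff(ys) > 0)
    assert np.all((ys >= 0) & (ys < 1))
    # continuous at 0
    assert logistic_threshold(3.0, 0.7, 1e-9) == pytest.approx(0.0, abs=1e-6)


def test_logistic_threshold_as_printed_variant_exceeds_one():
    # the uncorrected normalisation overshoots 1 for large input, which is
    # why the corrected variant is the default
    assert logistic_threshold(2.0, 0.5, 50.0, variant="as_printed") > 1.0


def test_logistic_threshold_rejects_bad_parameters():
    with pytest.raises(NetworkError):
        logistic_threshold(0.0, 0.5, 1.0)
    with pytest.raises(NetworkError):
        logistic_threshold(-2.0, 0.5, 1.0)
    with pytest.raises(NetworkError):
        logistic_threshold(2.0, -0.1, 1.0)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def test_aggregate_input_examples():
    conns = [Connection("A", "T", 0.8), Connection("B", "T", -0.5)]
    values = {"A": 1.0, "B": 1.0, "T": 0.0, "lonely": 0.3}
    assert aggregate_input("T", values, conns) == pytest.approx(0.3)
    assert aggregate_input("lonely", values, conns) == 0.0
    with pytest.raises(KeyError):
        aggregate_input("missing", values, conns)


def test_aggregate_input_matches_dot_product(rng):
    # structure of the sensed-effect aggregation: one positive predictive
    # input, one positive sensory input, two suppressive ones
    weights = [0.8, 0.7, -0.3, -0.6]
    sources = ["PA", "SS(b)", "PO", "EO"]
    conns = [Connection(s, "SR(b)", w) for s, w in zip(sources, weights)]
    for _ in range(20):
        vals = {s: float(rng.uniform(0, 1)) for s in sources}
        vals["SR(b)"] = 0.0
        expected = float(np.dot(weights, [vals[s] for s in sources]))
        assert aggregate_input("SR(b)", vals, conns) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _chain_model(**kwargs):
    states = [
        StateSpec("A", "external", 1.5, 0.1, initial_value=1.0),
        StateSpec("B", "internal", 2.0, 0.2),
        StateSpec("C", "internal", 2.5, 0.3),
    ]
    conns = [Connection("A", "B", 0.8), Connection("B", "C", 0.8)]
    return NetworkModel(states, conns, **kwargs)


def test_euler_step_zero_speed_is_identity():
    model = _chain_model(speed_slow=0.0, speed_fast=0.0)
    values = {"A": 1.0, "B": 0.4, "C": 0.2}
    assert euler_step(model, values) == values


def test_euler_step_fixed_point_is_unchanged():
    model = _chain_model()
    g_b = logistic_threshold(2.0, 0.2, 0.8 * 1.0)
    values = {"A": 0.0, "B": g_b, "C": 0.5}
    # A has no input: moves toward 0; B sits exactly at its target
    nxt = euler_step(model, {"A": 1.0, "B": g_b, "C": 0.5})
    assert nxt["B"] == pytest.approx(g_b, abs=1e-12)


def test_chain_matches_scalar_oracle_stepwise():
    model = _chain_model()
    values = {"A": 1.0, "B": 0.0, "C": 0.0}
    for _ in range(10):
        expected = oracle_step(
            model.states, model.connections, values, model.speed_slow,
            model.speed_fast, model.dt,
        )
        values = euler_step(model, values)
        for name in values:
            assert values[name] == pytest.approx(expected[name], abs=1e-12)


def test_simulate_flat_zero_for_zero_network():
    states = [StateSpec(f"S{i}", "internal", 1.0, 0.0) for i in range(3)]
    conns = [Connection("S0", "S1", 0.0)]
    trace = simulate(NetworkModel(states, conns), horizon=10)
    assert len(trace.times) == 41
    for name in trace.names:
        assert np.all(trace[name] == 0.0)


def test_simulate_identity_self_loop_persists():
    # a world state held by its unit self-connection stays at 1 for the
    # whole horizon when nothing suppresses it
    states = [StateSpec("WS", "external", 1.0, 0.01, 1.0, combination="identity")]
    conns = [Connection("WS", "WS", 1.0)]
    trace = simulate(NetworkModel(states, conns), horizon=50)
    assert np.all(trace["WS"] == 1.0)


def test_simulate_is_deterministic():
    model = _chain_model()
    t1 = simulate(model, {"A": 1.0}, horizon=30)
    t2 = simulate(model, {"A": 1.0}, horizon=30)
    for name in t1.names:
        assert np.array_equal(t1[name], t2[name])


def test_zero_input_state_decays_monotonically():
    states = [StateSpec("A", "internal", 2.0, 0.2, initial_value=0.9)]
    trace = simulate(NetworkModel(states, []), horizon=40)
    series = trace["A"]
    assert np.all(np.diff(series) <= 0)
    assert series[-1] < 1e-3


def test_simulate_validates_inputs():
    model = _chain_model()
    with pytest.raises(NetworkError):
        simulate(model, horizon=0)
    with pytest.raises(NetworkError):
        simulate(model, {"nope": 1.0}, horizon=10)
    with pytest.raises(NetworkError):
        simulate(model, {"A": 1.5}, horizon=10)


# ---------------------------------------------------------------------------
# model validation
# ---------------------------------------------------------------------------

def test_model_rejects_bad_structure():
    a, b = StateSpec("A"), StateSpec("B")
    with pytest.raises(NetworkError):
        NetworkModel([a, StateSpec("A")], [])
    with pytest.raises(NetworkError):
        NetworkModel([a, b], [Connection("A", "Z", 0.5)])
    with pytest.raises(NetworkError):
        NetworkModel([a, b], [Connection("A", "B", 0.5), Connection("A", "B", 0.2)])
    with pytest.raises(NetworkError):
        NetworkModel([a, b], [], speed_slow=0.9, speed_fast=0.5)
    with pytest.raises(NetworkError):
        Connection("A", "B", 1.5)
    with pytest.raises(NetworkError):
        StateSpec("A", steepness=-1.0)


def test_trace_alignment_invariant():
    with pytest.raises(NetworkError):
        Trace(times=np.arange(3) * 0.25, values={"A": np.zeros(4)})


# ---------------------------------------------------------------------------
# property: engine equals the scalar oracle on random small networks
# ---------------------------------------------------------------------------

@st.composite
def small_networks(draw):
    n = draw(st.integers(2, 5))
    names = [f"S{i}" for i in range(n)]
    states = [
        StateSpec(
            name,
            draw(st.sampled_from(["internal", "external"])),
            draw(st.floats(0.5, 8.0)),
            draw(st.floats(0.0, 2.0)),
            draw(st.floats(0.0, 1.0)),
            draw(st.sampled_from(["logistic", "logistic", "identity"])),
        )
        for name in names
    ]
    pairs = [(a, b) for a in names for b in names]
    k = draw(st.integers(1, min(8, len(pairs))))
    chosen = draw(
        st.lists(st.sampled_from(pairs), min_size=k, max_size=k, unique=True)
    )
    conns = [
        Connection(a, b, draw(st.floats(-1.0, 1.0))) for a, b in chosen
    ]
    slow = draw(st.floats(0.0, 1.0))
    fast = draw(st.floats(0.0, 1.0))
    slow, fast = min(slow, fast), max(slow, fast)
    return NetworkModel(states, conns, speed_slow=slow, speed_fast=fast)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(small_networks())
def test_engine_matches_scalar_oracle(model):
    values = {s.name: s.initial_value for s in model.states}
    trace = simulate(model, horizon=50 * model.dt)
    for step in range(50):
        values = oracle_step(
            model.states, model.connections, values, model.speed_slow,
            model.speed_fast, model.dt,
        )
        for name, expected in values.items():
            assert trace[name][step + 1] == pytest.approx(expected, abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(small_networks())
def test_trace_boundedness(model):
    trace = simulate(model, horizon=30)
    for name in trace.names:
        assert np.all((trace[name] >= 0.0) & (trace[name] <= 1.0))
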