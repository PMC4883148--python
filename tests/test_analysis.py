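"""Feature-extraction and constraint tests on synthetic series."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from awarenet.analysis import (
    QualitativeConstraint,
    binding_gap,
    check,
    dip,
    features,
    onset,
    peak,
)
from awarenet.network import Trace


def make_trace(**series):
    n = len(next(iter(series.values())))
    return Trace(
        times=np.arange(n) * 0.25,
        values={k: np.asarray(v, dtype=float) for k, v in series.items()},
    )


# ---------------------------------------------------------------------------
# peak / onset / dip
# ---------------------------------------------------------------------------

def test_peak_constant_series_ties_to_earliest():
    trace = make_trace(A=[0.3] * 8)
    assert peak(trace, "A") == (0.3, 0.0)


def test_peak_triangle_matches_exhaustive_scan(rng):
    values = np.concatenate([np.linspace(0, 0.9, 12), np.linspace(0.9, 0, 12)])
    trace = make_trace(A=values)
    v, t = peak(trace, "A")
    best = max(range(len(values)), key=lambda i: values[i])
    assert (v, t) == (values[best], trace.times[best])


def test_peak_unknown_state_raises():
    with pytest.raises(KeyError):
        peak(make_trace(A=[0.0]), "B")


def test_onset_examples():
    assert onset(make_trace(A=[0.0] * 10), "A") is None
    step = [0.0] * 12 + [0.5] * 4
    assert onset(make_trace(A=step), "A") == pytest.approx(12 * 0.25)
    assert onset(make_trace(A=[0.005, 0.02, 0.5]), "A", threshold=0.01) == 0.25


def test_dip_examples():
    rise_fall = np.concatenate([np.linspace(0, 0.8, 10), np.linspace(0.8, 0, 10)])
    assert dip(make_trace(A=rise_fall), "A") is None
    # two bumps with a known valley: 0.15 peak, 0.05 valley, 0.59 peak
    two = np.concatenate([
        np.linspace(0, 0.15, 8), np.linspace(0.15, 0.05, 8),
        np.linspace(0.05, 0.59, 10), np.linspace(0.59, 0, 10),
    ])
    assert dip(make_trace(A=two), "A") == pytest.approx(0.10, abs=1e-9)


def test_dip_requires_second_peak_higher():
    # second bump lower than the first: not the predicted-then-sensed shape
    two = np.concatenate([
        np.linspace(0, 0.6, 8), np.linspace(0.6, 0.2, 8),
        np.linspace(0.2, 0.4, 8), np.linspace(0.4, 0, 8),
    ])
    assert dip(make_trace(A=two), "A") is None


def test_features_bundle():
    series = [0.0, 0.0, 0.2, 0.6, 0.4]
    f = features(make_trace(A=series), "A")
    assert f.peak_value == 0.6
    assert f.peak_time == 3 * 0.25
    assert f.onset_time == 2 * 0.25
    assert f.dip_depth is None


# ---------------------------------------------------------------------------
# binding gap
# ---------------------------------------------------------------------------

def test_binding_gap_hand_placed_onsets():
    ea = [0.0, 0.5, 1.0, 0.5, 0.2, 0.1, 0.0, 0.0]
    outcome = [0.0] * 6 + [0.4, 0.5]
    trace = make_trace(EA=ea, F=outcome)
    # execution lifts at sample 1 (t=0.25); outcome lifts at sample 6 (t=1.5)
    assert binding_gap(trace, "EA", "F") == pytest.approx(1.25)
    # a pre-existing outcome clamps to zero
    pre = make_trace(EA=[0.0, 0.0, 0.5, 1.0], F=[0.3, 0.4, 0.5, 0.5])
    assert binding_gap(pre, "EA", "F") == 0.0


def test_binding_gap_equal_for_identical_traces():
    ea = [0.0, 0.2, 0.9, 0.4, 0.0, 0.0]
    f = [0.0, 0.0, 0.0, 0.3, 0.6, 0.2]
    t1 = make_trace(EA=ea, F=f)
    t2 = make_trace(EA=list(ea), F=list(f))
    assert binding_gap(t1, "EA", "F") == binding_gap(t2, "EA", "F")


def test_binding_gap_absent_outcome():
    trace = make_trace(EA=[0.0, 0.9, 0.1], F=[0.0, 0.0, 0.0])
    assert binding_gap(trace, "EA", "F") is None


# ---------------------------------------------------------------------------
# invariance and oracle properties
# ---------------------------------------------------------------------------

@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    arrays(float, st.integers(3, 40), elements=st.floats(0, 1, width=16)),
    st.integers(1, 30),
)
def test_features_invariant_under_trailing_zeros(values, pad):
    if float(np.max(values)) == 0.0:
        return
    # a settled trace already ends at rest; appending more zeros must not
    # change any feature
    values = np.concatenate([values, np.zeros(2)])
    base = make_trace(A=values)
    padded = make_trace(A=np.concatenate([values, np.zeros(pad)]))
    assert peak(base, "A") == peak(padded, "A")
    assert onset(base, "A") == onset(padded, "A")
    d1, d2 = dip(base, "A"), dip(padded, "A")
    if d1 is not None:
        assert d2 == pytest.approx(d1)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(arrays(float, st.integers(2, 60), elements=st.floats(0, 1, width=16)))
def test_peak_and_onset_match_exhaustive_scan(values):
    trace = make_trace(A=values)
    v, t = peak(trace, "A")
    assert v == max(values)
    assert t == trace.times[list(values).index(max(values))]
    crossing = [i for i, x in enumerate(values) if x >= 0.01]
    expected = trace.times[crossing[0]] if crossing else None
    assert onset(trace, "A") == expected


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

def test_ordering_constraint_passes_and_fails():
    trace = make_trace(
        A=[0.0, 0.5, 0.5, 0.5, 0.5],
        B=[0.0, 0.0, 0.6, 0.6, 0.6],
    )
    forward = QualitativeConstraint("ordering", ("onset:A", "onset:B"))
    inverted = QualitativeConstraint("ordering", ("onset:B", "onset:A"))
    assert forward.evaluate(trace).passed
    result = inverted.evaluate(trace)
    assert not result.passed
    assert result.violation > 0


def test_bound_and_absent_constraints():
    trace = make_trace(A=[0.0, 0.3, 0.6, 0.2], B=[0.0, 0.0, 0.0, 0.005])
    assert QualitativeConstraint("upper_bound", ("A",), {"value": 0.7}).evaluate(trace).passed
    low = QualitativeConstraint("upper_bound", ("A",), {"value": 0.5}).evaluate(trace)
    assert not low.passed and low.violation == pytest.approx(0.1)
    assert QualitativeConstraint("lower_bound", ("A",), {"value": 0.5}).evaluate(trace).passed
    assert QualitativeConstraint("absent", ("B",)).evaluate(trace).passed
    assert not QualitativeConstraint("absent", ("A",)).evaluate(trace).passed


def test_bimodal_constraint():
    two = np.concatenate([
        np.linspace(0, 0.15, 8), np.linspace(0.15, 0.05, 8),
        np.linspace(0.05, 0.59, 10), np.linspace(0.59, 0, 10),
    ])
    trace = make_trace(A=two)
    assert QualitativeConstraint("bimodal", ("A",), {"min_depth": 0.05}).evaluate(trace).passed
    assert not QualitativeConstraint("bimodal", ("A",), {"min_depth": 0.2}).evaluate(trace).passed


def test_check_report_aggregates():
    trace = make_trace(A=[0.0, 0.5, 0.5], B=[0.0, 0.0, 0.6])
    report = check(trace, [
        QualitativeConstraint("ordering", ("onset:A", "onset:B")),
        QualitativeConstraint("upper_bound", ("A",), {"value": 0.1}),
    ])
    assert not report.passed
    assert report.n_violated == 1
    assert len(report.to_records()) == 2


def test_unknown_constraint_kind_rejected():
    with pytest.raises(ValueError):
        QualitativeConstraint("sideways", ("A",))
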