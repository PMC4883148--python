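"""Trace analysis: peaks, onsets, dips, binding gaps and constraint checks.

The model is validated against qualitative features of its simulated
traces rather than against numeric time series: when does a state lift
off, how high does it peak, does the sensory representation of the effect
show the two-step (as-if peak, dip, body-loop peak) profile, and in which
order do the predictive and inferential states appear.  This module turns
a :class:`~awarenet.network.Trace` into those features and evaluates
machine-checkable constraints on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .network import Trace

__all__ = [
    "TraceFeature",
    "QualitativeConstraint",
    "ConstraintResult",
    "Report",
    "peak",
    "onset",
    "dip",
    "binding_gap",
    "features",
    "check",
]

#: Default lift-off threshold: first crossing counts as a state's onset.
ONSET_THRESHOLD = 0.01


def peak(trace: Trace, state: str) -> tuple[float, float]:
    """Global maximum of a state's series as ``(value, time)``.

    Ties resolve to the earliest time.
    """
    series = trace[state]
    i = int(np.argmax(series))
    return float(series[i]), float(trace.times[i])


def onset(trace: Trace, state: str, threshold: float = ONSET_THRESHOLD) -> float | None:
    """First model time at which the state reaches ``threshold``; None if never."""
    series = trace[state]
    hits = np.nonzero(series >= threshold)[0]
    if hits.size == 0:
        return None
    return float(trace.times[hits[0]])


def _median3(series: np.ndarray) -> np.ndarray:
    if len(series) < 3:
        return series.copy()
    out = series.copy()
    stacked = np.stack([series[:-2], series[1:-1], series[2:]])
    out[1:-1] = np.median(stacked, axis=0)
    return out


def _extrema(series: np.ndarray) -> list[tuple[int, int]]:
    """Alternating strict local extrema of ``series`` as (index, sign) with
    sign +1 for a maximum and -1 for a minimum; plateaus are compressed."""
    keep = np.nonzero(np.r_[True, np.diff(series) != 0])[0]
    comp = series[keep]
    out = []
    for p in range(1, len(comp) - 1):
        if comp[p] > comp[p - 1] and comp[p] > comp[p + 1]:
            out.append((int(keep[p]), +1))
        elif comp[p] < comp[p - 1] and comp[p] < comp[p + 1]:
            out.append((int(keep[p]), -1))
    return out


def dip(trace: Trace, state: str, min_depth: float = 0.0) -> float | None:
    """Depth of the first max-min-higher-max triple, or None if unimodal.

    The series is smoothed with a 3-sample moving median to ignore
    step-level jitter, then scanned for a local maximum followed by a
    local minimum followed by a higher local maximum (the series' final
    point counts as that second maximum when the trace ends on a rise).
    Returns first-maximum minus minimum when that depth exceeds
    ``min_depth``.
    """
    series = _median3(np.asarray(trace[state], dtype=float))
    ext = _extrema(series)
    maxima = [i for i, s in ext if s > 0]
    minima = [i for i, s in ext if s < 0]
    for m1 in maxima:
        for mn in minima:
            if mn <= m1:
                continue
            later = series[mn + 1 :]
            if later.size and float(np.max(later)) > series[m1]:
                depth = float(series[m1] - series[mn])
                if depth > min_depth:
                    return depth
            break  # only the first min after this max can close the triple
    return None


def binding_gap(
    trace: Trace,
    execution_state: str,
    outcome_state: str,
    threshold: float = ONSET_THRESHOLD,
) -> float | None:
    """Delay from action execution to the perceived sensory outcome.

    Measured as the onset of the outcome state (typically the feeling of,
    or awareness of, the sensed effect) minus the onset of the execution
    state, clamped below at 0: an outcome that was already present when
    the action started (a pre-existing prediction/awareness) gives gap 0,
    an outcome that only develops after execution gives a positive gap.
    None when either state never lifts off.
    """
    t_exec = onset(trace, execution_state, threshold=ONSET_THRESHOLD)
    t_outcome = onset(trace, outcome_state, threshold=threshold)
    if t_exec is None or t_outcome is None:
        return None
    return float(max(0.0, t_outcome - t_exec))


def features(trace: Trace, state: str) -> "TraceFeature":
    """All scalar features of one state's series."""
    value, t = peak(trace, state)
    return TraceFeature(
        state=state,
        peak_value=value,
        peak_time=t,
        onset_time=onset(trace, state),
        dip_depth=dip(trace, state),
    )


@dataclass(frozen=True)
class TraceFeature:
    state: str
    peak_value: float
    peak_time: float
    onset_time: float | None
    dip_depth: float | None


# ---------------------------------------------------------------------------
# Qualitative constraints
# ---------------------------------------------------------------------------

def _event_time(trace: Trace, subject: str, threshold: float) -> float | None:
    """Time of an 'onset:STATE' or 'peak:STATE' subject."""
    if ":" not in subject:
        raise ValueError(f"ordering subject {subject!r} needs an 'onset:' or 'peak:' prefix")
    kind, state = subject.split(":", 1)
    if kind == "onset":
        return onset(trace, state, threshold)
    if kind == "peak":
        return peak(trace, state)[1]
    raise ValueError(f"unknown event kind {kind!r} in {subject!r}")


@dataclass(frozen=True)
class ConstraintResult:
    constraint: "QualitativeConstraint"
    passed: bool
    measured: object
    violation: float  # 0 when satisfied; magnitude of the breach otherwise

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        return f"[{status}] {self.constraint.describe()}  measured={self.measured}"


@dataclass(frozen=True)
class QualitativeConstraint:
    """A machine-checkable statement about a trace.

    kinds
    -----
    ordering:
        ``subjects`` are event labels ``"onset:STATE"`` / ``"peak:STATE"``
        whose times must be strictly increasing.
    upper_bound / lower_bound:
        the single subject state's peak value must stay below / reach
        ``parameters["value"]``.
    absent:
        the subject state never lifts off (peak below the onset threshold).
    bimodal:
        the subject state shows a dip between two maxima of depth at least
        ``parameters.get("min_depth", 0.01)``.
    """

    kind: str
    subjects: tuple[str, ...]
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("ordering", "upper_bound", "lower_bound", "absent", "bimodal"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        object.__setattr__(self, "subjects", tuple(self.subjects))

    def describe(self) -> str:
        if self.kind == "ordering":
            return " < ".join(self.subjects)
        if self.kind in ("upper_bound", "lower_bound"):
            op = "<=" if self.kind == "upper_bound" else ">="
            return f"peak {self.subjects[0]} {op} {self.parameters['value']}"
        if self.kind == "absent":
            return f"{self.subjects[0]} never develops"
        return f"{self.subjects[0]} is bimodal (as-if peak, dip, body-loop peak)"

    def evaluate(self, trace: Trace) -> ConstraintResult:
        thr = self.parameters.get("threshold", ONSET_THRESHOLD)
        if self.kind == "ordering":
            times = [_event_time(trace, s, thr) for s in self.subjects]
            if any(t is None for t in times):
                missing = [s for s, t in zip(self.subjects, times) if t is None]
                return ConstraintResult(self, False, times, float(len(missing)))
            overlap = sum(
                max(0.0, a - b) for a, b in zip(times, times[1:])
            )
            strict = all(a < b for a, b in zip(times, times[1:]))
            return ConstraintResult(self, strict, times, overlap if not strict else 0.0)
        state = self.subjects[0]
        if self.kind == "upper_bound":
            value, _ = peak(trace, state)
            bound = self.parameters["value"]
            return ConstraintResult(self, value <= bound, value, max(0.0, value - bound))
        if self.kind == "lower_bound":
            value, _ = peak(trace, state)
            bound = self.parameters["value"]
            return ConstraintResult(self, value >= bound, value, max(0.0, bound - value))
        if self.kind == "absent":
            value, _ = peak(trace, state)
            return ConstraintResult(self, value < thr, value, max(0.0, value - thr))
        # bimodal
        min_depth = self.parameters.get("min_depth", 0.01)
        depth = dip(trace, state, min_depth=0.0)
        ok = depth is not None and depth >= min_depth
        violation = min_depth if depth is None else max(0.0, min_depth - depth)
        return ConstraintResult(self, ok, depth, 0.0 if ok else violation)


@dataclass
class Report:
    """Per-constraint pass/fail with measured values."""

    results: list[ConstraintResult]

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.results)

    @property
    def n_violated(self) -> int:
        return sum(not r.passed for r in self.results)

    @property
    def total_violation(self) -> float:
        return float(sum(r.violation for r in self.results))

    def to_records(self) -> list[dict]:
        return [
            {
                "kind": r.constraint.kind,
                "constraint": r.constraint.describe(),
                "passed": r.passed,
                "measured": r.measured,
                "violation": r.violation,
            }
            for r in self.results
        ]

    def __str__(self) -> str:
        return "\n".join(str(r) for r in self.results)


def check(trace: Trace, constraints: Iterable[QualitativeConstraint]) -> Report:
    """Evaluate every constraint on the trace."""
    return Report([c.evaluate(trace) for c in constraints])
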