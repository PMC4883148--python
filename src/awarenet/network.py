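"""Generic temporal-causal network engine.

A network is a set of named states coupled by weighted directed
connections.  Each state carries an activation level in [0, 1] that is
updated in discrete time: the incoming activations are aggregated into a
signed weighted sum, passed through a combination function (a normalised
logistic threshold by default), and the state moves toward that target at
a speed set by its category::

    y_i(t + dt) = y_i(t) + gamma_i * (g(sigma_i, tau_i, sum_j w_ji y_j) - y_i(t)) * dt

Internal (cognitive) states use the fast speed factor, external
(world/sensor/effector) states the slow one.  The engine is fully
deterministic and agnostic of any particular cognitive architecture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "StateSpec",
    "Connection",
    "NetworkModel",
    "Trace",
    "logistic_threshold",
    "aggregate_input",
    "euler_step",
    "simulate",
    "NetworkError",
    "SimulationDiverged",
]

#: Activation below which a state counts as quiescent for early stopping.
QUIESCENT = 1e-4

CATEGORIES = ("external", "internal")
COMBINATIONS = ("logistic", "identity")
LOGISTIC_VARIANTS = ("corrected", "as_printed")


class NetworkError(ValueError):
    """Invalid network structure or parameters."""


class SimulationDiverged(RuntimeError):
    """A non-finite activation appeared during integration."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateSpec:
    """One network node and its activation parameters.

    Parameters
    ----------
    name:
        Structured label, e.g. ``"PA(a1)"`` or ``"PAwr(a1,b1,c1,s1)"``.
    category:
        ``"external"`` (world, sensor and effector states; slow speed
        factor) or ``"internal"`` (cognitive states; fast speed factor).
    steepness:
        Logistic steepness sigma > 0.
    threshold:
        Logistic threshold tau >= 0, in activation units.
    initial_value:
        Activation at t = 0, in [0, 1].
    combination:
        ``"logistic"`` applies the threshold function to the aggregated
        input; ``"identity"`` uses the raw weighted sum as the target
        (useful for world states that should hold their value through a
        unit self-connection until actively suppressed).
    """

    name: str
    category: str = "internal"
    steepness: float = 1.0
    threshold: float = 0.0
    initial_value: float = 0.0
    combination: str = "logistic"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise NetworkError(f"{self.name}: unknown category {self.category!r}")
        if self.combination not in COMBINATIONS:
            raise NetworkError(f"{self.name}: unknown combination {self.combination!r}")
        if self.steepness <= 0:
            raise NetworkError(f"{self.name}: steepness must be > 0, got {self.steepness}")
        if self.threshold < 0:
            raise NetworkError(f"{self.name}: threshold must be >= 0, got {self.threshold}")
        if not 0.0 <= self.initial_value <= 1.0:
            raise NetworkError(
                f"{self.name}: initial value must lie in [0, 1], got {self.initial_value}"
            )


@dataclass(frozen=True)
class Connection:
    """A directed weighted causal link between two states.

    The weight lies in [-1, +1]; a negative weight makes the connection
    suppressive (it contributes negatively to the target's aggregated
    input, before the combination function is applied).
    """

    source: str
    target: str
    weight: float
    label: str = ""

    def __post_init__(self) -> None:
        if not -1.0 <= self.weight <= 1.0:
            raise NetworkError(
                f"connection {self.source} -> {self.target}: weight must lie in "
                f"[-1, +1], got {self.weight}"
            )

    @property
    def negative_flag(self) -> bool:
        """True iff the connection is suppressive."""
        return self.weight < 0


@dataclass
class NetworkModel:
    """A complete temporal-causal network.

    Holds the states, the connections, the two global speed factors
    (``speed_fast >= speed_slow``) and the integration step ``dt``.
    """

    states: Sequence[StateSpec]
    connections: Sequence[Connection]
    speed_slow: float = 0.6
    speed_fast: float = 0.7
    dt: float = 0.25
    logistic_variant: str = "corrected"
    _compiled: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [s.name for s in self.states]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise NetworkError(f"duplicate state names: {dup}")
        known = set(names)
        seen_pairs = set()
        for c in self.connections:
            if c.source not in known or c.target not in known:
                raise NetworkError(
                    f"connection {c.source} -> {c.target} references an unknown state"
                )
            pair = (c.source, c.target)
            if pair in seen_pairs:
                raise NetworkError(f"duplicate connection {c.source} -> {c.target}")
            seen_pairs.add(pair)
        if not 0.0 <= self.speed_slow <= 1.0 or not 0.0 <= self.speed_fast <= 1.0:
            raise NetworkError("speed factors must lie in [0, 1]")
        if self.speed_fast < self.speed_slow:
            raise NetworkError("internal states must be at least as fast as external ones")
        if self.dt <= 0:
            raise NetworkError("dt must be positive")
        if self.logistic_variant not in LOGISTIC_VARIANTS:
            raise NetworkError(f"unknown logistic variant {self.logistic_variant!r}")
        self._compiled = None

    # -- array compilation ---------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.states]

    def _compile(self) -> dict:
        if self._compiled is None:
            idx = {s.name: i for i, s in enumerate(self.states)}
            n = len(self.states)
            W = np.zeros((n, n))
            for c in self.connections:
                W[idx[c.source], idx[c.target]] = c.weight
            self._compiled = {
                "index": idx,
                "W": W,
                "sigma": np.array([s.steepness for s in self.states]),
                "tau": np.array([s.threshold for s in self.states]),
                "gamma": np.array(
                    [
                        self.speed_fast if s.category == "internal" else self.speed_slow
                        for s in self.states
                    ]
                ),
                "identity": np.array(
                    [s.combination == "identity" for s in self.states]
                ),
                "y0": np.array([s.initial_value for s in self.states]),
            }
        return self._compiled

    def with_weights(self, weights: Mapping[tuple[str, str], float]) -> "NetworkModel":
        """Return a copy with the given (source, target) weights replaced."""
        new = [
            replace(c, weight=weights[(c.source, c.target)])
            if (c.source, c.target) in weights
            else c
            for c in self.connections
        ]
        missing = set(weights) - {(c.source, c.target) for c in self.connections}
        if missing:
            raise NetworkError(f"no such connections: {sorted(missing)}")
        return NetworkModel(
            states=self.states,
            connections=new,
            speed_slow=self.speed_slow,
            speed_fast=self.speed_fast,
            dt=self.dt,
            logistic_variant=self.logistic_variant,
        )


@dataclass
class Trace:
    """Time-indexed activations of every state over one simulation."""

    times: np.ndarray
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, series in self.values.items():
            if len(series) != len(self.times):
                raise NetworkError(f"series {name!r} does not align with the time grid")

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.values[name]
        except KeyError:
            raise KeyError(
                f"state {name!r} not in trace; available: {sorted(self.values)}"
            ) from None

    @property
    def names(self) -> list[str]:
        return list(self.values)

    def to_frame(self):
        """Return the trace as a pandas DataFrame with a ``time`` column."""
        import pandas as pd

        data = {"time": self.times}
        data.update(self.values)
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame) -> "Trace":
        cols = list(frame.columns)
        if not cols or cols[0] != "time":
            raise NetworkError("trace table must start with a 'time' column")
        return cls(
            times=frame["time"].to_numpy(dtype=float),
            values={c: frame[c].to_numpy(dtype=float) for c in cols[1:]},
        )


# ---------------------------------------------------------------------------
# Combination function
# ---------------------------------------------------------------------------

def logistic_threshold(sigma, tau, x, variant: str = "corrected"):
    """Normalised logistic threshold combination function g(sigma, tau, x).

    Returns 0 for x <= 0 and, for x > 0,

        g = (1 / (1 + exp(-sigma (x - tau))) - 1 / (1 + exp(sigma tau))) * N

    where the normalisation N is ``1 + exp(-sigma tau)`` for the default
    ``"corrected"`` variant, which makes g continuous at 0 and g -> 1 as
    x -> inf, or ``1 + exp(sigma tau)`` for the ``"as_printed"`` variant
    (not bounded by 1; kept for comparison only).

    Accepts scalars or numpy arrays (broadcasting elementwise).
    """
    sigma = np.asarray(sigma, dtype=float)
    tau = np.asarray(tau, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(sigma <= 0):
        raise NetworkError("steepness sigma must be > 0")
    if np.any(tau < 0):
        raise NetworkError("threshold tau must be >= 0")
    if variant not in LOGISTIC_VARIANTS:
        raise NetworkError(f"unknown logistic variant {variant!r}")

    st = sigma * tau
    base = 1.0 / (1.0 + np.exp(np.clip(-sigma * (x - tau), -700, 700)))
    offset = 1.0 / (1.0 + np.exp(np.clip(st, None, 700)))
    norm = 1.0 + np.exp(np.clip(-st if variant == "corrected" else st, None, 700))
    out = np.where(x > 0, (base - offset) * norm, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Aggregation and integration
# ---------------------------------------------------------------------------

def aggregate_input(
    target: str,
    current_values: Mapping[str, float],
    connections: Iterable[Connection],
) -> float:
    """Signed weighted sum of the source activations feeding ``target``."""
    if target not in current_values:
        raise KeyError(f"unknown target state {target!r}")
    return float(
        sum(c.weight * current_values[c.source] for c in connections if c.target == target)
    )


def _step_arrays(model: NetworkModel, y: np.ndarray) -> np.ndarray:
    c = model._compile()
    agg = y @ c["W"]
    target = logistic_threshold(c["sigma"], c["tau"], agg, model.logistic_variant)
    target = np.where(c["identity"], agg, target)
    out = y + c["gamma"] * (target - y) * model.dt
    return np.clip(out, 0.0, 1.0)


def euler_step(
    model: NetworkModel, current_values: Mapping[str, float]
) -> dict[str, float]:
    """One discrete update of every state; returns the next value map."""
    c = model._compile()
    missing = [n for n in c["index"] if n not in current_values]
    if missing:
        raise NetworkError(f"current_values misses states: {missing}")
    y = np.array([current_values[n] for n in c["index"]], dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise NetworkError("current activations must lie in [0, 1]")
    nxt = _step_arrays(model, y)
    return {n: float(v) for n, v in zip(c["index"], nxt)}


def simulate(
    model: NetworkModel,
    initial_values: Mapping[str, float] | None = None,
    horizon: float = 120.0,
    stop_when_quiescent: bool = False,
) -> Trace:
    """Integrate the network from t = 0 to ``horizon`` in steps of dt.

    Returns a :class:`Trace` with ``floor(horizon / dt) + 1`` samples
    (fewer when ``stop_when_quiescent`` is set and every activation has
    fallen below ``QUIESCENT``).  Bitwise deterministic for a fixed model.
    """
    if horizon <= 0:
        raise NetworkError("horizon must be positive")
    c = model._compile()
    y = c["y0"].copy()
    if initial_values is not None:
        for name, value in initial_values.items():
            if name not in c["index"]:
                raise NetworkError(f"unknown state {name!r} in initial values")
            if not 0.0 <= value <= 1.0:
                raise NetworkError(f"initial value for {name!r} outside [0, 1]")
            y[c["index"][name]] = value

    n_steps = int(math.floor(horizon / model.dt + 1e-9))
    rows = np.empty((n_steps + 1, len(y)))
    rows[0] = y
    used = n_steps
    for k in range(1, n_steps + 1):
        y = _step_arrays(model, y)
        if not np.all(np.isfinite(y)):  # pragma: no cover - clipping prevents this
            raise SimulationDiverged(f"non-finite activation at step {k}")
        rows[k] = y
        if stop_when_quiescent and np.all(y < QUIESCENT):
            used = k
            break
    rows = rows[: used + 1]
    times = np.arange(used + 1) * model.dt
    names = list(c["index"])
    return Trace(times=times, values={n: rows[:, i].copy() for i, n in enumerate(names)})
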