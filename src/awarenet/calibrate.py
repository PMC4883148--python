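"""Multi-scenario parameter calibration.

The model has no numeric empirical target series, only qualitative
characteristics per scenario (orderings, bounds, presence/absence, the
sensory-representation dip).  Calibration therefore searches for one
generic weight set that satisfies the constraint suites of all scenarios
simultaneously, scenario by scenario: scenario k's constraints are added
only once scenarios 1..k-1 are satisfied, and every search step re-scores
all scenarios admitted so far, so a later scenario can force earlier ones
to be readdressed.  The search itself is a seeded combination of random
restarts and coordinate refinement within the parameter bounds; it is
deterministic for a fixed (problem, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .analysis import QualitativeConstraint, Report, check
from .model import DEFAULT_WEIGHTS
from .scenarios import scenario_config
from .network import simulate

__all__ = [
    "CalibrationProblem",
    "CalibrationResult",
    "CalibrationInfeasible",
    "score",
    "calibrate",
]


class CalibrationInfeasible(ValueError):
    """The declared parameter bounds admit no candidate at all."""


@dataclass
class CalibrationProblem:
    """A constrained search over a named subset of connection weights.

    ``free_parameters`` maps weight labels — a family label such as
    ``"PO->PAwr"``, or an instance-qualified one such as
    ``"PA->SR(b)@2"`` — to (lower, upper) bounds.  ``scenario_constraints``
    gives the per-scenario qualitative suites; scenarios are addressed in
    ascending id order.
    """

    free_parameters: dict[str, tuple[float, float]]
    scenario_constraints: dict[int, list[QualitativeConstraint]]
    budget: int = 300
    seed: int = 0
    start: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.free_parameters.items():
            fam = name.split("@", 1)[0]
            if fam not in DEFAULT_WEIGHTS:
                raise ValueError(f"free parameter {name!r} names no weight family")
            if lo > hi:
                raise CalibrationInfeasible(
                    f"bounds for {name!r} are empty: [{lo}, {hi}]"
                )
            if lo < -1.0 or hi > 1.0:
                raise ValueError(f"bounds for {name!r} leave [-1, +1]")
        for sid in self.scenario_constraints:
            if not 1 <= sid <= 8:
                raise ValueError(f"unknown scenario id {sid}")

    def start_point(self) -> dict[str, float]:
        """Starting candidate: explicit start, else the shipped generic set
        (clipped into the bounds)."""
        out = {}
        for name, (lo, hi) in self.free_parameters.items():
            fam = name.split("@", 1)[0]
            base = DEFAULT_WEIGHTS[fam] if self.start is None else self.start.get(
                name, DEFAULT_WEIGHTS[fam]
            )
            out[name] = float(min(max(base, lo), hi))
        return out


@dataclass
class CalibrationResult:
    parameter_values: dict[str, float]
    reports: dict[int, Report]
    satisfied: bool
    evaluations: int

    @property
    def n_violated(self) -> int:
        return sum(r.n_violated for r in self.reports.values())


def _trace_with(parameters: Mapping[str, float], scenario_id: int):
    """Run a scenario with candidate weights folded into its baseline.

    Family-level parameters replace the generic weight; scenario-specific
    overrides (the published per-scenario changes) are applied afterwards
    and always win.
    """
    from .model import apply_overrides, build_model

    config = scenario_config(scenario_id)
    family = {k: v for k, v in parameters.items() if "@" not in k}
    instance = {k: v for k, v in parameters.items() if "@" in k}
    config.template.weights.update(family)
    model = build_model(config.template)
    if instance:
        model = apply_overrides(model, instance)
    model = apply_overrides(model, config.overrides)
    initial = {name: 1.0 for name in config.initial_inputs}
    return simulate(model, initial_values=initial, horizon=config.horizon)


def score(
    parameters: Mapping[str, float],
    problem: CalibrationProblem,
    scenario_ids: Sequence[int] | None = None,
) -> tuple[int, float]:
    """Lexicographic score (violated count, total violation magnitude)."""
    n_violated = 0
    magnitude = 0.0
    for sid in sorted(scenario_ids or problem.scenario_constraints):
        trace = _trace_with(parameters, sid)
        report = check(trace, problem.scenario_constraints[sid])
        n_violated += report.n_violated
        magnitude += report.total_violation
    return n_violated, float(magnitude)


def _reports(parameters: Mapping[str, float], problem: CalibrationProblem):
    return {
        sid: check(_trace_with(parameters, sid), problem.scenario_constraints[sid])
        for sid in sorted(problem.scenario_constraints)
    }


def calibrate(problem: CalibrationProblem) -> CalibrationResult:
    """Incremental scenario-by-scenario constraint satisfaction.

    Returns the best candidate found within the evaluation budget, flagged
    ``satisfied`` when every constraint of every scenario passes.  With no
    free parameters the shipped set is simply evaluated and returned.
    """
    rng = np.random.default_rng(problem.seed)
    names = sorted(problem.free_parameters)
    bounds = problem.free_parameters
    current = problem.start_point()
    evaluations = 0

    if not names:
        reports = _reports(current, problem)
        satisfied = all(r.passed for r in reports.values())
        return CalibrationResult(current, reports, satisfied, 1)

    def evaluate(cand, active):
        nonlocal evaluations
        evaluations += 1
        return score(cand, problem, active)

    active: list[int] = []
    best = dict(current)
    best_score = (0, 0.0)
    for sid in sorted(problem.scenario_constraints):
        active.append(sid)
        best_score = evaluate(best, active)
        if best_score == (0, 0.0):
            continue
        # coordinate refinement with seeded random restarts, re-scoring all
        # scenarios admitted so far
        step = {n: 0.25 * (bounds[n][1] - bounds[n][0]) for n in names}
        while evaluations < problem.budget and best_score > (0, 0.0):
            improved = False
            for name in names:
                lo, hi = bounds[name]
                for delta in (-step[name], step[name]):
                    cand = dict(best)
                    cand[name] = float(min(max(cand[name] + delta, lo), hi))
                    if cand[name] == best[name]:
                        continue
                    s = evaluate(cand, active)
                    if s < best_score:
                        best, best_score = cand, s
                        improved = True
                    if evaluations >= problem.budget or best_score == (0, 0.0):
                        break
                if evaluations >= problem.budget or best_score == (0, 0.0):
                    break
            if best_score == (0, 0.0) or evaluations >= problem.budget:
                break
            if not improved:
                if all(s < 1e-3 for s in step.values()):
                    # local refinement exhausted: seeded random restart
                    cand = {
                        n: float(rng.uniform(bounds[n][0], bounds[n][1]))
                        for n in names
                    }
                    s = evaluate(cand, active)
                    if s < best_score:
                        best, best_score = cand, s
                    step = {
                        n: 0.25 * (bounds[n][1] - bounds[n][0]) for n in names
                    }
                else:
                    step = {n: s / 2 for n, s in step.items()}
        if best_score > (0, 0.0):
            break  # budget exhausted; report the best found so far

    reports = _reports(best, problem)
    satisfied = all(r.passed for r in reports.values())
    return CalibrationResult(best, reports, satisfied, evaluations)
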