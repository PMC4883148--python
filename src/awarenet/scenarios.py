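"""The eight shipped simulation scenarios.

Each scenario is the generic parameter set plus a handful of weight
overrides (most change one or two connections) and an input schedule:

1. normal execution with ownership and both awareness states (baseline)
2. execution with ownership but no awareness (awareness inputs zeroed)
3. unsatisfactory predicted effect: the prepared action is vetoed
4. poor feeling of a correct prediction (schizophrenia-like): execution
   without adequate retrospective states
5. two competing options; the weaker prediction collapses, the winner runs
   the full execute-own-aware-communicate cycle and stops all inputs
6. as 5, but the winner stops only its own inputs, so the loser executes
   afterwards
7. predicted effect b1 vs actual effect b2 (mismatch): strong prior but
   poor retrospective awareness, larger action-outcome binding gap
8. two identical options except for the awareness-to-execution weight: the
   consciously biased (negative-feeling) option wins
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .analysis import QualitativeConstraint
from .model import ModelTemplate, apply_overrides, build_model
from .network import NetworkModel, Trace, simulate

__all__ = [
    "ScenarioConfig",
    "scenario_config",
    "scenario_model",
    "run_scenario",
    "scenario_constraints",
    "SCENARIO_IDS",
]

SCENARIO_IDS = tuple(range(1, 9))

#: Default horizon (model-time units) per scenario; 6 needs room for the
#: second execution cycle.
_HORIZONS = {6: 240}
DEFAULT_HORIZON = 120.0


@dataclass
class ScenarioConfig:
    """A complete runnable experiment."""

    id: int
    template: ModelTemplate
    overrides: dict[str, float] = field(default_factory=dict)
    initial_inputs: tuple[str, ...] = ()
    horizon: float = DEFAULT_HORIZON
    description: str = ""


def _inputs(template: ModelTemplate) -> tuple[str, ...]:
    names = []
    for k in range(1, template.n_stimuli + 1):
        names += [f"WS(s{k})", f"WS(c{k})"]
    return tuple(names)


def scenario_config(scenario_id: int) -> ScenarioConfig:
    """The published configuration for scenario 1..8."""
    if scenario_id not in SCENARIO_IDS:
        raise ValueError(f"scenario id must be in 1..8, got {scenario_id}")

    if scenario_id in (1, 2, 3, 4):
        template = ModelTemplate()
    elif scenario_id in (5, 8):
        template = ModelTemplate(n_options=2, n_stimuli=2, suppression_scope="all")
    elif scenario_id == 6:
        template = ModelTemplate(n_options=2, n_stimuli=2, suppression_scope="own")
    else:  # 7: one action, two effect variants, one stimulus tuple
        template = ModelTemplate(n_options=2, n_stimuli=1, shared_action=True)

    overrides: dict[str, float] = {}
    if scenario_id == 2:
        # remove every positive input into the awareness states
        overrides = {
            "PO->PAwr": 0.0,
            "F->PAwr": 0.0,
            "EA->RAwr": 0.0,
            "F->RAwr": 0.0,
            "PO->RAwr": 0.0,
        }
    elif scenario_id == 3:
        overrides = {"PA->SR(b)": 0.2}
    elif scenario_id == 4:
        overrides = {"SR(b)->F": 0.2}
    elif scenario_id in (5, 6):
        overrides = {"PA->SR(b)@2": 0.6}
    elif scenario_id == 7:
        overrides = {
            # execution produces b2, not the predicted b1
            "EA->WS(b)@1": 0.0,
            "EA->WS(b)@2": 0.5,
            "EO-|WS(b)@1": 0.0,
            "EO-|WS(b)@2": -0.5,
            "WS(b)->SS(b)@2": 0.5,
            # b2 is not predicted: no as-if input, no predictive suppression,
            # and no prior awareness of it
            "PA->SR(b)@2": 0.0,
            "PO-|SR(b)@2": 0.0,
            "PO->PAwr@2": 0.0,
            # no retrospective ownership of the unrealised b1, and the b2
            # column lacks the prior states that would normally feed it
            "EA->RO@1": 0.0,
            "PO->RO@2": 0.0,
            "EA->RAwr@1": 0.0,
            "PAwr->RAwr@2": 0.0,
        }
    elif scenario_id == 8:
        # identical options except the conscious awareness-to-execution bias
        overrides = {"PAwr->EA@1": 0.2, "PAwr->EA@2": 0.8}

    descriptions = {
        1: "normal execution with ownership and awareness",
        2: "execution with ownership but without awareness",
        3: "prepared action lacks satisfactory predicted effects (veto)",
        4: "poor feeling of predicted effects (schizophrenia-like)",
        5: "two competing options; the weaker one collapses",
        6: "two competing options; sequential double execution",
        7: "mismatch between predicted and actual effect",
        8: "awareness-biased selection of the negative-feeling option",
    }
    return ScenarioConfig(
        id=scenario_id,
        template=template,
        overrides=overrides,
        initial_inputs=_inputs(template),
        horizon=_HORIZONS.get(scenario_id, DEFAULT_HORIZON),
        description=descriptions[scenario_id],
    )


def scenario_model(config: ScenarioConfig) -> NetworkModel:
    """Build the scenario's network with its overrides applied."""
    return apply_overrides(build_model(config.template), config.overrides)


def run_scenario(
    scenario: int | ScenarioConfig,
    horizon: float | None = None,
    extra_overrides: dict[str, float] | None = None,
) -> Trace:
    """Simulate a scenario (by id or explicit config) and return its trace."""
    config = scenario_config(scenario) if isinstance(scenario, int) else scenario
    model = scenario_model(config)
    if extra_overrides:
        model = apply_overrides(model, extra_overrides)
    initial = {name: 1.0 for name in config.initial_inputs}
    return simulate(model, initial_values=initial, horizon=horizon or config.horizon)


# ---------------------------------------------------------------------------
# Qualitative constraint suites (the calibration targets)
# ---------------------------------------------------------------------------

_Y1 = "a1,b1,c1,s1"
_Y2 = "a2,b2,c2,s2"
_Y7_1 = "a1,b1,c1,s1"
_Y7_2 = "a1,b2,c1,s1"


def scenario_constraints(scenario_id: int) -> list[QualitativeConstraint]:
    """The qualitative behaviour each scenario must reproduce."""
    C = QualitativeConstraint
    if scenario_id == 1:
        return [
            # predictive states precede execution, inferential states follow
            C("ordering", (
                "onset:PA(a1)",
                f"onset:PO({_Y1})",
                f"onset:PAwr({_Y1})",
                "peak:EA(a1)",
            )),
            C("ordering", (
                f"onset:PAwr({_Y1})",
                f"onset:RO({_Y1})",
                f"onset:RAwr({_Y1})",
                f"peak:EO({_Y1})",
            )),
            C("lower_bound", ("EA(a1)",), {"value": 0.4}),
            C("lower_bound", (f"PAwr({_Y1})",), {"value": 0.4}),
            C("lower_bound", (f"RAwr({_Y1})",), {"value": 0.4}),
            C("lower_bound", (f"EO({_Y1})",), {"value": 0.4}),
            # two-step sigmoid of the sensed effect: as-if peak, dip, body peak
            C("bimodal", ("SR(b1)",), {"min_depth": 0.01}),
        ]
    if scenario_id == 2:
        return [
            C("absent", (f"PAwr({_Y1})",), {"threshold": 0.01}),
            C("absent", (f"RAwr({_Y1})",), {"threshold": 0.01}),
            C("lower_bound", ("EA(a1)",), {"value": 0.2}),
            C("upper_bound", ("EA(a1)",), {"value": 0.6}),
            C("upper_bound", (f"EO({_Y1})",), {"value": 0.1}),
        ]
    if scenario_id == 3:
        return [
            C("upper_bound", ("EA(a1)",), {"value": 0.1}),
            C("upper_bound", (f"RO({_Y1})",), {"value": 0.1}),
            C("upper_bound", (f"EO({_Y1})",), {"value": 0.1}),
            C("upper_bound", ("F(b1)",), {"value": 0.2}),
        ]
    if scenario_id == 4:
        return [
            C("lower_bound", ("EA(a1)",), {"value": 0.4}),
            C("upper_bound", ("F(b1)",), {"value": 0.35}),
            C("upper_bound", (f"RAwr({_Y1})",), {"value": 0.1}),
            C("upper_bound", (f"EO({_Y1})",), {"value": 0.1}),
            C("lower_bound", (f"PAwr({_Y1})",), {"value": 0.3}),
        ]
    if scenario_id == 5:
        return [
            C("lower_bound", ("EA(a1)",), {"value": 0.4}),
            C("absent", ("EA(a2)",), {"threshold": 0.05}),
            C("absent", (f"PAwr({_Y2})",), {"threshold": 0.1}),
            C("lower_bound", (f"EO({_Y1})",), {"value": 0.4}),
        ]
    if scenario_id == 6:
        return [
            C("lower_bound", ("EA(a1)",), {"value": 0.4}),
            C("lower_bound", ("EA(a2)",), {"value": 0.4}),
            C("lower_bound", (f"EO({_Y2})",), {"value": 0.4}),
            # option 2 reaches execution strength only after option 1 has
            # peaked; activation below ~0.1 counts as not executed, so the
            # sequencing is anchored at 0.05
            C("ordering", ("peak:EA(a1)", "onset:EA(a2)"), {"threshold": 0.05}),
        ]
    if scenario_id == 7:
        return [
            C("lower_bound", ("EA(a1)",), {"value": 0.4}),
            C("lower_bound", (f"PAwr({_Y7_1})",), {"value": 0.4}),
            C("upper_bound", (f"PAwr({_Y7_2})",), {"value": 0.1}),
            C("upper_bound", (f"RAwr({_Y7_1})",), {"value": 0.2}),
            C("lower_bound", ("SR(b2)",), {"value": 0.3}),
            C("lower_bound", ("F(b2)",), {"value": 0.3}),
            C("upper_bound", (f"EO({_Y7_1})",), {"value": 0.2}),
        ]
    if scenario_id == 8:
        return [
            C("lower_bound", ("EA(a2)",), {"value": 0.4}),
            C("upper_bound", ("EA(a1)",), {"value": 0.1}),
            C("lower_bound", (f"PAwr({_Y2})",), {"value": 0.4}),
            C("upper_bound", (f"PAwr({_Y1})",), {"value": 0.2}),
            C("lower_bound", (f"RAwr({_Y2})",), {"value": 0.4}),
        ]
    raise ValueError(f"scenario id must be in 1..8, got {scenario_id}")
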