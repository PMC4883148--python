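"""Config files, trace CSV round-tripping and report writers.

Scenario and calibration configs are YAML.  A scenario file either names a
shipped scenario by id or spells out a template, with optional weight and
per-option override maps::

    kind: scenario
    id: 3                      # start from the shipped scenario 3 ...
    overrides: {"SR(b)->F": 0.4}   # ... and change more weights

    kind: calibration
    free_parameters: {"PO->PAwr": [0.0, 1.0]}
    scenarios:
      1:
        - {kind: lower_bound, subjects: ["EA(a1)"], parameters: {value: 0.4}}
    budget: 200
    seed: 7

Traces are written as plain CSV, one column per state, first column the
model time; headers are the structured state labels (``PAwr(a1,b1,c1,s1)``).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .analysis import QualitativeConstraint, Report
from .calibrate import CalibrationProblem
from .model import DEFAULT_WEIGHTS, ModelTemplate
from .network import NetworkError, Trace
from .scenarios import ScenarioConfig, scenario_config

__all__ = [
    "ConfigError",
    "load_config",
    "write_trace",
    "read_trace",
    "write_report",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]


class ConfigError(ValueError):
    """Invalid configuration file; carries the full list of problems."""

    def __init__(self, path, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            f"{path}: {len(self.errors)} problem(s):\n  - " + "\n  - ".join(self.errors)
        )


_TEMPLATE_FIELDS = {
    "n_options",
    "n_stimuli",
    "option_map",
    "shared_action",
    "rawr_parents",
    "suppression_scope",
    "speed_slow",
    "speed_fast",
    "dt",
    "logistic_variant",
}


def _check_weight_map(mapping, errors, where):
    if not isinstance(mapping, dict):
        errors.append(f"{where} must be a mapping of weight labels to numbers")
        return {}
    out = {}
    for key, value in mapping.items():
        fam = str(key).split("@", 1)[0]
        if fam not in DEFAULT_WEIGHTS:
            errors.append(f"{where}: unknown weight label {key!r}")
            continue
        if not isinstance(value, (int, float)):
            errors.append(f"{where}: weight {key!r} must be a number")
            continue
        if not -1.0 <= value <= 1.0:
            errors.append(
                f"{where}: weight {key!r} = {value} outside [-1, +1]"
            )
            continue
        out[str(key)] = float(value)
    return out


def _scenario_from_dict(data: dict, errors: list[str]) -> ScenarioConfig | None:
    config = None
    if "id" in data:
        if data["id"] not in range(1, 9):
            errors.append(f"scenario id must be 1..8, got {data['id']!r}")
            return None
        config = scenario_config(int(data["id"]))
    template_data = data.get("template", {})
    unknown = set(template_data) - _TEMPLATE_FIELDS
    if unknown:
        errors.append(f"unknown template fields: {sorted(unknown)}")
    weights = _check_weight_map(data.get("weights", {}), errors, "weights")
    overrides = _check_weight_map(data.get("overrides", {}), errors, "overrides")
    horizon = data.get("horizon")
    if horizon is not None and (not isinstance(horizon, (int, float)) or horizon <= 0):
        errors.append(f"horizon must be a positive number, got {horizon!r}")
    if errors:
        return None
    if config is None:
        try:
            template = ModelTemplate(
                **{k: v for k, v in template_data.items() if k in _TEMPLATE_FIELDS}
            )
        except NetworkError as exc:
            errors.append(str(exc))
            return None
        config = ScenarioConfig(
            id=0,
            template=template,
            initial_inputs=tuple(
                data.get(
                    "initial_inputs",
                    [
                        f"WS({w}{k})"
                        for k in range(1, template.n_stimuli + 1)
                        for w in ("s", "c")
                    ],
                )
            ),
        )
    else:
        for key, value in template_data.items():
            setattr(config.template, key, value)
    for fam, value in weights.items():
        config.template.weights[fam] = value
    config.overrides = {**config.overrides, **overrides}
    if horizon is not None:
        config.horizon = float(horizon)
    return config


def _calibration_from_dict(data: dict, errors: list[str]) -> CalibrationProblem | None:
    free = {}
    for key, bounds in (data.get("free_parameters") or {}).items():
        fam = str(key).split("@", 1)[0]
        if fam not in DEFAULT_WEIGHTS:
            errors.append(f"free_parameters: unknown weight label {key!r}")
        elif (
            not isinstance(bounds, (list, tuple))
            or len(bounds) != 2
            or not all(isinstance(b, (int, float)) for b in bounds)
        ):
            errors.append(f"free_parameters: bounds for {key!r} must be [lo, hi]")
        else:
            free[str(key)] = (float(bounds[0]), float(bounds[1]))
    suites = {}
    for sid, items in (data.get("scenarios") or {}).items():
        try:
            sid = int(sid)
        except (TypeError, ValueError):
            errors.append(f"scenarios: bad scenario id {sid!r}")
            continue
        constraints = []
        for item in items or []:
            try:
                constraints.append(
                    QualitativeConstraint(
                        kind=item["kind"],
                        subjects=tuple(item["subjects"]),
                        parameters=dict(item.get("parameters", {})),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                errors.append(f"scenarios[{sid}]: bad constraint {item!r} ({exc})")
        suites[sid] = constraints
    if not suites:
        errors.append("calibration config needs at least one scenario suite")
    if errors:
        return None
    return CalibrationProblem(
        free_parameters=free,
        scenario_constraints=suites,
        budget=int(data.get("budget", 300)),
        seed=int(data.get("seed", 0)),
    )


def load_config(path) -> ScenarioConfig | CalibrationProblem:
    """Load and validate a scenario or calibration YAML file.

    All validation problems are collected and reported together in the
    raised :class:`ConfigError`, not just the first.
    """
    path = Path(path)
    errors: list[str] = []
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(path, [f"not valid YAML: {exc}"]) from exc
    if not isinstance(data, dict) or not data:
        raise ConfigError(path, ["file must contain a non-empty mapping"])
    kind = data.get("kind", "scenario")
    if kind == "scenario":
        result = _scenario_from_dict(data, errors)
    elif kind == "calibration":
        result = _calibration_from_dict(data, errors)
    else:
        raise ConfigError(path, [f"unknown config kind {kind!r}"])
    if errors or result is None:
        raise ConfigError(path, errors or ["invalid configuration"])
    return result


def model_to_dict(model) -> dict:
    """Serialise a fully built network (state-level, not template-level)."""
    return {
        "kind": "network",
        "globals": {
            "speed_slow": model.speed_slow,
            "speed_fast": model.speed_fast,
            "dt": model.dt,
            "logistic_variant": model.logistic_variant,
        },
        "states": [
            {
                "name": s.name,
                "category": s.category,
                "steepness": s.steepness,
                "threshold": s.threshold,
                "initial_value": s.initial_value,
                "combination": s.combination,
            }
            for s in model.states
        ],
        "connections": [
            {"source": c.source, "target": c.target, "weight": c.weight, "label": c.label}
            for c in model.connections
        ],
    }


def model_from_dict(data: dict):
    """Inverse of :func:`model_to_dict`; validation happens in the types."""
    from .network import Connection, NetworkModel, StateSpec

    return NetworkModel(
        states=[StateSpec(**s) for s in data["states"]],
        connections=[Connection(**c) for c in data["connections"]],
        **data.get("globals", {}),
    )


def save_model(model, path) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(model), sort_keys=False))


def load_model(path):
    return model_from_dict(yaml.safe_load(Path(path).read_text()))


def write_trace(trace: Trace, path) -> None:
    """Write a trace as CSV (lossless float round-trip)."""
    trace.to_frame().to_csv(path, index=False)


def read_trace(path) -> Trace:
    """Read a trace CSV written by :func:`write_trace`."""
    return Trace.from_frame(pd.read_csv(path, float_precision="round_trip"))


def write_report(report: Report, path) -> None:
    """Write a constraint report as structured JSON."""
    payload = {
        "passed": report.passed,
        "n_violated": report.n_violated,
        "total_violation": report.total_violation,
        "results": report.to_records(),
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
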