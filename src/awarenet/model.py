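"""Action-awareness network architecture.

Builds the cognitive agent model as a :class:`~awarenet.network.NetworkModel`:
world states (stimulus s, context c, effect b) feed sensor and sensory
representation states; preparation PA(a) drives execution EA(a) through the
body loop and predicts its effect through the as-if body loop
PA -> SR(b) -> F(b) -> PA; prior ownership (PO) and prior awareness (PAwr)
gate execution before it happens, retrospective ownership (RO) and
retrospective awareness (RAwr) integrate the sensed effect afterwards, and
EO communicates the result.  Suppressive links implement lateral inhibition
between competing preparations, the predicted-effect suppression of the
sensed effect, the predictive-to-inferential handover (RO -| PO,
RAwr -| PAwr) and the scenario-housekeeping removal of inputs after
execution.

Connections are named by semantic family labels (e.g. ``"PA->SR(b)"``;
``-|`` marks suppressive families).  A template instantiates the
architecture for a chosen number of action options and stimulus/context
tuples; per-option weight changes are applied with
:func:`apply_overrides` using ``"FAMILY@option"`` keys.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from typing import Mapping

from .network import Connection, NetworkError, NetworkModel, StateSpec

__all__ = [
    "ModelTemplate",
    "build_model",
    "apply_overrides",
    "ModelConfigError",
    "DEFAULT_WEIGHTS",
    "SIGMA_TAU",
    "EXTERNAL_KINDS",
    "state_count",
]


class ModelConfigError(NetworkError):
    """Template or override inconsistent with the architecture."""


#: Steepness / threshold per state kind.
SIGMA_TAU: dict[str, tuple[float, float]] = {
    "WS(s)": (1.0, 0.01),
    "WS(c)": (1.0, 0.01),
    "WS(b)": (6.0, 0.01),
    "SS(s)": (2.0, 0.01),
    "SS(c)": (2.0, 0.01),
    "SS(b)": (3.5, 0.01),
    "SR(s)": (2.0, 0.01),
    "SR(c)": (2.0, 0.01),
    "SR(b)": (3.0, 0.01),
    "PA": (2.0, 0.5),
    "F": (3.5, 0.01),
    "PO": (6.0, 1.0),
    "PAwr": (5.0, 0.6),
    "EA": (6.0, 1.0),
    "RO": (5.0, 1.9),
    "RAwr": (4.0, 1.6),
    "EO": (5.0, 0.8),
}

#: State kinds outside the agent's internal (fast) processing loop.
EXTERNAL_KINDS = {"WS(s)", "WS(c)", "WS(b)", "SS(s)", "SS(c)", "SS(b)", "EA", "EO"}

#: Generic connection-weight set shared by all scenarios (scenario-specific
#: overrides change at most a couple of entries).  Calibrated once against
#: the qualitative trace constraints of the eight shipped scenarios; see
#: docs/methods.md for the procedure.
DEFAULT_WEIGHTS: dict[str, float] = {
    # world-state persistence self-loops
    "WS(s)->WS(s)": 1.0,
    "WS(c)->WS(c)": 1.0,
    "WS(b)->WS(b)": 0.295,
    # sensing chains
    "WS(s)->SS(s)": 1.0,
    "WS(c)->SS(c)": 1.0,
    "WS(b)->SS(b)": 1.0,
    "SS(s)->SR(s)": 0.722,
    "SS(c)->SR(c)": 0.722,
    "SS(b)->SR(b)": 0.843,
    # preparation and lateral inhibition
    "SR(s)->PA": 0.562,
    "F->PA": 0.842,
    "PAwr->PA": 0.647,
    "PA-|PA": -0.29,
    # as-if body loop and predicted-effect suppression
    "PA->SR(b)": 0.8,
    "PO-|SR(b)": -0.919,
    "EO-|SR(b)": -0.089,
    "SR(b)->F": 0.8,
    # prior ownership
    "SR(s)->PO": 0.576,
    "SR(c)->PO": 0.576,
    "PA->PO": 0.995,
    "F->PO": 0.777,
    "RO-|PO": -0.606,
    # prior awareness
    "PO->PAwr": 0.972,
    "F->PAwr": 0.029,
    "RAwr-|PAwr": -0.044,
    # execution
    "PA->EA": 0.522,
    "PO->EA": 0.948,
    "PAwr->EA": 0.452,
    "EA->WS(b)": 0.322,
    # retrospective ownership
    "PO->RO": 0.974,
    "SR(c)->RO": 0.989,
    "F->RO": 0.686,
    "EA->RO": 0.551,
    # retrospective awareness (default parent set: EA, F, PO, PAwr)
    "EA->RAwr": 0.379,
    "F->RAwr": 0.736,
    "PO->RAwr": 0.613,
    "PAwr->RAwr": 0.663,
    "RO->RAwr": 0.818,
    # communication
    "RO->EO": 0.715,
    "RAwr->EO": 0.717,
    # scenario housekeeping: stop the inputs once the action is done
    "EA-|WS(s)": -0.101,
    "EO-|WS(c)": -0.183,
    "EO-|WS(b)": -0.446,
}

#: Families that must be suppressive (weight <= 0) in every scenario.
SUPPRESSIVE_FAMILIES = (
    "PA-|PA",
    "PO-|SR(b)",
    "EO-|SR(b)",
    "RO-|PO",
    "RAwr-|PAwr",
    "EA-|WS(s)",
    "EO-|WS(c)",
    "EO-|WS(b)",
)


@dataclass
class ModelTemplate:
    """Parameterisation of the awareness architecture.

    ``n_options`` action options and ``n_stimuli`` stimulus/context tuples
    are instantiated; ``option_map`` assigns each option its driving tuple
    (defaults: option i <-> tuple i when the counts match, tuple 1 for
    everyone when a single tuple is shared).  With ``shared_action`` all
    option columns share one preparation/execution pair PA(a1)/EA(a1) and
    differ only in their effect b — the mismatch configuration.
    ``rawr_parents`` selects which states feed retrospective awareness:
    ``"prior"`` uses execution, feeling, prior ownership and prior
    awareness; ``"retrospective"`` replaces prior ownership with
    retrospective ownership.
    """

    n_options: int = 1
    n_stimuli: int = 1
    option_map: dict[int, int] | None = None
    shared_action: bool = False
    rawr_parents: str = "prior"
    suppression_scope: str = "all"
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    sigma_tau: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(SIGMA_TAU)
    )
    speed_slow: float = 0.6
    speed_fast: float = 0.7
    dt: float = 0.25
    logistic_variant: str = "corrected"

    def __post_init__(self) -> None:
        if self.n_options < 1 or self.n_stimuli < 1:
            raise ModelConfigError("need at least one option and one stimulus tuple")
        if self.rawr_parents not in ("prior", "retrospective"):
            raise ModelConfigError(f"unknown rawr_parents {self.rawr_parents!r}")
        if self.suppression_scope not in ("all", "own"):
            raise ModelConfigError(f"unknown suppression_scope {self.suppression_scope!r}")
        if self.option_map is None:
            if self.n_stimuli == self.n_options:
                self.option_map = {j: j for j in range(1, self.n_options + 1)}
            elif self.n_stimuli == 1:
                self.option_map = {j: 1 for j in range(1, self.n_options + 1)}
            else:
                raise ModelConfigError(
                    "option_map required when n_stimuli matches neither 1 nor n_options"
                )
        bad = {j: k for j, k in self.option_map.items() if not 1 <= k <= self.n_stimuli}
        if bad or set(self.option_map) != set(range(1, self.n_options + 1)):
            raise ModelConfigError(f"invalid option_map {self.option_map}")

    def action_of(self, option: int) -> int:
        return 1 if self.shared_action else option


def state_count(n_options: int, n_stimuli: int, shared_action: bool = False) -> int:
    """Closed-form number of states the template instantiates."""
    n_actions = 1 if shared_action else n_options
    return 6 * n_stimuli + 2 * n_actions + 9 * n_options


def _spec(template: ModelTemplate, kind: str, label: str, initial: float = 0.0) -> StateSpec:
    sigma, tau = template.sigma_tau[kind]
    return StateSpec(
        name=label,
        category="external" if kind in EXTERNAL_KINDS else "internal",
        steepness=sigma,
        threshold=tau,
        initial_value=initial,
        # world stimulus/context states hold their value through the unit
        # self-loop (identity combination); everything else is logistic
        combination="identity" if kind in ("WS(s)", "WS(c)") else "logistic",
    )


def build_model(template: ModelTemplate) -> NetworkModel:
    """Instantiate the architecture as a runnable network."""
    w = template.weights
    missing = [f for f in DEFAULT_WEIGHTS if f not in w]
    if missing:
        raise ModelConfigError(f"missing weight for families: {missing}")
    for fam in SUPPRESSIVE_FAMILIES:
        if w[fam] > 0:
            raise ModelConfigError(f"family {fam!r} must be suppressive, got {w[fam]}")

    states: list[StateSpec] = []
    for k in range(1, template.n_stimuli + 1):
        states += [
            _spec(template, "WS(s)", f"WS(s{k})"),
            _spec(template, "SS(s)", f"SS(s{k})"),
            _spec(template, "SR(s)", f"SR(s{k})"),
            _spec(template, "WS(c)", f"WS(c{k})"),
            _spec(template, "SS(c)", f"SS(c{k})"),
            _spec(template, "SR(c)", f"SR(c{k})"),
        ]
    actions = sorted({template.action_of(j) for j in range(1, template.n_options + 1)})
    for i in actions:
        states += [
            _spec(template, "PA", f"PA(a{i})"),
            _spec(template, "EA", f"EA(a{i})"),
        ]
    y_label = {}
    for j in range(1, template.n_options + 1):
        i, k = template.action_of(j), template.option_map[j]
        y = f"a{i},b{j},c{k},s{k}"
        y_label[j] = y
        states += [
            _spec(template, "WS(b)", f"WS(b{j})"),
            _spec(template, "SS(b)", f"SS(b{j})"),
            _spec(template, "SR(b)", f"SR(b{j})"),
            _spec(template, "F", f"F(b{j})"),
            _spec(template, "PO", f"PO({y})"),
            _spec(template, "PAwr", f"PAwr({y})"),
            _spec(template, "RO", f"RO({y})"),
            _spec(template, "RAwr", f"RAwr({y})"),
            _spec(template, "EO", f"EO({y})"),
        ]

    conns: dict[tuple[str, str], Connection] = {}

    def add(family: str, source: str, target: str, instance: str) -> None:
        pair = (source, target)
        c = Connection(source, target, w[family], label=f"{family}@{instance}")
        if pair in conns:
            if conns[pair].weight != c.weight:
                raise ModelConfigError(f"conflicting weights for {source} -> {target}")
            return
        conns[pair] = c

    for k in range(1, template.n_stimuli + 1):
        add("WS(s)->WS(s)", f"WS(s{k})", f"WS(s{k})", str(k))
        add("WS(c)->WS(c)", f"WS(c{k})", f"WS(c{k})", str(k))
        add("WS(s)->SS(s)", f"WS(s{k})", f"SS(s{k})", str(k))
        add("WS(c)->SS(c)", f"WS(c{k})", f"SS(c{k})", str(k))
        add("SS(s)->SR(s)", f"SS(s{k})", f"SR(s{k})", str(k))
        add("SS(c)->SR(c)", f"SS(c{k})", f"SR(c{k})", str(k))

    for j in range(1, template.n_options + 1):
        i, k = template.action_of(j), template.option_map[j]
        y = y_label[j]
        pa, ea = f"PA(a{i})", f"EA(a{i})"
        po, pawr = f"PO({y})", f"PAwr({y})"
        ro, rawr, eo = f"RO({y})", f"RAwr({y})", f"EO({y})"
        sr_b, ss_b, ws_b, fb = f"SR(b{j})", f"SS(b{j})", f"WS(b{j})", f"F(b{j})"
        inst = str(j)

        # effect sensing and persistence
        add("WS(b)->WS(b)", ws_b, ws_b, inst)
        add("WS(b)->SS(b)", ws_b, ss_b, inst)
        add("SS(b)->SR(b)", ss_b, sr_b, inst)
        # body loop
        add("SR(s)->PA", f"SR(s{k})", pa, inst)
        add("PA->EA", pa, ea, inst)
        add("EA->WS(b)", ea, ws_b, inst)
        # as-if body loop
        add("PA->SR(b)", pa, sr_b, inst)
        add("SR(b)->F", sr_b, fb, inst)
        add("F->PA", fb, pa, inst)
        # prior ownership
        add("SR(s)->PO", f"SR(s{k})", po, inst)
        add("SR(c)->PO", f"SR(c{k})", po, inst)
        add("PA->PO", pa, po, inst)
        add("F->PO", fb, po, inst)
        add("RO-|PO", ro, po, inst)
        add("PO->PAwr", po, pawr, inst)
        add("PO->RO", po, ro, inst)
        add("PO->EA", po, ea, inst)
        add("PO-|SR(b)", po, sr_b, inst)
        # prior awareness
        add("F->PAwr", fb, pawr, inst)
        add("RAwr-|PAwr", rawr, pawr, inst)
        add("PAwr->PA", pawr, pa, inst)
        add("PAwr->EA", pawr, ea, inst)
        # retrospective ownership
        add("SR(c)->RO", f"SR(c{k})", ro, inst)
        add("F->RO", fb, ro, inst)
        add("EA->RO", ea, ro, inst)
        # retrospective awareness
        add("EA->RAwr", ea, rawr, inst)
        add("F->RAwr", fb, rawr, inst)
        if template.rawr_parents == "prior":
            add("PO->RAwr", po, rawr, inst)
        else:
            add("RO->RAwr", ro, rawr, inst)
        add("PAwr->RAwr", pawr, rawr, inst)
        # communication and inferential shutdown
        add("RO->EO", ro, eo, inst)
        add("RAwr->EO", rawr, eo, inst)
        add("EO-|SR(b)", eo, sr_b, inst)
        add("EO-|WS(b)", eo, ws_b, inst)
        # housekeeping suppression of the inputs
        targets = (
            range(1, template.n_stimuli + 1)
            if template.suppression_scope == "all"
            else (k,)
        )
        for kk in targets:
            add("EA-|WS(s)", ea, f"WS(s{kk})", f"{j},{kk}")
            add("EO-|WS(c)", eo, f"WS(c{kk})", f"{j},{kk}")

    # lateral inhibition between distinct preparations
    for i in actions:
        for i2 in actions:
            if i != i2:
                add("PA-|PA", f"PA(a{i})", f"PA(a{i2})", f"{i},{i2}")

    return NetworkModel(
        states=states,
        connections=list(conns.values()),
        speed_slow=template.speed_slow,
        speed_fast=template.speed_fast,
        dt=template.dt,
        logistic_variant=template.logistic_variant,
    )


def _parse_key(key: str) -> tuple[str, str | None]:
    if "@" in key:
        fam, inst = key.split("@", 1)
        return fam, inst
    return key, None


def apply_overrides(
    model: NetworkModel, overrides: Mapping[str, float]
) -> NetworkModel:
    """Return a copy of ``model`` with the named family weights replaced.

    Keys are family labels (``"PA->SR(b)"``, affecting every instance) or
    instance-qualified labels (``"PA->SR(b)@2"``, affecting option 2
    only).  Unknown labels raise with the closest matching candidates.
    """
    if not overrides:
        return model
    available: dict[str, list[Connection]] = {}
    for c in model.connections:
        fam, inst = _parse_key(c.label)
        available.setdefault(fam, []).append(c)
        available.setdefault(c.label, []).append(c)

    new_weights: dict[tuple[str, str], float] = {}
    for key, value in overrides.items():
        fam, inst = _parse_key(key)
        lookup = key if inst is not None else fam
        matches = available.get(lookup, [])
        if inst is not None and not matches:
            # per-(option, stimulus) instances such as "EA-|WS(s)@1,1"
            matches = [
                c
                for c in available.get(fam, [])
                if _parse_key(c.label)[1].split(",")[0] == inst
            ]
        if not matches:
            close = difflib.get_close_matches(key, sorted(set(available)), n=3)
            raise ModelConfigError(
                f"override {key!r} matches no connection; close matches: {close}"
            )
        for c in matches:
            new_weights[(c.source, c.target)] = value
    return model.with_weights(new_weights)
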