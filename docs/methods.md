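# Methods

## The model

`awarenet` simulates action awareness and ownership as a temporal-causal
activation network.  Every state `y_i` carries an activation in [0, 1] and
evolves in discrete time by

    y_i(t + Δt) = y_i(t) + γ_i · [ g(σ_i, τ_i, Σ_j ω_ji · y_j(t)) − y_i(t) ] · Δt

where the sum runs over the incoming connections of state `i`, each with a
signed weight ω ∈ [−1, +1] (negative = suppressive), and `g` is a
normalised logistic threshold

    g(σ, τ, X) = ( 1/(1 + e^{−σ(X−τ)}) − 1/(1 + e^{στ}) ) · (1 + e^{−στ})   for X > 0
    g(σ, τ, X) = 0                                                          for X ≤ 0

σ is the steepness, τ the threshold.  This normalisation makes `g`
continuous at 0 with g(0) = 0 and g → 1 as X → ∞, so activations stay in
[0, 1]; the variant without the sign flip in the normalising exponent
(`logistic_variant="as_printed"`) is retained for comparison but exceeds 1
for large input and is not used by the shipped scenarios.  After every
Euler step activations are clipped to [0, 1] as a numerical guard.

Two global speed factors are used: γ = 0.7 for internal (cognitive)
states and γ = 0.6 for external states (world, sensor and effector
states: WS, SS, EA, EO) — neurons update faster than sense organs and
effectors.  The integration step is Δt = 0.25 model-time units;
"time point N" in scenario descriptions means N model-time units
(4 Euler steps).  The engine is fully deterministic: no noise enters the
dynamics anywhere, and two runs of the same configuration produce
bitwise-identical traces.

## The architecture

For each action option `a_i`, effect `b_i` and stimulus/context tuple
`(s_k, c_k)` the builder instantiates the state kinds

- world/sensing chains WS → SS → SR for s, c and b,
- preparation PA(a_i) and execution EA(a_i),
- feeling F(b_i),
- prior and retrospective ownership PO / RO over (a_i, b_i, c_k, s_k),
- prior and retrospective awareness PAwr / RAwr,
- communication EO,

wired as: the body loop SR(s) → PA → EA → WS(b) → SS(b) → SR(b) → F; the
as-if body loop PA → SR(b) → F → PA that internally valuates an option's
predicted effect before execution; lateral inhibition PA(a_i) ⊣ PA(a_j)
between competing preparations; prior ownership fed by SR(s), SR(c), PA
and F, gating execution and suppressing the sensed-effect representation
(the predicted effect suppresses the actual one); prior awareness fed
only by PO and F (awareness rides on, and follows, the unconscious
machinery) and feeding back into PA and EA (the conscious bias channel);
retrospective ownership integrating PO, SR(c), F and EA after execution,
suppressing PO (the predictive-to-inferential handover); retrospective
awareness fed by EA, F, PO and PAwr, suppressing PAwr; and EO fed by RO
and RAwr, closing the episode by suppressing SR(b), WS(b) and WS(c),
while EA suppresses WS(s).

Two readings exist for the parents of retrospective awareness; both are
implemented behind `ModelTemplate.rawr_parents`.  The default (`"prior"`)
uses {EA, F, PO, PAwr}; the alternative (`"retrospective"`) replaces PO
with RO.  The default was chosen because the scenario that removes
awareness zeroes exactly the EA/F/PO inputs, which is only coherent under
the first reading.

### World-state persistence

The input states WS(s) and WS(c) start at 1 and must hold that value
until the executed action removes them, producing the plateau-then-
collapse input profile of the published figures.  Nothing in the
architecture feeds them, so each WS state carries an implicit
self-connection of weight +1.  For WS(b) (σ = 6) the logistic
self-loop is effectively bistable and holds the state high once the
execution has driven it up.  For WS(s)/WS(c), whose σ = 1 makes a
logistic self-loop decay from 1, the combination function is the
identity (the model's combination function is selectable per state, and
the identity is the standard choice for simple pass-through states):
the aggregate input is then `y + ω_sup · EA`, which holds the value
exactly until the suppressive link pulls it down.  This device is this
package's reading of the published figures, not something the original
description states.

## Parameters

| parameter | value | meaning |
|---|---|---|
| Δt | 0.25 | integration step, model-time units |
| γ_slow / γ_fast | 0.6 / 0.7 | external / internal update speed per unit time |
| σ, τ per state kind | see `awarenet.model.SIGMA_TAU` | logistic shape per state kind |
| ω per connection family | see `awarenet.model.DEFAULT_WEIGHTS` | the generic weight set |
| horizon | 120 (240 for the double-execution scenario) | simulation length |
| onset threshold | 0.01 | first crossing counts as a state's lift-off |

σ/τ: input and sensing states use low thresholds (τ = 0.01) so they pass
activation through; the gate-like states carry genuine thresholds —
preparation τ = 0.5, prior ownership and execution τ = 1.0, prior
awareness τ = 0.6, retrospective ownership τ = 1.9, retrospective
awareness τ = 1.6, communication τ = 0.8 — so that each fires only when
several parents are jointly active.  Execution's high threshold with
steep σ = 6 is what makes the go/no-go behaviour sharp.

### The generic weight set

A handful of weights are pinned directly by the scenario definitions
(e.g. the as-if prediction weight PA→SR(b) = 0.8 in the baseline, 0.2 in
the veto scenario, 0.6 on the weaker option of the competition
scenarios; the sensed-feeling weight SR(b)→F = 0.8, 0.2 in the
poor-feeling scenario).  The remaining family weights are not individually
published; they were fixed once by the package's own calibration
machinery (`awarenet.calibrate`), run in exactly the incremental
fashion the procedure section below describes, against the published
qualitative trace features of all eight scenarios simultaneously —
onset orderings, presence/absence of states, peak-activation levels and
the bimodal sensed-effect profile.  The resulting set is frozen in
`DEFAULT_WEIGHTS` and shipped as the single generic parameter set used
by every scenario; no scenario changes more than a few weights from it.

## Scenarios

Eight configurations are shipped (`awarenet.scenarios`); each is the
generic set plus the scenario's published overrides.  Scenario 7 is
modelled as one action with two effect columns (shared PA/EA, separate
b-chains and ownership/awareness columns), matching the description of a
single prepared action whose actual effect differs from the predicted
one; because the unrealised effect's column never completes the
ownership-awareness-communication cycle, this scenario ends in a
sustained activation state rather than decaying to rest — the episode
is executed but never "closed" by communication, which is exactly its
point.  The unpredicted effect's column additionally carries no
prior-awareness drive (its ownership-to-awareness link is zeroed along
with its as-if and predictive-suppression links): awareness of the
actual effect can only arise retrospectively, which is what produces
the enlarged action-outcome binding gap.  Scenario 8 instantiates two stimulus tuples, matching the
published figure legend, although the accompanying trace text speaks of a
single tuple driving both options; the discrepancy is noted here and the
two-tuple reading was chosen for consistency with the competition
scenarios' machinery.  In the competition scenarios the executed option
suppresses all input tuples (scenario 5) or only its own (scenario 6);
this is the `suppression_scope` template field.

## Trace analysis

Features are deliberately simple and discrete: `peak` is the global
maximum (earliest on ties); `onset` the first crossing of 0.01 (the
published narratives say "starts to trigger" without defining it; 0.01
is this package's operationalisation and is configurable); `dip` looks
for a local maximum, a subsequent local minimum and a later higher
maximum after smoothing with a 3-sample moving median (guards against
Δt-level jitter); `binding_gap` measures the delay from the
execution state's lift-off to the perceived outcome's lift-off, clamped
at zero: a pre-existing prediction or awareness of the effect gives gap
0, an effect that is only discovered after acting gives a positive gap
(the intentional-binding contrast).  Qualitative constraints (ordering / bounds / absence /
bimodality) evaluate to pass/fail plus a violation magnitude — time
overlap for orderings, excess beyond the bound otherwise — which is what
the calibration search minimises.

## Calibration

The published estimation procedure is manual; the search strategy here
is this package's own and makes no claim of matching it beyond its
outer loop: address scenario 1, then add each further scenario's
constraints only once the previous ones are satisfied, re-scoring all
admitted scenarios at every step so that a newly added scenario can send
the search back to earlier ones.  Within that loop the search is
seeded coordinate refinement (per-parameter step halving within bounds)
with random restarts once local refinement is exhausted.  Scores are
lexicographic: first the number of violated constraints, then the summed
violation magnitude, both unweighted.  Identical (problem, seed) pairs
give identical results; infeasible bounds raise immediately rather than
returning a silent best effort.

## Numerical choices and degenerate inputs

- Exponentials in `g` are argument-clipped at ±700 to avoid overflow; the
  branch X ≤ 0 → 0 is exact.
- Post-step clipping to [0, 1] makes divergence impossible; a non-finite
  activation is treated as an internal error, not a model outcome.
- Ties in `peak` resolve to the earliest sample; an all-zero series has
  onset "absent" and peak (0, t=0).
- A state with no incoming connections has aggregate input 0, hence
  target 0, and decays monotonically — quiescence is the default.
- Horizons are required to be positive; the sample count is
  ⌊horizon/Δt⌋ + 1.

## What the simulations do and do not show

With the shipped weight set the baseline episode winds down after the
inputs are suppressed, but the tail is slow: the feeling and
sensory-representation states rebound briefly once the ownership
suppression releases and then decay over tens of time units instead of
dropping straight to zero.  The qualitative structure (peaks, orderings,
the dip, the collapse after input removal) is unaffected.

All validation is against the model's own published trace
phenomenology, not against neural or behavioural recordings: the time
axis and activation levels are a frame of reference without physical
units.  Passing the scenario suites shows that the architecture plus
the generic parameter set reproduces the qualitative interplay of
unconscious preparation, ownership, awareness and execution that the
model was designed to exhibit — it does not validate the model against
empirical data, which do not exist at this resolution.  Mirroring
(context = "other"), learning/plasticity, mood dynamics and intentional
(conscious) inhibition are outside this package's scope; the SR(c)
wiring supports "other"-context extensions but no such scenario is
shipped.
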