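"""Independent straight-line scalar re-implementation of the update rule,
used as the oracle against the vectorised engine."""

import math


def oracle_g(sigma, tau, x):
    if x <= 0:
        return 0.0
    return (1 / (1 + math.exp(-sigma * (x - tau))) - 1 / (1 + math.exp(sigma * tau))) * (
        1 + math.exp(-sigma * tau)
    )


def oracle_step(states, connections, values, speed_slow, speed_fast, dt):
    out = {}
    for s in states:
        total = 0.0
        for c in connections:
            if c.target == s.name:
                total += c.weight * values[c.source]
        gamma = speed_fast if s.category == "internal" else speed_slow
        if s.combination == "identity":
            target = total
        else:
            target = oracle_g(s.steepness, s.threshold, total)
        nxt = values[s.name] + gamma * (target - values[s.name]) * dt
        out[s.name] = min(1.0, max(0.0, nxt))
    return out
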