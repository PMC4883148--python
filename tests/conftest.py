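import numpy as np
import pytest

from awarenet.scenarios import run_scenario


@pytest.fixture(scope="session")
def traces():
    """Session-wide cache of scenario traces (the model is deterministic)."""
    cache = {}

    def get(scenario_id: int):
        if scenario_id not in cache:
            cache[scenario_id] = run_scenario(scenario_id)
        return cache[scenario_id]

    return get


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
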