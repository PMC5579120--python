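import numpy as np
import pandas as pd
import pytest

from ziphius import simulate


@pytest.fixture(scope="session")
def small_scenario():
    cfg = simulate.ScenarioConfig(n_whales=3, days=6.0)
    return simulate.simulate_scenario(cfg, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def ts(s: str) -> pd.Timestamp:
    t = pd.Timestamp(s)
    return t.tz_localize("UTC") if t.tzinfo is None else t
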