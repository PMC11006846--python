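import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hemobayes as hb

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def fast_config():
    return hb.FitConfig.fast(seed=7)


@pytest.fixture(scope="session")
def normal_fit_n60():
    """Default-config normal fit of 60 N(5, 2) draws, shared across tests."""
    y = np.random.default_rng(5).normal(5, 2, 60)
    return y, hb.fit_family(y, "normal", hb.FitConfig(seed=11))


@pytest.fixture
def tiny_table():
    """Small paired study table: 6 animals with pH before/after."""
    import pandas as pd

    rows = []
    before = [7.50, 7.52, 7.55, 7.49, 7.53, 7.51]
    after = [7.10, 7.15, 7.20, 7.05, None, 7.12]
    for i, (b, a) in enumerate(zip(before, after), start=1):
        rows.append((str(i), "Bas", "pH", b))
        if a is not None:
            rows.append((str(i), "CO2", "pH", a))
    df = pd.DataFrame(rows, columns=["animal_id", "treatment", "variable", "value"])
    return hb.make_study_table(df)
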