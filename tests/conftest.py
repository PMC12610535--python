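import numpy as np
import pandas as pd
import pytest

from herdstress.pipeline import run_pipeline
from herdstress.synthetic import SimConfig, simulate_herd


@pytest.fixture(scope="session")
def herd60():
    """10 cows for 60 days under default study conditions."""
    return simulate_herd(SimConfig(n_cows=10, n_days=60, seed=1))


@pytest.fixture(scope="session")
def pipe60(herd60):
    return run_pipeline(herd60)


@pytest.fixture(scope="session")
def herd120():
    """The episode-recovery herd: 10 cows x 120 days, default effect sizes."""
    return simulate_herd(SimConfig(n_cows=10, n_days=120, seed=7))


def hourly_frame(cow: str, hours: int, start="2023-01-01", **cols) -> pd.DataFrame:
    """Helper: a gap-free hourly frame for one cow."""
    ts = pd.date_range(start, periods=hours, freq="h")
    out = pd.DataFrame({"cow_id": cow, "timestamp": ts})
    for name, val in cols.items():
        out[name] = val
    return out
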