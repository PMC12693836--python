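from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from winotherm.logio import LogDataset
from winotherm.simulate import scenario_default, simulate


@pytest.fixture(scope="session")
def default_sim():
    """7-day default scenario with the light-modulated living source."""
    return simulate(scenario_default(duration_days=7.0, seed=1))


@pytest.fixture(scope="session")
def null_sim():
    """Same scenario with all sources zeroed (no thermogenesis)."""
    return simulate(scenario_default(duration_days=7.0, seed=1, zero_sources=True))


def make_dataset(values: dict[str, float | np.ndarray], days: float = 3.0,
                 start: datetime = datetime(2022, 4, 1), period_s: float = 60.0) -> LogDataset:
    """Constant-or-array multi-channel dataset sampled on a regular grid."""
    n = int(days * 86400 / period_s)
    idx = pd.date_range(start, periods=n, freq=f"{int(period_s)}s")
    frame = pd.DataFrame(
        {ch: (np.full(n, v) if np.isscalar(v) else np.asarray(v)) for ch, v in values.items()},
        index=idx,
    )
    return LogDataset(frame=frame, sampling_period=period_s)


@pytest.fixture
def constant_dataset():
    """3 days of constant readings on all five core channels."""
    return make_dataset(
        {
            "living_top": 25.5,
            "living_bottom": 25.0,
            "control_top": 25.25,
            "control_bottom": 25.0,
            "incubator": 25.1,
        }
    )
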