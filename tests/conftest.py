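import warnings

import numpy as np
import pandas as pd
import pytest

import bovigas as bg

warnings.filterwarnings("ignore", category=UserWarning, module="bovigas")


@pytest.fixture(scope="session")
def small_config() -> bg.SimulationConfig:
    return bg.SimulationConfig(n_cows=8, n_days=3, seed=11)


@pytest.fixture(scope="session")
def small_campaign(small_config) -> bg.Campaign:
    return bg.simulate_campaign(small_config)


@pytest.fixture(scope="session")
def processed_small(small_campaign):
    return bg.process_gas_log(
        small_campaign.gas, small_campaign.visits, small_campaign.background_windows
    )


def anova_components(y: np.ndarray) -> tuple[float, float]:
    """Closed-form one-way random-effects ANOVA (method of moments) on a
    balanced (n_groups, n_per) matrix: returns (sigma2_group, sigma2_resid)."""
    n_groups, n_per = y.shape
    gm = y.mean(axis=1)
    msb = n_per * gm.var(ddof=1)
    msw = ((y - gm[:, None]) ** 2).sum() / (n_groups * (n_per - 1))
    return (msb - msw) / n_per, msw


def balanced_frame(y: np.ndarray) -> pd.DataFrame:
    """Long-format frame for a balanced (n_groups, n_per) response matrix."""
    n_groups, n_per = y.shape
    return pd.DataFrame({
        "y": y.ravel(),
        "cow_id": np.repeat([f"c{i}" for i in range(n_groups)], n_per),
    })
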