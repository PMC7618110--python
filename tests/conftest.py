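import logging

import numpy as np
import pytest

from tempmort.stage1 import ModelConfig, fit_location
from tempmort.synthetic import (MetaStructure, RiskParams, paper_like_scenario,
                                simulate_scenario)

logging.getLogger("tempmort").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_study():
    """4 locations x 3 years with a uniform-lag J-shaped truth: large
    enough to fit, small enough to share across tests."""
    scenario = paper_like_scenario(
        seed=42, n_locations=4, years=3.0,
        risk=RiskParams(mmt_percentile=25, log_rr_heat=0.2, log_rr_cold=0.06,
                        heat_lag_shape="uniform", cold_lag_shape="uniform"),
        meta=MetaStructure(modifier_heat=None, sd_log_heat=0.1, sd_log_cold=0.1))
    return simulate_scenario(scenario)


@pytest.fixture(scope="session")
def small_fits(small_study):
    cfg = ModelConfig()
    return {s.location_id: fit_location(s, cfg) for s in small_study.series}


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
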