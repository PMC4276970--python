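import warnings

import numpy as np
import pytest

import relapsim as rs


@pytest.fixture
def hand_dataset():
    """Five-patient fixture whose life table and KM curve are hand-computed."""
    return rs.SurvivalDataset(
        times=np.array([2.0, 5.0, 8.0, 8.0, 11.0]),
        events=np.array([True, True, True, False, True]),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """10,000-patient untreated cohort under the default calibration."""
    records = rs.simulate_cohort(rs.default_config(10000, seed=7))
    return rs.SurvivalDataset.from_records(records)


@pytest.fixture(scope="session")
def constant_hazard_dataset():
    """20,000 patients with exponential (memoryless) relapse, horizon 120."""
    rng = np.random.default_rng(404)
    t = rng.exponential(100.0, 20000)
    e = t <= 120.0
    return rs.SurvivalDataset(np.minimum(t, 120.0), e)


@pytest.fixture(autouse=True)
def _silence_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
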