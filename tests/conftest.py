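import numpy as np
import pandas as pd
import pytest

from tcrquant.localization_stats import LocalizationTable, RegionMask
from tcrquant.synthetic_data import GroundTruth, simulate_dose_response


@pytest.fixture(scope="session")
def square_mask() -> RegionMask:
    """5 x 5 um all-true region at 20 nm mask pixels."""
    return RegionMask.from_rect(5000.0, 5000.0, 20.0)


@pytest.fixture
def one_site_truth() -> GroundTruth:
    return GroundTruth("binding", {"bmax": 1000.0, "kd": 50.0}, noise_cv=0.0, seed=1)


@pytest.fixture
def one_site_clean(one_site_truth) -> "pd.DataFrame":
    return simulate_dose_response(one_site_truth, condition_label="A")


def csr_table(n: int, side_nm: float, seed: int, mask: RegionMask) -> LocalizationTable:
    """Uniform (completely spatially random) localization pattern."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0.0, side_nm, (n, 2))
    rec = pd.DataFrame(
        {"x_nm": xy[:, 0], "y_nm": xy[:, 1], "frame": np.arange(n), "photons": 1000.0}
    )
    return LocalizationTable(rec, pixel_size_nm=107.0, mask=mask)
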