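import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from seedage.omics import FeatureTable


def survival_frame(days, germinated, total):
    return pd.DataFrame(
        {
            "storage_days": np.asarray(days, float),
            "germinated": np.asarray(germinated),
            "total": total,
        }
    )


@pytest.fixture
def noiseless_survival():
    """Counts generated by rounding the viability-probit expectation.

    Truth: Ki = 2.0 NED, sigma_inv = 0.08 NED/day, 90 seeds per test.
    """
    days = np.array([0.0, 14.0, 28.0, 42.0, 56.0])
    total = 90
    g = np.round(total * norm.cdf(2.0 - 0.08 * days)).astype(int)
    return survival_frame(days, g, total), {"Ki": 2.0, "sigma_inv": 0.08}


@pytest.fixture
def toy_feature_table():
    """5 samples x 4 compounds with known detection pattern and an IS channel.

    Compound A exceeds 15,000 counts in exactly 3 samples, B in 2, Z never.
    """
    intensities = pd.DataFrame(
        {
            "A": [20000.0, 18000.0, 16000.0, 100.0, 5.0],
            "B": [20000.0, 16000.0, 100.0, 100.0, 5.0],
            "Z": [0.0, 0.0, 0.0, 0.0, 0.0],
            "IS": [1e5, 1e5, 1e5, 1e5, 1e5],
        },
        index=[f"s{i}" for i in range(5)],
    )
    meta = pd.DataFrame(
        {
            "treatment": ["EPPO"] * 5,
            "storage_days": [0, 14, 28, 42, 56],
            "germination_pct": [95.0, 80.0, 50.0, 20.0, 5.0],
        },
        index=intensities.index,
    )
    return FeatureTable(intensities=intensities, sample_meta=meta, is_channel="IS")
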