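import numpy as np
import pandas as pd
import pytest

from climvuln.synthetic import GeneratorConfig, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def fast_study():
    """One small synthetic study shared across tests (30 regions, 3 years)."""
    return generate_study(GeneratorConfig.fast(seed=42))


def make_series(dates, tmax=None, tmin=None, precip=None, region="R001"):
    """Single-region daily frame with optional variables."""
    n = len(dates)
    return pd.DataFrame(
        {
            "region_id": region,
            "date": pd.to_datetime(dates),
            "tmax": np.full(n, np.nan) if tmax is None else np.asarray(tmax, dtype=float),
            "tmin": np.full(n, np.nan) if tmin is None else np.asarray(tmin, dtype=float),
            "precip": np.full(n, np.nan) if precip is None else np.asarray(precip, dtype=float),
        }
    )


@pytest.fixture
def series_factory():
    return make_series
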