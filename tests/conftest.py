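import numpy as np
import pandas as pd
import pytest

from epichannel import SyntheticConfig, WeeklySeries, simulate


def make_series(counts_by_year: dict[int, list[int]], disease: str = "test") -> WeeklySeries:
    """Build a WeeklySeries from {year: [weekly counts...]} starting at week 1."""
    idx, vals = [], []
    for year, counts in counts_by_year.items():
        for week, c in enumerate(counts, start=1):
            idx.append((year, week))
            vals.append(c)
    data = pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["year", "week"]))
    return WeeklySeries(disease_id=disease, data=data)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture(scope="session")
def default_synthetic():
    """One simulated default-scenario series (572 weeks) shared by tests."""
    return simulate(SyntheticConfig())


@pytest.fixture(scope="session")
def full_series(default_synthetic):
    return default_synthetic[0]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
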