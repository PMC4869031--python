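import numpy as np
import pandas as pd
import pytest

from conflict_ecology import (
    LandscapeConfig,
    TruthParams,
    generate_landscape,
    simulate_salmon_streams,
)
from conflict_ecology.synthetic import build_design_truth, simulate_kills


@pytest.fixture(scope="session")
def truth() -> TruthParams:
    return TruthParams()


@pytest.fixture(scope="session")
def small_landscape(truth):
    config = LandscapeConfig(
        n_units=8, year_range=(1980, 1999), frac_salmon_units=0.5, seed=42
    )
    return generate_landscape(config, truth)


@pytest.fixture(scope="session")
def small_streams(small_landscape, truth):
    return simulate_salmon_streams(small_landscape, truth, seed=7)


@pytest.fixture(scope="session")
def small_kills(small_landscape, small_streams, truth):
    design_truth = build_design_truth(small_landscape, small_streams, truth)
    return simulate_kills(small_landscape, design_truth, truth, seed=11)


def make_series(counts, years=None, stream_id="S1", species="pink", unit_id="U1"):
    """Long-format stream-species series from a list (None = missing)."""
    if years is None:
        years = range(2000, 2000 + len(counts))
    return pd.DataFrame(
        {
            "stream_id": stream_id,
            "species": species,
            "unit_id": unit_id,
            "year": list(years),
            "count": [np.nan if c is None else float(c) for c in counts],
        }
    )


@pytest.fixture
def make_stream_series():
    return make_series
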