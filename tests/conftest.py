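import numpy as np
import pandas as pd
import pytest

from coreniche import SimConfig, simulate_survey
from coreniche.io import CommunityMatrix


@pytest.fixture
def tiny_community() -> CommunityMatrix:
    """Six samples (3 stations x 2 months) by five taxa, hand-written."""
    counts = pd.DataFrame(
        [
            [8, 2, 0, 5, 1],
            [6, 4, 1, 5, 0],
            [7, 3, 0, 4, 2],
            [9, 1, 2, 6, 0],
            [5, 5, 0, 5, 1],
            [8, 2, 1, 4, 0],
        ],
        index=[f"S{i}" for i in range(1, 7)],
        columns=list("ABCDE"),
    )
    meta = pd.DataFrame(
        {
            "station": ["ST1", "ST2", "ST3", "ST1", "ST2", "ST3"],
            "month": [1, 1, 1, 7, 7, 7],
            "latitude": [22.2, 22.3, 22.4, 22.2, 22.3, 22.4],
            "longitude": [114.0, 114.1, 114.2, 114.0, 114.1, 114.2],
        },
        index=counts.index,
    )
    return CommunityMatrix(counts, meta)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A scaled-down survey used by unit tests that need realistic structure."""
    return SimConfig(
        n_stations=10, n_months=6, n_taxa=400, n_core=80,
        n_dominant_core=8, depth=4000, seed=11,
    )


@pytest.fixture(scope="session")
def small_survey(small_cfg):
    counts, taxonomy, env, truth = simulate_survey(small_cfg)
    meta = env[["station", "month", "season", "latitude", "longitude"]]
    return CommunityMatrix(counts, meta), taxonomy, env, truth
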