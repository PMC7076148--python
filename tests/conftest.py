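import numpy as np
import pandas as pd
import pytest

from gridsurvey import GridSpec, SettledCellFrame, make_fixture
from gridsurvey.stratify import Stratification


@pytest.fixture(scope="session")
def tiny_landscape():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def tiny_frame(tiny_landscape):
    return tiny_landscape.frame()


@pytest.fixture(scope="session")
def medium_landscape():
    return make_fixture("medium")


def single_stratum_frame(populations) -> tuple[SettledCellFrame, Stratification]:
    """A 1-row frame holding the given populations, all in stratum 0."""
    populations = np.asarray(populations, dtype=float)
    m = populations.size
    grid = GridSpec(origin_x=0.0, origin_y=1.0, cell_size=0.01, n_rows=1, n_cols=m)
    cols = np.arange(m)
    cells = pd.DataFrame(
        {
            "cell_id": cols,
            "row": np.zeros(m, dtype=int),
            "col": cols,
            "centroid_lon": (cols + 0.5) * 0.01,
            "centroid_lat": np.full(m, 0.995),
            "population": populations,
        }
    )
    frame = SettledCellFrame(grid=grid, cells=cells)
    strat = Stratification(k=1, labels=np.zeros(m, dtype=int))
    return frame, strat


@pytest.fixture(scope="session")
def frame50():
    """50-cell single-stratum fixture with moderately skewed populations."""
    rng = np.random.default_rng(42)
    pop = np.round(rng.lognormal(mean=2.0, sigma=0.5, size=50), 3)
    return single_stratum_frame(pop)
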