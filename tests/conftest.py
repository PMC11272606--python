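import warnings

import numpy as np
import pandas as pd
import pytest

from fledgeline import (
    atlas,
    coal_tit_preset,
    fit_posterior,
    simulate_observations,
)

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def coal_tit_data():
    """Simulated coal-tit-like dataset (n=2000 for tight recovery checks)."""
    truth, cond = coal_tit_preset()
    obs, sidecar = simulate_observations(truth, 2000, cond["years"], seed=321)
    encoded, _ = atlas.encode_responses(obs)
    return truth, sidecar, encoded.dropna(subset=["response"])


@pytest.fixture(scope="session")
def coal_tit_fit(coal_tit_data):
    """One fitted posterior shared across recovery tests (4 x 800)."""
    truth, sidecar, records = coal_tit_data
    draws = fit_posterior(records, chains=4, iterations=800, seed=4)
    return truth, sidecar, draws


@pytest.fixture()
def tiny_observation_csv(tmp_path):
    """A small hand-written observation file exercising the reader."""
    path = tmp_path / "obs.csv"
    pd.DataFrame(
        {
            "species": ["coal_tit"] * 4,
            "date": ["2015-06-18", "2016-02-29", "2015-05-01", "not-a-date"],
            "elevation_m": [1600, 1700, 1499, 1800],
            "year": [2015, 2016, 2015, 2015],
            "atlas_code": [13, 16, 13, 13],
        }
    ).to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240725)
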