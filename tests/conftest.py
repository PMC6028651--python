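import warnings

import numpy as np
import pytest

from petrad.pipeline import build_feature_matrix
from petrad.synthetic import CohortConfig, generate_cohort
from petrad.volume_io import SUVVolume, VOIMask, extract_voi


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def ball_voi(rng):
    """A noisy spherical VOI inside a flat background volume."""
    grid = np.full((16, 16, 16), 1.0)
    coords = np.indices((16, 16, 16)) - 8
    mask = (coords**2).sum(axis=0) <= 12
    grid[mask] = 5.0 + rng.normal(0.0, 0.6, int(mask.sum()))
    vol = SUVVolume(grid, (4.0, 4.0, 4.0))
    m = VOIMask(mask.astype(np.uint8), (4.0, 4.0, 4.0))
    return extract_voi(vol, m)


@pytest.fixture(scope="session")
def small_cohort_matrix():
    """Feature matrix of a 12-patient synthetic cohort (session-cached)."""
    cfg = CohortConfig(n_patients=12, n_progression=4, seed=7)
    records, images = generate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix, y = build_feature_matrix(records, images)
    return records, matrix, y
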