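import numpy as np
import pytest

from cosmpn.datasets import (
    karasawa_design,
    karasawa_observations,
    karasawa_sample,
)


@pytest.fixture(scope="session")
def design():
    return karasawa_design()


@pytest.fixture(scope="session")
def soil_sample():
    return karasawa_sample()


@pytest.fixture(scope="session")
def karasawa_obs():
    return karasawa_observations()


def brute_force_mpn(positives, tubes, volumes, grid=None):
    """Independent MPN oracle: maximize the Poisson single-hit log-likelihood
    on a fine logarithmic grid (no score equation, no root finding)."""
    p = np.asarray(positives, float)
    n = np.asarray(tubes, float)
    v = np.asarray(volumes, float)
    if grid is None:
        grid = np.logspace(-3, 3, 600001)
    q = 1.0 - np.exp(-np.outer(grid, v))
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(p > 0, p * np.log(np.maximum(q, 1e-300)), 0.0).sum(axis=1)
    ll -= (np.outer(grid, v) * (n - p)).sum(axis=1)
    return float(grid[np.argmax(ll)])
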