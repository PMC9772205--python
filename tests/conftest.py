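import numpy as np
import pytest

import casvision as cv

TINY_C_GRID = (0.1, 1.0)
TINY_NC_GRID = (8, 16)


@pytest.fixture(scope="session")
def high_signal_spec() -> cv.CohortSpec:
    """Small cohort with maximal rendered signs and near-perfect raters."""
    return cv.CohortSpec(
        n_patients=60,
        seed=11,
        intensity_range=(1.0, 1.0),
        raters=tuple(cv.RaterProfile(0.97, 0.97) for _ in range(3)),
        consensus_flip_prob=0.0,
    )


@pytest.fixture(scope="session")
def high_signal_cohort(high_signal_spec) -> cv.SyntheticCohort:
    return cv.generate_cohort(high_signal_spec)


@pytest.fixture(scope="session")
def high_signal_features(high_signal_cohort):
    return cv.cohort_features(high_signal_cohort)


@pytest.fixture(scope="session")
def gaussian_pair():
    """Two well-separated Gaussian classes in pixel space.

    Centroid separation is 6x the within-class SD along one axis, so
    the Bayes error of the projected problem is below 2e-3.
    """
    rng = np.random.default_rng(42)
    n, d = 200, 12288
    direction = rng.normal(size=d)
    direction /= np.linalg.norm(direction)
    sd = 0.05  # within-class SD along the discriminant
    y = np.arange(n) % 2 == 0
    coord = np.where(y, 3 * sd, -3 * sd) + rng.normal(scale=sd, size=n)
    X = rng.normal(scale=0.005, size=(n, d)) + coord[:, None] * direction[None, :]
    return X, y
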