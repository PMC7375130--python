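import warnings

import numpy as np
import pytest

from bbsgca import synthetic as syn


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # Heywood flags and K-clipping are routine on small fixtures.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def small_spec():
    return syn.SyntheticSpec(n_subjects=150, n_voxels=300, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return syn.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_parcellation(small_spec):
    return syn.make_parcellation(small_spec)


@pytest.fixture(scope="session")
def small_maps(small_spec, small_cohort, small_parcellation):
    return syn.generate_contrast_maps(small_cohort, small_parcellation,
                                      small_spec, "2bk-0bk")


def bifactor_sample(n=1000, seed=0, general=0.7, group=0.4):
    """Raw scores drawn from the canonical bifactor configuration."""
    rng = np.random.default_rng(seed)
    lg = np.full(10, general)
    _, blocks = syn.default_behavior_loadings()
    lf = np.where(blocks != 0, group, 0.0)
    psi = 1.0 - lg**2 - (lf**2).sum(axis=1)
    g = rng.standard_normal(n)
    fac = rng.standard_normal((n, 4))
    X = np.outer(g, lg) + fac @ lf.T + rng.standard_normal((n, 10)) * np.sqrt(psi)
    return X, g, lg, lf, psi
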