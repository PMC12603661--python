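import warnings

import numpy as np
import pytest

from zerolag.synthetic import (SyntheticCohortSpec, make_geometry,
                               make_structural_connectome, simulate_cohort)


@pytest.fixture(scope="session")
def geometry16():
    return make_geometry(16, seed=3)


@pytest.fixture(scope="session")
def connectome16(geometry16):
    return make_structural_connectome(geometry16, seed=5)


@pytest.fixture(scope="session")
def small_cohort():
    """A shared desk-scale cohort: 12 participants, 16 regions, 10-s epochs."""
    spec = SyntheticCohortSpec(n_regions=16, n_participants=12,
                               epoch_seconds=10.0, seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(spec)


@pytest.fixture(scope="session")
def dk_cohort():
    """Study-layout cohort: 68 regions, 10 participants, 10-s epochs."""
    spec = SyntheticCohortSpec(n_regions=68, n_participants=10,
                               epoch_seconds=10.0, seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def circular_corr(a, b):
    """Fisher-Lee circular correlation coefficient (test oracle helper)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sa = np.sin(a - np.angle(np.exp(1j * a).mean()))
    sb = np.sin(b - np.angle(np.exp(1j * b).mean()))
    return float((sa * sb).sum() / np.sqrt((sa ** 2).sum() * (sb ** 2).sum()))
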