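import numpy as np
import pytest

import solscm as scm


@pytest.fixture(scope="session")
def benchmark_grid():
    return scm.benchmark_grid()


@pytest.fixture(scope="session")
def comb_sites():
    """Ideal comb: spacing 10000 on a 200 kb support (20 sites)."""
    return scm.benchmark_comb()


@pytest.fixture(scope="session")
def motif_train_sites():
    """Aperiodic 5-site motif repeated 8 times at period 10000 (40 sites)."""
    sites, spec = scm.benchmark_motif_train(seed=42)
    return sites, spec


@pytest.fixture(scope="session")
def two_train_mixture():
    """Two 3-site motif trains (periods 7270 and 10000) up to position 80000."""
    mix, spec = scm.benchmark_two_train_mixture(seed=0)
    return mix, spec


def designated_point_angles(R, n, rng):
    """Uniform circular configurations centered on a designated point.

    The designated point sits at angle 0 (rank 0 after sorting); the
    other n-1 angles are iid uniform.  Centering avoids the size bias of
    picking a site by rank relative to a fixed origin.
    """
    theta = np.concatenate([np.zeros((R, 1)), rng.random((R, n - 1))], axis=1)
    return np.sort(theta, axis=1)
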