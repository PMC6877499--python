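import numpy as np
import pytest

from loopmsm.synthetic import (default_spec, generate_ensemble,
                               three_state_spec, two_state_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def spec4():
    return default_spec(seed=7)


@pytest.fixture(scope="session")
def ensemble4(spec4):
    """Small 4-state ensemble shared across tests."""
    return generate_ensemble(spec4, n_traj=12, traj_len=800)


@pytest.fixture(scope="session")
def spec2():
    return two_state_spec(seed=11)


@pytest.fixture(scope="session")
def ensemble2(spec2):
    return generate_ensemble(spec2, n_traj=6, traj_len=1500)


@pytest.fixture(scope="session")
def spec3():
    return three_state_spec(seed=5)


def random_torsion_set(rng, L):
    """Generic per-residue (omega, phi, psi) torsions, wrapped, with the
    undefined terminal entries left NaN."""
    t = rng.uniform(-180.0, 180.0, size=(L, 3))
    t[0, 0] = np.nan
    t[0, 1] = np.nan
    t[-1, 2] = np.nan
    return t
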