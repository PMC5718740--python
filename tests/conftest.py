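import numpy as np
import pytest

from mammodose import materials as M
from mammodose import mc_transport as mc
from mammodose import phantom as ph


@pytest.fixture(scope="session")
def water():
    return M.water()


@pytest.fixture(scope="session")
def spectrum():
    return M.ir192_spectrum()


@pytest.fixture(scope="session")
def water_grid(water, spectrum):
    """A medium-sized MC run in uniform water, shared across tests.

    10 cm half-extent keeps a full-scatter margin (>= 5 cm) around every
    scored shell out to r = 5 cm, matching the infinite-medium assumption
    of the point-kernel oracle.
    """
    balloon = ph.BalloonGeometry(0.0, water)
    phantom = ph.build_phantom(balloon, water, 10.0)
    grid = mc.run_mc(
        phantom,
        mc.SourceModel(),
        spectrum,
        config=mc.McConfig(n_histories=1_000_000, seed=123),
    )
    return grid


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
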