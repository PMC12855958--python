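import numpy as np
import pytest

from specgen import lattice, synth


@pytest.fixture(scope="session")
def full_design():
    """The full 6-category / 51-exemplar / 24-view condition set."""
    return synth.make_stimulus_design()


@pytest.fixture(scope="session")
def small_design():
    """A compact design for fast metric tests: 2 categories, 7 exemplars."""
    return synth.make_stimulus_design(
        categories=("animal", "tool"),
        exemplars_per_category=(3, 4),
        n_views=5,
        n_spiky=2,
    )


@pytest.fixture(scope="session")
def quadrant_patterns_20():
    return synth.generate_lattice_patterns(20, 20)


@pytest.fixture(scope="session")
def coupling_20_global(quadrant_patterns_20):
    """Fully connected (lambda = 0) couplings on the 20 x 20 lattice."""
    cfg = lattice.LatticeConfig(height=20, width=20, lam=0.0, seed=1)
    return lattice.build_coupling(cfg, quadrant_patterns_20)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
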