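import numpy as np
import pytest

from sceit import (
    brain_spectra,
    build_circular_mesh,
    opposite_adjacent_protocol,
)


@pytest.fixture(scope="session")
def protocol():
    return opposite_adjacent_protocol()


@pytest.fixture(scope="session")
def tiny_mesh():
    """64-element disk (16 sectors, 2 rings) for finite-difference oracles."""
    return build_circular_mesh(1.0, 16, 64, n_sectors=16)


@pytest.fixture(scope="session")
def inverse_mesh():
    """The 512-element / 289-node reconstruction mesh."""
    return build_circular_mesh(300.0, 16, 512)


@pytest.fixture(scope="session")
def forward_mesh():
    """The 800-element / 441-node data-generation mesh."""
    return build_circular_mesh(300.0, 16, 800)


@pytest.fixture(scope="session")
def spectra():
    return brain_spectra()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
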