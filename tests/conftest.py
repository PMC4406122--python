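from __future__ import annotations

import numpy as np
import pytest

from pebblekit.fixtures import lattice_patch_network, random_small_net


@pytest.fixture
def rng():
    return np.random.default_rng(20150318)


@pytest.fixture
def lattice_patch():
    return lattice_patch_network()


@pytest.fixture(params=[3, 11, 27])
def small_net(request):
    """A few seeded small networks with enumerable fluctuating-edge ensembles."""
    return random_small_net(6, 9, fluct_fraction=0.5, seed=request.param)
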