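import numpy as np
import pytest

from ionbridge import synth
from ionbridge.core import assign_leaflets


@pytest.fixture(scope="session")
def small_bilayer():
    """64 molecules/leaflet physiological-composition bilayer, leaflets tagged."""
    spec = synth.physiological_composition(molecules_per_leaflet=64)
    traj = synth.build_bilayer(spec, seed=11)
    return assign_leaflets(traj)


@pytest.fixture(scope="session")
def small_spec():
    return synth.physiological_composition(molecules_per_leaflet=64)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
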