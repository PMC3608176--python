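import numpy as np
import pytest
from hypothesis import settings

from gpcrbundle import (
    BundleSpec,
    EnergyModel,
    default_membrane_params,
    default_packing_params,
    make_ideal_bundle,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

SMALL_SPEC = BundleSpec(helix_length=12, loop_length=6)


@pytest.fixture(scope="session")
def bundle():
    """Default ideal bundle: (structure, topology, membrane frame)."""
    return make_ideal_bundle()


@pytest.fixture(scope="session")
def small_bundle():
    """Shorter bundle for cheap framework-level tests."""
    return make_ideal_bundle(SMALL_SPEC)


@pytest.fixture(scope="session")
def energy_model(bundle):
    s, topo, frame = bundle
    return EnergyModel(topology=topo, packing=default_packing_params(), frame=frame)


@pytest.fixture(scope="session")
def small_energy_model(small_bundle):
    s, topo, frame = small_bundle
    return EnergyModel(
        topology=topo,
        packing=default_packing_params(SMALL_SPEC),
        frame=frame,
        membrane=default_membrane_params(SMALL_SPEC),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
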