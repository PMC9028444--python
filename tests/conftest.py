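import numpy as np
import pytest

from abseit.forward import ElectrodeModel, simulate_voltages
from abseit.mesh import build_mesh
from abseit.phantom import PhantomSpec, ShapeSpec, build_phantom


@pytest.fixture(scope="session")
def mesh_small():
    """Coarse symmetric mesh (576 elements) for fast solver tests."""
    return build_mesh(28.0, 6)


@pytest.fixture(scope="session")
def mesh_default():
    """The default 3136-element mesh."""
    return build_mesh(28.0, 14)


@pytest.fixture(scope="session")
def offcenter_spec():
    """One low-conductivity sphere, well off centre, no perturbation."""
    enc = ShapeSpec(kind="sphere", t=(0.4 * 28.0, 0.15 * 28.0, 0.0),
                    s=(0.2 * 28.0,) * 3, euler=(0.0, 0.0, 0.0), contrast=0.1)
    return PhantomSpec(sigma_bg=0.2, enclosures=(enc,), perturb_std=0.0)


@pytest.fixture(scope="session")
def offcenter_frame(mesh_small, offcenter_spec):
    ph = build_phantom(mesh_small, offcenter_spec)
    return simulate_voltages(mesh_small, ph.sigma, ElectrodeModel())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
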