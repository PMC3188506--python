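import numpy as np
import pytest

from allocomm.synthetic import make_helix_coordinates, straight_chain


@pytest.fixture(scope="session")
def helix20():
    """Ideal alpha-helical Calpha trace, 20 residues."""
    return make_helix_coordinates(20)


@pytest.fixture(scope="session")
def chain10():
    """Straight chain of 10 residues at 4 A spacing (hand-checkable geometry)."""
    return straight_chain(10, spacing=4.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rigid_transform(rng):
    """A random proper rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation

    quat = rng.standard_normal(4)
    quat /= np.linalg.norm(quat)
    return Rotation.from_quat(quat).as_matrix(), rng.normal(scale=20.0, size=3)
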