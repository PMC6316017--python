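import numpy as np
import pytest

from depthvol.geometry import Intrinsics
from depthvol.render import default_catalogue, make_primitive, render_sample


@pytest.fixture(scope="session")
def k_small() -> Intrinsics:
    """Quarter-VGA camera used throughout the unit tests."""
    return Intrinsics(fx=142.5, fy=142.5, cx=79.5, cy=59.5, width=160, height=120)


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def sphere_mesh(catalogue):
    return make_primitive(catalogue["sphere"])[0]


@pytest.fixture(scope="session")
def cube_mesh(catalogue):
    return make_primitive(catalogue["cube"])[0]


@pytest.fixture(scope="session")
def sphere_sample(sphere_mesh, k_small):
    """One rendered initial/opposite pair of the 3.65 cm sphere."""
    return render_sample(sphere_mesh, seed=42, k=k_small, object_id="sphere")


@pytest.fixture(scope="session")
def sphere_sample_vga(sphere_mesh):
    """Full-VGA rendered pair (rim sampling fine enough for tight volumes)."""
    from depthvol.geometry import DEFAULT_INTRINSICS

    return render_sample(sphere_mesh, seed=42, k=DEFAULT_INTRINSICS,
                         object_id="sphere")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
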