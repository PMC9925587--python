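import numpy as np
import pytest

from bisym import CpdConfig, RunConfig, TibiaShapeParams, TriangleMesh, generate_tibia

try:
    from hypothesis import settings
    settings.register_profile("ci", derandomize=True, max_examples=25,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def tibia_small():
    """Coarse synthetic tibia (resolution 2) for cheap geometric tests."""
    return generate_tibia(TibiaShapeParams(mesh_resolution=2))


@pytest.fixture(scope="session")
def tibia_default():
    """Default-resolution synthetic tibia."""
    return generate_tibia()


@pytest.fixture()
def fast_config():
    """Pipeline config with a reduced registration sample for test speed."""
    cfg = RunConfig()
    cfg.registration = CpdConfig(subsample_n=600)
    return cfg


@pytest.fixture()
def tetrahedron():
    v = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f)


@pytest.fixture()
def unit_cube():
    """Axis-aligned unit cube with outward winding (signed volume +1)."""
    v = np.array([[x, y, z] for x in (0.0, 1) for y in (0.0, 1) for z in (0.0, 1)])
    f = np.array([
        [0, 1, 3], [0, 3, 2],      # x = 0, inward normal -x
        [4, 7, 5], [4, 6, 7],      # x = 1
        [0, 4, 5], [0, 5, 1],      # y = 0
        [2, 3, 7], [2, 7, 6],      # y = 1
        [0, 2, 6], [0, 6, 4],      # z = 0
        [1, 5, 7], [1, 7, 3],      # z = 1
    ])
    return TriangleMesh(v, f)


def random_valid_mesh(rng: np.random.Generator, n_vertices=30, n_faces=40,
                      scale=100.0) -> TriangleMesh:
    """Random mesh with valid topology (helper for invariance tests)."""
    v = rng.uniform(-scale, scale, (n_vertices, 3))
    faces = []
    while len(faces) < n_faces:
        f = rng.choice(n_vertices, 3, replace=False)
        faces.append(f)
    return TriangleMesh(v, np.array(faces))
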