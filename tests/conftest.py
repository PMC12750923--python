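"""Shared fixtures: small analytic meshes and session-cached bone surrogates."""

import numpy as np
import pytest
import trimesh

from pairmorph.mesh_core import TriangleMesh
from pairmorph.synthetic_data import BoneSurrogateSpec, make_surrogate


@pytest.fixture
def tetrahedron() -> TriangleMesh:
    """Unit-edge regular tetrahedron with outward-oriented faces."""
    s = 1.0 / np.sqrt(2.0)
    v = np.array(
        [[1, 0, -s], [-1, 0, -s], [0, 1, s], [0, -1, s]], dtype=float
    ) * 0.5
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    mesh = TriangleMesh(v, f)
    if mesh.signed_volume() < 0:
        mesh = TriangleMesh(v, f[:, [0, 2, 1]])
    return mesh


@pytest.fixture
def sphere_mesh() -> TriangleMesh:
    """50 mm-radius sphere at ~5 mm edges."""
    s = trimesh.creation.icosphere(subdivisions=4, radius=50.0)
    return TriangleMesh.from_arrays(s.vertices, s.faces)


@pytest.fixture(scope="session")
def femur_surrogate() -> TriangleMesh:
    return make_surrogate(BoneSurrogateSpec(kind="femur", scale=70.0))


@pytest.fixture(scope="session")
def patella_surrogate() -> TriangleMesh:
    return make_surrogate(BoneSurrogateSpec(kind="patella", scale=38.0))


@pytest.fixture(scope="session")
def tibia_surrogate() -> TriangleMesh:
    return make_surrogate(BoneSurrogateSpec(kind="tibia", scale=75.0))


@pytest.fixture(scope="session")
def surrogates(femur_surrogate, patella_surrogate, tibia_surrogate):
    return {
        "femur": femur_surrogate,
        "patella": patella_surrogate,
        "tibia": tibia_surrogate,
    }
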