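import numpy as np
import pytest

from mandifem.mesh import LabeledMesh, promote_tet4_to_tet10, tet_box_mesh
from mandifem.scenarios import run_biting_suite
from mandifem.synthetic import MandibleParams, default_materials, generate_mandible_mesh


@pytest.fixture
def unit_tet() -> LabeledMesh:
    """Right tetrahedron with corners at the origin and unit axes (V = 1/6)."""
    coords = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    return LabeledMesh(coords, [[0, 1, 2, 3]], ["MM"], {"tip": [3]})


@pytest.fixture
def two_tets() -> LabeledMesh:
    """Two TET4 sharing the face (0, 1, 2)."""
    coords = np.array(
        [[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0.4, 0.4, -1.0]]
    )
    return LabeledMesh(coords, [[0, 1, 2, 3], [0, 2, 1, 4]], ["MM", "BLADE"], {})


@pytest.fixture
def box_tet10() -> LabeledMesh:
    return promote_tet4_to_tet10(tet_box_mesh((2.0, 1.0, 1.0), (4, 2, 2)))


@pytest.fixture(scope="session")
def coarse_mandible():
    """Small (~1.8k element) mandible for fast end-to-end tests."""
    return generate_mandible_mesh(MandibleParams(resolution=40.0))


@pytest.fixture(scope="session")
def coarse_suite(coarse_mandible):
    return run_biting_suite(coarse_mandible, default_materials())


@pytest.fixture(scope="session")
def materials():
    return default_materials()
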