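"""Shared fixtures: coarse synthetic heads, caps and lead fields.

Session-scoped so the expensive FEM objects are built once; all fixtures are
deterministic (fixed seeds, deterministic mesh generator).
"""

import numpy as np
import pytest

from cemfwd import (
    ConductivityModel,
    TetMesh,
    assemble_cem_system,
    assemble_stiffness,
    build_source_space,
    build_sphere_head,
    compute_lead_field,
    default_cap,
)


@pytest.fixture(scope="session")
def default_head():
    """Default-resolution head bundle (~48k tets) shared by the experiment
    and acceptance tests."""
    from cemfwd import ExperimentConfig, build_head

    return build_head(ExperimentConfig())


@pytest.fixture(scope="session")
def medium_bundle():
    """Validation-scale head bundle (~35k tets) with cap and source space."""
    from cemfwd import ExperimentConfig, build_head

    return build_head(ExperimentConfig(target_edge_length=0.0065))


@pytest.fixture(scope="session")
def small_head():
    """Coarse four-shell head (~10k tets) for fast unit tests."""
    return build_sphere_head(target_edge_length=0.009)


@pytest.fixture(scope="session")
def medium_head():
    """Mid-resolution head (~35k tets) for accuracy-sensitive tests."""
    return build_sphere_head(target_edge_length=0.0065)


@pytest.fixture(scope="session")
def small_cap(small_head):
    return default_cap(small_head, impedance=2000.0)


@pytest.fixture(scope="session")
def medium_cap(medium_head):
    return default_cap(medium_head, impedance=2000.0)


@pytest.fixture(scope="session")
def sigma_i():
    return ConductivityModel.model("I")


@pytest.fixture(scope="session")
def small_space(small_head):
    return build_source_space(small_head)


@pytest.fixture(scope="session")
def medium_space(medium_head):
    return build_source_space(medium_head)


@pytest.fixture(scope="session")
def small_stiffness(small_head, sigma_i):
    return assemble_stiffness(small_head, sigma_i)


@pytest.fixture(scope="session")
def small_cem(small_head, sigma_i, small_cap, small_stiffness):
    return assemble_cem_system(small_head, sigma_i, small_cap, stiffness=small_stiffness)


@pytest.fixture(scope="session")
def small_lead_field(small_cem, small_space):
    return compute_lead_field(small_cem, small_space.G, method="schur")


@pytest.fixture()
def two_tet_mesh():
    """Two unit tetrahedra sharing the face {0, 1, 2}; opposite nodes 3, 4."""
    nodes = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
            [1.0, 1.0, -1.0],
        ]
    )
    tets = np.array([[0, 1, 2, 3], [0, 1, 2, 4]])
    return TetMesh(nodes, tets, np.array([1, 1]))


@pytest.fixture()
def single_tet_mesh():
    nodes = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    return TetMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([1]))


@pytest.fixture(scope="session")
def fine_space():
    """Source space on a fine head; the deep eccentricity bands hold >= 100
    dipoles only at this resolution."""
    return build_source_space(build_sphere_head(target_edge_length=0.0035))
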