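"""Shared fixtures: small meshes, closed-form load helpers."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from eruptsim.geometry import GeometryConfig, TetMesh, build_labelled_grid, voxels_to_tets
from eruptsim.materials import REGION_CODES, RegionLabel


def make_box_mesh(nx: int, ny: int, nz: int, pitch: float = 1.0,
                  region: RegionLabel = RegionLabel.CANCELLOUS_BONE) -> TetMesh:
    """Homogeneous box of nx x ny x nz voxels split into tets."""
    grid = np.full((nx, ny, nz), REGION_CODES[region], dtype=np.int32)
    return voxels_to_tets(grid, pitch)


def face_census(mesh: TetMesh) -> Counter:
    """Count occurrences of every triangular face (as sorted node triples)."""
    faces = Counter()
    for el in mesh.elements:
        for tri in ([0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]):
            faces[tuple(sorted(el[tri]))] += 1
    return faces


def boundary_triangles(mesh: TetMesh) -> list:
    """Triangles lying on the mesh boundary (appear in exactly one tet)."""
    return [tri for tri, n in face_census(mesh).items() if n == 1]


def consistent_face_load(mesh: TetMesh, node_mask: np.ndarray,
                         traction: np.ndarray) -> np.ndarray:
    """Consistent nodal forces for a uniform traction on the boundary
    triangles whose three nodes all satisfy ``node_mask``."""
    forces = np.zeros((mesh.n_nodes, 3))
    for tri in boundary_triangles(mesh):
        tri = list(tri)
        if not node_mask[tri].all():
            continue
        a, b, c = mesh.nodes[tri]
        area = 0.5 * np.linalg.norm(np.cross(b - a, c - a))
        for n in tri:
            forces[n] += np.asarray(traction) * area / 3.0
    return forces


@pytest.fixture(scope="session")
def small_geometry() -> GeometryConfig:
    """Coarse tooth-in-crypt scene, small enough for fast solves."""
    return GeometryConfig(
        box=(16.0, 10.0, 12.0),
        pitch=1.0,
        crown_centre=(8.0, 5.0, 8.5),
        crown_radius=1.8,
        root_length=4.5,
        follicle_thickness=1.0,
    )


@pytest.fixture(scope="session")
def small_mesh(small_geometry) -> TetMesh:
    grid = build_labelled_grid(small_geometry)
    return voxels_to_tets(grid, small_geometry.pitch)


@pytest.fixture(scope="session")
def bar_mesh() -> TetMesh:
    """8 x 2 x 2 voxel bar used for closed-form uniaxial checks."""
    return make_box_mesh(8, 2, 2)
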