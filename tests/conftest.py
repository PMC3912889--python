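"""Shared fixtures: small analytic meshes and STL files built on the fly."""

import struct

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dentalign as dl

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------- geometry

CUBE_CORNERS = np.array(
    [
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ],
    dtype=float,
)
# 12 triangles, two per face, outward orientation
CUBE_FACES = np.array(
    [
        [0, 2, 1], [0, 3, 2],  # bottom (z=0)
        [4, 5, 6], [4, 6, 7],  # top (z=1)
        [0, 1, 5], [0, 5, 4],  # front (y=0)
        [2, 3, 7], [2, 7, 6],  # back (y=1)
        [1, 2, 6], [1, 6, 5],  # right (x=1)
        [3, 0, 4], [3, 4, 7],  # left (x=0)
    ]
)


@pytest.fixture
def cube_soup():
    """Unwelded 36-vertex triangle soup of the unit cube."""
    V = CUBE_CORNERS[CUBE_FACES].reshape(-1, 3)
    F = np.arange(36).reshape(-1, 3)
    return dl.TriangleMesh(V, F, welded=False)


@pytest.fixture
def cube_mesh(cube_soup):
    return dl.weld_vertices(cube_soup, 1e-6)


@pytest.fixture
def tetra_mesh():
    """Regular unit tetrahedron; vertex 3 is the apex."""
    V = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.5, np.sqrt(3) / 2, 0.0],
            [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)],
        ]
    )
    F = np.array([[0, 1, 3], [1, 2, 3], [2, 0, 3], [0, 2, 1]])
    return dl.mesh_from_arrays(V, F)


def grid_mesh(n=9, spacing=1.0, z=None):
    """Flat (or height-field) triangulated grid, independent triangulation."""
    xs = np.arange(n) * spacing
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    Z = np.zeros_like(X) if z is None else z(X, Y)
    V = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            v = i * n + j
            faces.append([v, v + n, v + n + 1])
            faces.append([v, v + n + 1, v + 1])
    return dl.mesh_from_arrays(V, np.array(faces))


@pytest.fixture
def flat_grid():
    return grid_mesh(9)


# ---------------------------------------------------------------- STL files


def write_binary_stl(path, triangles, facet_count=None, truncate=None):
    """Hand-rolled binary STL writer (oracle independent of the package).

    ``triangles`` is (n, 3, 3).  ``facet_count`` overrides the header
    count; ``truncate`` drops trailing bytes — both for malformed-file
    tests.
    """
    triangles = np.asarray(triangles, dtype=np.float32)
    blob = b"test header".ljust(80, b"\0")
    blob += struct.pack(
        "<I", len(triangles) if facet_count is None else facet_count
    )
    for t in triangles:
        blob += struct.pack("<3f", 0.0, 0.0, 0.0)
        for v in t:
            blob += struct.pack("<3f", *v)
        blob += struct.pack("<H", 0)
    if truncate:
        blob = blob[:-truncate]
    path.write_bytes(blob)
    return path


def write_ascii_stl(path, triangles):
    lines = ["solid test"]
    for t in np.asarray(triangles, float):
        lines.append("facet normal 0 0 0")
        lines.append("outer loop")
        for v in t:
            lines.append(f"vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
        lines.append("endloop")
        lines.append("endfacet")
    lines.append("endsolid test")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def unit_triangle():
    return np.array([[[0, 0, 0], [1, 0, 0], [0, 1, 0]]], dtype=float)
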