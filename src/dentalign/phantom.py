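"""Synthetic dental-like mesh pairs with known ground-truth transforms.

The phantom is a triangulated height field: a smooth arch-like dome plus
a few Gaussian "cusps" (localized high-curvature bumps), mimicking an
occlusal surface.  From one phantom, :func:`make_pair` produces

* a *reference* mesh — the full surface, vertex-subsampled and
  re-triangulated (the coarse, full-coverage CT analogue), and
* a *target* mesh — a dense crop of the cusp-rich region, displaced by a
  seeded random rigid transform with optional measurement noise (the
  high-resolution, crown-only optical-scan analogue),

together with the ground-truth rigid transform mapping the target back
into the reference frame.  Identical seeds reproduce bit-identical
meshes, so every registration stage can be tested against known truth.

A closed bumpy icosphere (via trimesh) is also provided; being genus 0 it
serves the discrete Gauss-Bonnet check, which open height fields cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import Delaunay

from .curvature import all_curvatures
from .errors import PhantomError
from .mesh_io import TriangleMesh, mesh_from_arrays
from .rigid import RigidTransform

DEFAULT_N_CUSPS = 4
DEFAULT_BASE_SIZE = 30.0  # mm
DEFAULT_GRID_RES = 64
DEFAULT_ROTATION_MAX = 30.0  # degrees
DEFAULT_TRANSLATION_MAX = 20.0  # mm
DEFAULT_CROP_FRACTION = 0.5
DEFAULT_KEEP_FRACTION = 0.3
DEFAULT_NOISE_SD = 0.05  # mm


@dataclass
class PhantomPair:
    """Reference/target meshes plus the truth that registration must find."""

    reference: TriangleMesh
    target: TriangleMesh
    ground_truth: RigidTransform  # maps target into the reference frame
    noise_sd: float
    seed: int


def make_phantom(
    n_cusps: int = DEFAULT_N_CUSPS,
    base_size: float = DEFAULT_BASE_SIZE,
    grid_res: int = DEFAULT_GRID_RES,
    seed: int = 0,
    cusp_height: tuple[float, float] = (1.5, 2.5),
    cusp_width: tuple[float, float] = (1.5, 2.5),
    arch_height: float = 3.0,
    with_info: bool = False,
):
    """Triangulated height field: smooth dome plus ``n_cusps`` Gaussian bumps.

    Bump centers are seeded uniformly within the central 60% of the
    square, kept at least two mean widths apart; heights/widths are drawn
    from the given ranges.  Bump apices are curvature maxima; the dome
    background stays well below the default feature threshold.  A zero
    height range gives the flat(-ish) featureless variant.

    With ``with_info`` the planted ground truth is returned alongside the
    mesh: ``(mesh, {"centers": (n,2), "heights": (n,), "widths": (n,)})``.
    """
    if n_cusps < 1:
        raise ValueError("n_cusps must be >= 1")
    if grid_res < 16:
        raise ValueError("grid_res must be >= 16")
    rng = np.random.default_rng(seed)
    coords = np.linspace(0.0, base_size, grid_res)
    X, Y = np.meshgrid(coords, coords, indexing="ij")
    c = base_size / 2.0
    dome_sigma = base_size / 2.2
    Z = arch_height * np.exp(-((X - c) ** 2 + (Y - c) ** 2) / (2 * dome_sigma**2))

    lo, hi = 0.2 * base_size, 0.8 * base_size
    min_sep = 2.0 * np.mean(cusp_width)
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_cusps and attempts < 10_000:
        p = rng.uniform(lo, hi, size=2)
        attempts += 1
        if all(np.linalg.norm(p - q) >= min_sep for q in centers):
            centers.append(p)
    if len(centers) < n_cusps:
        raise PhantomError(
            f"could not place {n_cusps} cusps at separation {min_sep:.2f} mm"
        )
    heights, widths = [], []
    for cx, cy in centers:
        h = rng.uniform(*cusp_height)
        w = rng.uniform(*cusp_width)
        heights.append(h)
        widths.append(w)
        Z = Z + h * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * w**2))

    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    faces = _grid_faces(grid_res, grid_res)
    mesh = mesh_from_arrays(vertices, faces)
    if with_info:
        return mesh, {
            "centers": np.array(centers),
            "heights": np.array(heights),
            "widths": np.array(widths),
        }
    return mesh


def _grid_faces(nx: int, ny: int) -> np.ndarray:
    """Two triangles per cell of an nx-by-ny vertex grid."""
    i, j = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
    v00 = (i * ny + j).ravel()
    v01 = v00 + 1
    v10 = v00 + ny
    v11 = v10 + 1
    return np.concatenate(
        [
            np.column_stack([v00, v10, v11]),
            np.column_stack([v00, v11, v01]),
        ]
    )


def make_bumpy_sphere(
    seed: int = 0,
    radius: float = 10.0,
    n_bumps: int = 6,
    bump_height: float = 1.0,
    subdivisions: int = 3,
) -> TriangleMesh:
    """Closed genus-0 fixture: icosphere with radial Gaussian bumps.

    Used for Gauss-Bonnet validation (total angle deficit 4*pi regardless
    of the bumps).
    """
    rng = np.random.default_rng(seed)
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    V = np.asarray(ico.vertices, float).copy()
    dirs = V / np.linalg.norm(V, axis=1)[:, None]
    for _ in range(n_bumps):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = np.arccos(np.clip(dirs @ axis, -1.0, 1.0))
        V += dirs * (bump_height * np.exp(-((ang / 0.3) ** 2)))[:, None]
    return mesh_from_arrays(V, np.asarray(ico.faces))


def random_rigid_transform(
    rotation_max: float, translation_max: float, seed=None
) -> RigidTransform:
    """Seeded rigid transform with bounded rotation angle and translation.

    Axis uniform on the sphere, angle uniform in [0, rotation_max]
    degrees, translation along a uniform direction with magnitude uniform
    in [0, translation_max] mm.  Bounds (0, 0) give the identity.
    """
    if rotation_max < 0 or translation_max < 0:
        raise ValueError("bounds must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, rotation_max))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    tdir = rng.normal(size=3)
    tdir /= np.linalg.norm(tdir)
    T = tdir * rng.uniform(0.0, translation_max)
    return RigidTransform(R, T)


def make_pair(
    phantom: TriangleMesh,
    rotation_max: float = DEFAULT_ROTATION_MAX,
    translation_max: float = DEFAULT_TRANSLATION_MAX,
    crop_fraction: float = DEFAULT_CROP_FRACTION,
    decimate_keep_fraction: float = DEFAULT_KEEP_FRACTION,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    noise_mode: str = "normal",
) -> PhantomPair:
    """Build a reference/target pair from one phantom surface.

    Reference: a seeded random ``decimate_keep_fraction`` of the vertices,
    re-triangulated by planar Delaunay (the coarse full-coverage mesh).
    Target: the faces of the full-resolution phantom inside a square
    window of relative area ``crop_fraction`` centred on the
    high-curvature (cusp) region, displaced by a seeded random rigid
    transform and perturbed by Gaussian noise of sd ``noise_sd`` mm —
    along vertex normals by default (``noise_mode="normal"``), or
    isotropically (``"isotropic"``).

    The returned ground truth maps the displaced target back into the
    reference frame.  Raises :class:`PhantomError` when the crop window
    contains no cusp (feature-based registration would be impossible).
    """
    if not (0 < crop_fraction <= 1):
        raise ValueError("crop_fraction must be in (0, 1]")
    if not (0 < decimate_keep_fraction <= 1):
        raise ValueError("decimate_keep_fraction must be in (0, 1]")
    if noise_mode not in ("normal", "isotropic"):
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    rng = np.random.default_rng(seed)
    V = phantom.vertices

    # ---- reference: structured vertex subsample, re-triangulated in the
    # plane.  A regular coarse sampling mimics a CT-derived surface mesh
    # and, unlike a random subsample, does not create sliver triangles
    # whose tiny one-rings produce spurious curvature spikes.
    if decimate_keep_fraction >= 1.0:
        reference = phantom
    else:
        stride = 1.0 / np.sqrt(decimate_keep_fraction)
        xs = np.unique(np.round(V[:, 0], 9))
        ys = np.unique(np.round(V[:, 1], 9))
        kx = xs[np.unique(np.round(np.arange(0, len(xs) - 0.5, stride)).astype(int))]
        ky = ys[np.unique(np.round(np.arange(0, len(ys) - 0.5, stride)).astype(int))]
        keep = np.flatnonzero(
            np.isin(np.round(V[:, 0], 9), kx) & np.isin(np.round(V[:, 1], 9), ky)
        )
        kv = V[keep]
        tri = Delaunay(kv[:, :2])
        reference = mesh_from_arrays(kv, tri.simplices)

    # ---- target: dense crop of the cusp region
    K = all_curvatures(phantom)
    finite = np.where(np.isfinite(K), K, -np.inf)
    n_top = max(1, int(0.1 * np.isfinite(K).sum()))
    top = np.argsort(finite)[::-1][:n_top]
    center = V[top, :2].mean(axis=0)
    lo, hi = V[:, :2].min(axis=0), V[:, :2].max(axis=0)
    xr, yr = hi - lo
    half = 0.5 * np.sqrt(crop_fraction * xr * yr)
    # keep the window inside the surface footprint (degenerates to the
    # full surface when crop_fraction == 1)
    center = np.where(
        lo + half < hi - half,
        np.clip(center, lo + half, hi - half),
        (lo + hi) / 2.0,
    )
    inside = (np.abs(V[:, 0] - center[0]) <= half + 1e-9) & (
        np.abs(V[:, 1] - center[1]) <= half + 1e-9
    )
    face_in = inside[phantom.faces].all(axis=1)
    if not face_in.any():
        raise PhantomError("crop window contains no complete face")
    crop_faces = phantom.faces[face_in]
    used = np.unique(crop_faces)
    remap = -np.ones(len(V), dtype=np.int64)
    remap[used] = np.arange(len(used))
    crop = mesh_from_arrays(V[used], remap[crop_faces])

    cusp_threshold = 0.01
    if not np.any(np.where(np.isfinite(K[used]), K[used], -np.inf) > cusp_threshold):
        raise PhantomError(
            "crop window contains no cusp; the pair would be unregistrable "
            "by curvature features"
        )

    # ---- displace: ground truth maps target -> reference frame
    displace = random_rigid_transform(rotation_max, translation_max, rng)
    pts = crop.vertices
    if noise_sd > 0:
        if noise_mode == "normal":
            pts = pts + crop.vertex_normals() * rng.normal(
                0.0, noise_sd, size=len(pts)
            )[:, None]
        else:
            pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    target = mesh_from_arrays(displace.apply(pts), crop.faces)
    return PhantomPair(
        reference=reference,
        target=target,
        ground_truth=displace.inverse(),
        noise_sd=noise_sd,
        seed=seed,
    )
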