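"""Constraint-based three-point coarse registration.

Three reference points with top-decile curvature and homogeneous spatial
spread are picked on the reference model.  For each, the target model's
feature vertices with similar curvature form a candidate list; the triple
of candidates that matches the reference triple's three side lengths
(distance constraint) and triangle area (area constraint) — both rigid
invariants — is the correspondence.  The two local orthonormal frames
built on the triples then give the coarse rotation R = T_n T_m^T and
translation from the triple centroids.

Thresholds:

``curv_tol``
    max curvature difference (1/mm^2) for a candidate.  The documented
    default 1.5e-4 presumes both meshes sample the surface at comparable
    density; across resolutions the discrete estimate itself shifts by
    far more, so cross-resolution runs need a looser value (see
    RunConfig.phantom()).
``dist_tol`` / ``area_tol``
    max side-length deviation (mm) and area deviation (mm^2) for an
    accepted triple; they bound how far the matched vertices may sit from
    the true corresponding surface points, so they must exceed the coarser
    mesh's sampling spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist

from .curvature import FeaturePointSet
from .errors import DegenerateGeometryError, NoMatchError, SelectionError
from .rigid import RigidTransform

DEFAULT_CURV_TOL = 0.00015  # 1/mm^2
DEFAULT_DIST_TOL = 2.0  # mm
DEFAULT_AREA_TOL = 20.0  # mm^2
DEFAULT_CANDIDATE_CAP = 64
_COLLINEAR_REL = 1e-9


@dataclass
class CorrespondenceTriple:
    """Matched point triples with their constraint residuals."""

    ref_indices: np.ndarray  # mesh-vertex indices (m1, m2, m3)
    target_indices: np.ndarray  # mesh-vertex indices (n1, n2, n3)
    ref_points: np.ndarray  # (3, 3) mm
    target_points: np.ndarray  # (3, 3) mm
    curvature_deviations: np.ndarray  # (3,) 1/mm^2
    side_deviations: np.ndarray  # (3,) |d_mimj - d_ninj| mm
    area_deviation: float  # |S(m) - S(n)| mm^2
    verification_score: float | None = None  # mean NN misalignment (mm)


def triangle_sides(p1, p2, p3) -> tuple[float, float, float]:
    """(a, b, c) = distances (p1,p2), (p1,p3), (p2,p3)."""
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    return (
        float(np.linalg.norm(p1 - p2)),
        float(np.linalg.norm(p1 - p3)),
        float(np.linalg.norm(p2 - p3)),
    )


def triangle_area(a: float, b: float, c: float, tol: float = 1e-9) -> float:
    """Heron's formula S = sqrt(s(s-a)(s-b)(s-c)), s = (a+b+c)/2.

    Degenerate (collinear) side triples give 0; a triangle-inequality
    violation beyond ``tol`` (relative to the semi-perimeter) raises.
    """
    if min(a, b, c) < 0:
        raise DegenerateGeometryError("negative side length")
    s = (a + b + c) / 2.0
    val = s * (s - a) * (s - b) * (s - c)
    if val < 0:
        scale = max(s, 1.0) ** 4
        if val < -tol * scale:
            raise DegenerateGeometryError(
                f"sides ({a}, {b}, {c}) violate the triangle inequality"
            )
        val = 0.0
    return float(np.sqrt(val))


def _is_collinear(p1, p2, p3) -> bool:
    u = np.asarray(p3, float) - np.asarray(p1, float)
    v = np.asarray(p2, float) - np.asarray(p1, float)
    return np.linalg.norm(np.cross(u, v)) < _COLLINEAR_REL * np.linalg.norm(
        u
    ) * np.linalg.norm(v)


def select_reference_points(features: FeaturePointSet) -> np.ndarray:
    """Three spread-out mesh-vertex indices from the top curvature decile.

    "Homogeneously distributed" is operationalized as the triple that
    maximizes the minimum pairwise distance: exhaustively over all triples
    when at most 50 points are eligible, otherwise by a farthest-point
    heuristic (the most distant pair plus the point maximizing the minimum
    distance to it).
    """
    n = len(features)
    if n < 3:
        raise SelectionError(f"need at least 3 feature points, got {n}")
    # top decile, but with a floor so sparse feature sets still offer a
    # spatially spread triple rather than three vertices of one cusp
    k = min(n, max(30, int(np.ceil(0.1 * n))))
    order = np.argsort(features.curvatures)[::-1]
    eligible = order[:k]
    pts = features.mesh.vertices[features.indices[eligible]]

    if len(eligible) <= 50:
        d = cdist(pts, pts)
        best, best_score = None, -1.0
        for i, j, l in combinations(range(len(eligible)), 3):
            score = min(d[i, j], d[i, l], d[j, l])
            if score > best_score and not _is_collinear(pts[i], pts[j], pts[l]):
                best, best_score = (i, j, l), score
        if best is None:
            raise SelectionError("all eligible feature triples are collinear")
        chosen = np.array(best)
    else:
        d = cdist(pts, pts)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        dmin = np.minimum(d[i], d[j])
        dmin[[i, j]] = -1.0
        for l in np.argsort(dmin)[::-1]:
            if dmin[l] <= 0:
                raise SelectionError("all eligible feature triples are collinear")
            if not _is_collinear(pts[i], pts[j], pts[l]):
                chosen = np.array([i, j, l])
                break
        else:  # pragma: no cover - exhausted loop handled above
            raise SelectionError("all eligible feature triples are collinear")
    return features.indices[eligible[chosen]]


def candidate_correspondences(
    ref_curvature: float, target_features: FeaturePointSet, curv_tol: float
) -> np.ndarray:
    """Positions (into the feature set) of target vertices whose curvature
    is within ``curv_tol`` of the reference point's, ascending deviation."""
    if curv_tol <= 0:
        raise ValueError("curv_tol must be > 0")
    dev = np.abs(target_features.curvatures - ref_curvature)
    hits = np.flatnonzero(dev < curv_tol)
    return hits[np.argsort(dev[hits], kind="stable")]


def match_triple(
    ref_points,
    ref_curvatures,
    target_features: FeaturePointSet,
    curv_tol: float = DEFAULT_CURV_TOL,
    dist_tol: float = DEFAULT_DIST_TOL,
    area_tol: float = DEFAULT_AREA_TOL,
    candidate_cap: int = DEFAULT_CANDIDATE_CAP,
    ref_indices=None,
    verify: tuple | None = None,
    verify_top: int = 50,
) -> CorrespondenceTriple:
    """Find the target triple matching the reference triple's geometry.

    Candidate lists (capped at ``candidate_cap`` per reference point, by
    ascending curvature deviation) are searched exhaustively; a triple
    survives when all three side-length deviations are below ``dist_tol``,
    the area deviation is below ``area_tol``, and its vertices are
    distinct.  Among survivors the combined normalized residual
    sum(side dev)/dist_tol + area dev/area_tol is minimized.

    When candidate lists are large (loose ``curv_tol``), a coincidental
    triple can reproduce the reference triangle's geometry better than the
    true correspondence does, so the geometric residual alone misleads.
    Passing ``verify = (reference_cloud, target_cloud)`` re-ranks the
    ``verify_top`` best survivors by the quality of the rigid transform
    each implies: the mean nearest-neighbour distance from the transformed
    target cloud to the reference cloud.  The winner still satisfies all
    constraints; verification only chooses among survivors.
    """
    ref_points = np.asarray(ref_points, float).reshape(3, 3)
    ref_curvatures = np.asarray(ref_curvatures, float).reshape(3)
    cands = []
    for k in range(3):
        c = candidate_correspondences(ref_curvatures[k], target_features, curv_tol)
        if len(c) == 0:
            raise NoMatchError(
                f"reference point {k} has no curvature-similar candidate "
                f"(curv_tol={curv_tol})"
            )
        cands.append(c[:candidate_cap])

    a_ref, b_ref, c_ref = triangle_sides(*ref_points)
    s_ref = triangle_area(a_ref, b_ref, c_ref)

    pos = [target_features.positions()[c] for c in cands]
    vid = [target_features.indices[c] for c in cands]
    d12 = cdist(pos[0], pos[1])
    d13 = cdist(pos[0], pos[2])
    d23 = cdist(pos[1], pos[2])
    dev12 = np.abs(d12 - a_ref)
    dev13 = np.abs(d13 - b_ref)
    dev23 = np.abs(d23 - c_ref)

    distinct = (
        (vid[0][:, None, None] != vid[1][None, :, None])
        & (vid[0][:, None, None] != vid[2][None, None, :])
        & (vid[1][None, :, None] != vid[2][None, None, :])
    )
    combined_sides = (
        dev12[:, :, None] + dev13[:, None, :] + dev23[None, :, :]
    ) / dist_tol
    ok = (
        distinct
        & (dev12[:, :, None] < dist_tol)
        & (dev13[:, None, :] < dist_tol)
        & (dev23[None, :, :] < dist_tol)
    )

    def _areas(i, j, l):
        s = (d12[i, j] + d13[i, l] + d23[j, l]) / 2.0
        val = s * (s - d12[i, j]) * (s - d13[i, l]) * (s - d23[j, l])
        return np.sqrt(np.maximum(val, 0.0))

    if not ok.any():
        best = None
        if distinct.any():
            masked = np.where(distinct, combined_sides, np.inf)
            i, j, l = np.unravel_index(np.argmin(masked), masked.shape)
            best = {
                "side_deviations": [dev12[i, j], dev13[i, l], dev23[j, l]],
                "area_deviation": float(abs(_areas(i, j, l) - s_ref)),
            }
        raise NoMatchError(
            "no candidate triple satisfies the distance constraints "
            f"(dist_tol={dist_tol})",
            best_residuals=best,
        )

    ii, jj, ll = np.nonzero(ok)
    area_dev = np.abs(_areas(ii, jj, ll) - s_ref)
    pass_area = area_dev < area_tol
    if not pass_area.any():
        i = int(np.argmin(area_dev))
        raise NoMatchError(
            f"no candidate triple satisfies the area constraint "
            f"(area_tol={area_tol}); best area deviation "
            f"{float(area_dev[i]):.4g} mm^2",
            best_residuals={
                "side_deviations": [
                    dev12[ii[i], jj[i]],
                    dev13[ii[i], ll[i]],
                    dev23[jj[i], ll[i]],
                ],
                "area_deviation": float(area_dev[i]),
            },
        )
    ii, jj, ll, area_dev = ii[pass_area], jj[pass_area], ll[pass_area], area_dev[pass_area]
    residual = (
        combined_sides[ii, jj, ll] + area_dev / area_tol
    )
    score = None
    if verify is not None and len(residual) > 1:
        from scipy.spatial import cKDTree  # local import to avoid cycle at top

        ref_cloud, tgt_cloud = (np.asarray(a, float) for a in verify)
        tree = cKDTree(ref_cloud)
        top = np.argsort(residual, kind="stable")[: min(verify_top, len(residual))]
        best_w, best_score = None, np.inf
        for w in top:
            i, j, l = int(ii[w]), int(jj[w]), int(ll[w])
            n_pts = np.vstack([pos[0][i], pos[1][j], pos[2][l]])
            try:
                t = coarse_transform(n_pts, ref_points)  # target -> reference
            except DegenerateGeometryError:
                continue
            s = float(np.mean(tree.query(t.apply(tgt_cloud))[0]))
            if s < best_score:
                best_w, best_score = int(w), s
        if best_w is None:
            raise NoMatchError(
                "all constraint-satisfying candidate triples are collinear"
            )
        w = best_w
        score = best_score
    else:
        w = int(np.argmin(residual))
    i, j, l = int(ii[w]), int(jj[w]), int(ll[w])
    sel = [cands[0][i], cands[1][j], cands[2][l]]
    if ref_indices is None:
        ref_indices = np.full(3, -1)
    return CorrespondenceTriple(
        ref_indices=np.asarray(ref_indices, dtype=np.int64),
        target_indices=np.array(
            [vid[0][i], vid[1][j], vid[2][l]], dtype=np.int64
        ),
        ref_points=ref_points,
        target_points=np.vstack([pos[0][i], pos[1][j], pos[2][l]]),
        curvature_deviations=np.array(
            [
                abs(target_features.curvatures[sel[k]] - ref_curvatures[k])
                for k in range(3)
            ]
        ),
        side_deviations=np.array([dev12[i, j], dev13[i, l], dev23[j, l]]),
        area_deviation=float(area_dev[w]),
        verification_score=score,
    )


def local_frame(p1, p2, p3) -> np.ndarray:
    """Orthonormal frame with columns (t1, t2, t3):

    t1 = (p3 - p1)/|p3 - p1|,
    t2 = (p3 - p1) x (p2 - p1), normalized,
    t3 = t1 x t2.
    """
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    u = p3 - p1
    v = p2 - p1
    cr = np.cross(u, v)
    nu, nv, ncr = np.linalg.norm(u), np.linalg.norm(v), np.linalg.norm(cr)
    if nu == 0 or nv == 0 or ncr < _COLLINEAR_REL * nu * nv:
        raise DegenerateGeometryError("frame points are collinear or coincident")
    t1 = u / nu
    t2 = cr / ncr
    t3 = np.cross(t1, t2)
    return np.column_stack([t1, t2, t3])


def coarse_transform(m_triple, n_triple) -> RigidTransform:
    """Rigid transform mapping the m triple onto the n triple.

    R = T_n T_m^T from the two local frames; T moves the centroid of m
    onto the centroid of n.  Exact when the triples are exact rigid
    images of each other.
    """
    m = np.asarray(m_triple, float).reshape(3, 3)
    n = np.asarray(n_triple, float).reshape(3, 3)
    Tm = local_frame(*m)
    Tn = local_frame(*n)
    R = Tn @ Tm.T
    T = n.mean(axis=0) - R @ m.mean(axis=0)
    return RigidTransform(R, T)
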