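"""ICP refinement with unique k-d-tree correspondences.

Starting from the coarse transform, each iteration (a) transforms the
target point set P by the latest incremental transform, (b) finds for
each transformed p its closest reference point q (k-d tree), (c) computes
the mean corresponding-point distance r, stops when |r_{k+1} - r_k| <= mu,
and otherwise (d) estimates an incremental rigid transform between the
current P and its correspondences by least-squares SVD, accumulates it,
and repeats.

Correspondence uniqueness: each reference point may be claimed by at most
one target point.  Tentative (p, q) pairs from a growing k-nearest search
are sorted by distance (ties by lower reference index — deterministic)
and assigned greedily, skipping claimed reference points; points whose
candidates are exhausted re-query with a doubled k.  The classic
non-unique assignment is also available; with it the squared-error
objective is provably non-increasing, while the unique mode trades that
guarantee for robustness to density mismatch (many dense target points
collapsing onto one coarse reference point).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import EstimationError
from .rigid import RigidTransform, estimate_svd

DEFAULT_MU = 1e-6  # mm
DEFAULT_MAX_ITER = 100


@dataclass
class ICPResult:
    """Outcome of :func:`icp_register`.

    ``transform`` is cumulative: it maps the *original* target points into
    the reference frame (the init transform composed with all incremental
    updates).  ``residuals`` holds r_0 .. r_K (mm), one more entry than
    ``iterations``.  ``objective`` tracks the summed squared distance at
    each iteration (the quantity that is monotone under the classic
    assignment).
    """

    transform: RigidTransform
    residuals: np.ndarray
    iterations: int
    converged: bool
    stop_reason: str  # "tolerance" | "max_iter"
    objective: np.ndarray = field(default=None, repr=False)


def _is_identity(t: RigidTransform) -> bool:
    return np.array_equal(t.R, np.eye(3)) and not t.T.any()


def nearest(Q, P) -> np.ndarray:
    """Classic assignment: index into Q of the closest point to each p."""
    _, idx = cKDTree(Q).query(P)
    return np.asarray(idx, dtype=np.int64)


def nearest_unique(Q, P) -> np.ndarray:
    """Unique assignment: index into Q per p, no q claimed twice.

    Greedy by globally ascending pair distance: conceptually all |P|x|Q|
    pairs are scanned in order of (distance, reference index) and a pair
    is kept whenever both its points are still free.  Implemented lazily
    with a priority queue over each target point's next-nearest unclaimed
    candidate (k-d tree, candidate lists grown on demand), which yields
    exactly the same assignment without materializing all pairs.
    Requires |P| <= |Q|.
    """
    import heapq

    Q = np.asarray(Q, float).reshape(-1, 3)
    P = np.asarray(P, float).reshape(-1, 3)
    if len(P) > len(Q):
        raise ValueError(
            f"unique assignment needs |P| <= |Q|, got {len(P)} > {len(Q)}"
        )
    tree = cKDTree(Q)
    n_q = len(Q)
    k0 = min(n_q, 4)
    d0, i0 = tree.query(P, k=k0)
    d0 = np.atleast_2d(d0)
    i0 = np.atleast_2d(i0)
    cand_d = [d0[i] for i in range(len(P))]
    cand_i = [i0[i] for i in range(len(P))]
    cursor = np.zeros(len(P), dtype=np.int64)

    def push(heap, p):
        """Queue p's next candidate, growing its k-NN list when drained."""
        while cursor[p] >= len(cand_i[p]):
            if len(cand_i[p]) >= n_q:
                return  # fully exhausted; cannot happen before assignment
            k = min(n_q, 2 * len(cand_i[p]))
            d, idx = tree.query(P[p], k=k)
            cand_d[p] = np.atleast_1d(d)
            cand_i[p] = np.atleast_1d(idx)
        c = cursor[p]
        heapq.heappush(heap, (float(cand_d[p][c]), int(cand_i[p][c]), int(p)))

    heap: list = []
    for p in range(len(P)):
        push(heap, p)
    assignment = np.full(len(P), -1, dtype=np.int64)
    claimed = np.zeros(n_q, dtype=bool)
    remaining = len(P)
    while remaining:
        _, q, p = heapq.heappop(heap)
        if assignment[p] != -1:
            continue
        if not claimed[q]:
            assignment[p] = q
            claimed[q] = True
            remaining -= 1
        else:
            cursor[p] += 1
            push(heap, p)
    return assignment


def residual(P, D) -> float:
    """Mean (unsquared) Euclidean distance between paired points (mm)."""
    P = np.asarray(P, float).reshape(-1, 3)
    D = np.asarray(D, float).reshape(-1, 3)
    if len(P) != len(D):
        raise ValueError(f"point-set sizes differ: {len(P)} vs {len(D)}")
    return float(np.linalg.norm(P - D, axis=1).mean())


class MeshSurface:
    """Closest-point-on-surface queries against a triangle mesh.

    Candidate faces come from the ``k`` nearest face centroids (k-d
    tree); the exact closest point on each candidate triangle is then
    computed and the best taken.  On meshes with reasonably uniform
    triangle size the candidate set contains the true closest face; a
    larger ``k`` trades speed for robustness on irregular meshes.
    """

    def __init__(self, mesh, k: int = 8):
        self.triangles = mesh.vertices[mesh.faces]
        self._tree = cKDTree(self.triangles.mean(axis=1))
        self.k = min(k, len(self.triangles))

    def query(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Closest surface points and distances for each query point."""
        p = np.asarray(points, float).reshape(-1, 3)
        _, fi = self._tree.query(p, k=self.k)
        fi = np.atleast_2d(fi)
        cand = self.triangles[fi]  # (n, k, 3, 3)
        cp = _closest_point_triangles(p, cand)
        d2 = ((p[:, None, :] - cp) ** 2).sum(-1)
        w = np.argmin(d2, axis=1)
        rows = np.arange(len(p))
        return cp[rows, w], np.sqrt(d2[rows, w])


def _closest_point_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each candidate triangle (Ericson's region test).

    ``p`` is (n, 3); ``tri`` is (n, k, 3, 3); returns (n, k, 3).
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    ab, ac = b - a, c - a
    ap = p[:, None, :] - a
    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p[:, None, :] - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp_ = p[:, None, :] - c
    d5 = np.einsum("...i,...i->...", ab, cp_)
    d6 = np.einsum("...i,...i->...", ac, cp_)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    denom = np.where(denom != 0, denom, 1.0)
    v = vb / denom
    w = vc / denom
    out = a + ab * v[..., None] + ac * w[..., None]  # face interior default
    mA = (d1 <= 0) & (d2 <= 0)
    mB = (d3 >= 0) & (d4 <= d3)
    mC = (d6 >= 0) & (d5 <= d6)
    shape = np.broadcast_shapes(out.shape, a.shape)
    out = np.broadcast_to(out, shape).copy()
    out[mA] = np.broadcast_to(a, shape)[mA]
    out[mB] = np.broadcast_to(b, shape)[mB]
    out[mC] = np.broadcast_to(c, shape)[mC]
    done = mA | mB | mC
    mAB = (vc <= 0) & (d1 >= 0) & (d3 <= 0) & ~done
    t = d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3)
    out[mAB] = (a + ab * t[..., None])[mAB]
    done |= mAB
    mAC = (vb <= 0) & (d2 >= 0) & (d6 <= 0) & ~done
    t = d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6)
    out[mAC] = (a + ac * t[..., None])[mAC]
    done |= mAC
    mBC = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0) & ~done
    num, den = d4 - d3, (d4 - d3) + (d5 - d6)
    t = num / np.where(den == 0, 1.0, den)
    out[mBC] = (b + (c - b) * t[..., None])[mBC]
    return out


def icp_register_surface(
    P,
    ref_mesh,
    init: RigidTransform | None = None,
    mu: float = DEFAULT_MU,
    max_iter: int = DEFAULT_MAX_ITER,
    surface: MeshSurface | None = None,
) -> ICPResult:
    """ICP with closest-point-on-*surface* correspondences.

    Same iteration scheme and stopping rule as :func:`icp_register`, but
    each target point pairs with its exact closest point on the
    reference triangle mesh instead of the closest reference vertex.
    This removes the vertex-sampling quantization that biases
    point-to-point correspondences when the reference is much coarser
    than the target; the update is still the rigid point-to-point SVD
    estimate (not a point-to-plane linearization).
    """
    P = np.asarray(P, float).reshape(-1, 3)
    if len(P) < 3:
        raise EstimationError(f"need at least 3 target points, got {len(P)}")
    if init is None:
        init = RigidTransform.identity()
    surf = surface if surface is not None else MeshSurface(ref_mesh)

    P_k = P
    step = init
    cumulative = RigidTransform.identity()
    D, d = surf.query(P_k)
    r_prev = float(d.mean())
    residuals = [r_prev]
    objective = [float((d**2).sum())]
    converged = False
    iterations = 0
    if _is_identity(init):
        try:
            step = estimate_svd(P_k, D)
        except EstimationError:
            pass
    for _ in range(max_iter):
        P_k = step.apply(P_k)
        cumulative = step.compose(cumulative)
        D, d = surf.query(P_k)
        r = float(d.mean())
        residuals.append(r)
        objective.append(float((d**2).sum()))
        iterations += 1
        if abs(r - r_prev) <= mu:
            converged = True
            break
        r_prev = r
        step = estimate_svd(P_k, D)
    return ICPResult(
        transform=cumulative,
        residuals=np.asarray(residuals),
        iterations=iterations,
        converged=converged,
        stop_reason="tolerance" if converged else "max_iter",
        objective=np.asarray(objective),
    )


def icp_register(
    P,
    Q,
    init: RigidTransform | None = None,
    mu: float = DEFAULT_MU,
    max_iter: int = DEFAULT_MAX_ITER,
    assignment: str = "unique",
) -> ICPResult:
    """Refine the alignment of target points P onto reference points Q.

    ``init`` is the coarse transform (identity if omitted).  Iterates
    until the mean corresponding-point distance changes by at most ``mu``
    between consecutive iterations, or ``max_iter`` incremental updates
    have been applied.
    """
    P = np.asarray(P, float).reshape(-1, 3)
    Q = np.asarray(Q, float).reshape(-1, 3)
    if len(P) < 3:
        raise EstimationError(f"need at least 3 target points, got {len(P)}")
    if assignment == "unique" and len(Q) < len(P):
        raise ValueError(
            f"unique assignment needs |P| <= |Q|, got {len(P)} > {len(Q)}"
        )
    if assignment not in ("unique", "classic"):
        raise ValueError(f"unknown assignment mode {assignment!r}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if init is None:
        init = RigidTransform.identity()
    assign = nearest_unique if assignment == "unique" else nearest

    P_k = P
    step = init  # (R^k, T^k) applied at the start of each iteration
    cumulative = RigidTransform.identity()
    idx = assign(Q, P_k)
    r_prev = residual(P_k, Q[idx])
    residuals = [r_prev]
    objective = [float(np.sum((P_k - Q[idx]) ** 2))]
    converged = False
    iterations = 0
    if _is_identity(init):
        # an identity first step would reproduce r_0 exactly and trip the
        # stopping rule before anything moved; start from the SVD estimate
        # of the initial correspondences instead
        try:
            step = estimate_svd(P_k, Q[idx])
        except EstimationError:
            pass

    for _ in range(max_iter):
        P_k = step.apply(P_k)
        cumulative = step.compose(cumulative)
        idx = assign(Q, P_k)
        D = Q[idx]
        r = residual(P_k, D)
        residuals.append(r)
        objective.append(float(np.sum((P_k - D) ** 2)))
        iterations += 1
        if abs(r - r_prev) <= mu:
            converged = True
            break
        r_prev = r
        try:
            step = estimate_svd(P_k, D)
        except EstimationError as exc:
            raise EstimationError(
                f"SVD update failed at iteration {iterations}: {exc}"
            ) from exc

    return ICPResult(
        transform=cumulative,
        residuals=np.asarray(residuals),
        iterations=iterations,
        converged=converged,
        stop_reason="tolerance" if converged else "max_iter",
        objective=np.asarray(objective),
    )
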