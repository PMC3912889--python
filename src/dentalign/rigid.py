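"""Rigid transforms: the model q = R p + T, the squared-error objective,
and the least-squares SVD estimator used by both registration stages.

Convention: points are column vectors, transforms act as q = R p + T.
Serialized JSON states this explicitly:
``{"R": [[...3x3...]], "T": [x, y, z], "convention": "q = R p + T"}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EstimationError

ROTATION_TOL = 1e-9  # validation tolerance for internally built transforms


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation (3x3, det +1) plus translation (mm)."""

    R: np.ndarray
    T: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "R", np.asarray(self.R, float).reshape(3, 3))
        object.__setattr__(self, "T", np.asarray(self.T, float).reshape(3))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        """Map points (n,3) or (3,) through q = R p + T."""
        pts = np.asarray(points, float)
        return pts @ self.R.T + self.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(self.R @ other.R, self.R @ other.T + self.T)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.T)

    def rotation_angle_deg(self) -> float:
        """Rotation magnitude in degrees, from the trace."""
        c = np.clip((np.trace(self.R) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    def to_dict(self) -> dict:
        return {
            "R": self.R.tolist(),
            "T": self.T.tolist(),
            "convention": "q = R p + T",
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["R"], float), np.array(d["T"], float))

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def apply(t: RigidTransform, points) -> np.ndarray:
    return t.apply(points)


def squared_error(P, Q, t: RigidTransform) -> float:
    """Sum of squared residuals  e = sum_i || q_i - (R p_i + T) ||^2  (mm^2)."""
    P = np.asarray(P, float).reshape(-1, 3)
    Q = np.asarray(Q, float).reshape(-1, 3)
    if len(P) != len(Q):
        raise ValueError(f"point-set sizes differ: {len(P)} vs {len(Q)}")
    r = Q - t.apply(P)
    return float(np.einsum("ij,ij->", r, r))


def estimate_svd(P, Q) -> RigidTransform:
    """Least-squares rigid transform mapping P onto Q (Arun/Kabsch).

    Both sets are demeaned, the cross-covariance H = sum p'_i q'_i^T is
    decomposed as U S V^T, and R = V D U^T with D = diag(1, 1, det(V U^T))
    so the result is always a proper rotation; T = q_bar - R p_bar.  The
    estimate minimizes the squared-error objective over all proper rigid
    transforms.

    Raises :class:`EstimationError` for fewer than 3 pairs or a collinear
    (rank-deficient) configuration of P.
    """
    P = np.asarray(P, float).reshape(-1, 3)
    Q = np.asarray(Q, float).reshape(-1, 3)
    if len(P) != len(Q):
        raise EstimationError(f"point-set sizes differ: {len(P)} vs {len(Q)}")
    if len(P) < 3:
        raise EstimationError(f"need at least 3 correspondences, got {len(P)}")
    p_bar = P.mean(axis=0)
    q_bar = Q.mean(axis=0)
    Pc = P - p_bar
    Qc = Q - q_bar
    # collinearity of P leaves rotation about the line undetermined
    sv = np.linalg.svd(Pc, compute_uv=False)
    if sv[1] <= 1e-12 * max(sv[0], 1.0):
        raise EstimationError("P is (near-)collinear; rotation is undetermined")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    V = Vt.T
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(V @ U.T))
    R = V @ D @ U.T
    return RigidTransform(R, q_bar - R @ p_bar)


def validate_rotation(M, tol: float = ROTATION_TOL):
    """Check that M is a proper rotation within ``tol``.

    Returns ``(ok, diagnostics)`` where diagnostics holds the max-abs
    orthonormality deviation ||M^T M - I||_max and the determinant.
    """
    M = np.asarray(M, float).reshape(3, 3)
    deviation = float(np.abs(M.T @ M - np.eye(3)).max())
    det = float(np.linalg.det(M))
    ok = deviation <= tol and abs(det - 1.0) <= tol
    return ok, {"orthonormality_deviation": deviation, "determinant": det}
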