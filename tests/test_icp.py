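"""ICP: correspondence assignment, residuals, iteration and stopping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dentalign as dl
from dentalign.icp import (
    MeshSurface,
    icp_register,
    icp_register_surface,
    nearest,
    nearest_unique,
    residual,
)
from dentalign.rigid import RigidTransform


def brute_force_unique(Q, P):
    """Exhaustive oracle for the greedy unique assignment rule: all pairs
    sorted by (distance, reference index), assigned greedily."""
    d = np.linalg.norm(P[:, None] - Q[None, :], axis=-1)
    pairs = sorted(
        ((d[i, j], j, i) for i in range(len(P)) for j in range(len(Q)))
    )
    assignment = {}
    claimed = set()
    for dist, j, i in pairs:
        if i not in assignment and j not in claimed:
            assignment[i] = j
            claimed.add(j)
    return np.array([assignment[i] for i in range(len(P))])


class TestNearestUnique:
    def test_exact_subset(self):
        Q = np.random.default_rng(0).uniform(0, 10, (20, 3))
        P = Q[[3, 7, 11]]
        idx = nearest_unique(Q, P)
        np.testing.assert_array_equal(idx, [3, 7, 11])

    def test_contention_resolved_by_distance(self):
        Q = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        P = np.array([[0.1, 0, 0], [0.2, 0, 0]])  # both closest to Q[0]
        idx = nearest_unique(Q, P)
        assert idx[0] == 0  # closer pair keeps it
        assert idx[1] == 1  # other point takes next unclaimed

    def test_single_pair(self):
        assert nearest_unique(np.zeros((1, 3)), np.ones((1, 3)))[0] == 0

    def test_size_precondition(self):
        with pytest.raises(ValueError):
            nearest_unique(np.zeros((2, 3)), np.zeros((3, 3)))

    @given(st.integers(0, 200))
    def test_matches_exhaustive_oracle_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_p = rng.integers(1, 9)
        n_q = rng.integers(n_p, 9)
        P = rng.uniform(0, 10, (n_p, 3))
        Q = rng.uniform(0, 10, (n_q, 3))
        np.testing.assert_array_equal(
            nearest_unique(Q, P), brute_force_unique(Q, P)
        )

    def test_no_reference_point_claimed_twice(self):
        rng = np.random.default_rng(1)
        Q = rng.uniform(0, 5, (50, 3))
        P = rng.uniform(0, 5, (50, 3))
        idx = nearest_unique(Q, P)
        assert len(set(idx.tolist())) == len(P)


class TestResidual:
    def test_coincident_zero(self):
        P = np.random.default_rng(0).normal(size=(5, 3))
        assert residual(P, P) == 0.0

    def test_mean_of_distances(self):
        P = np.zeros((2, 3))
        D = np.array([[1.0, 0, 0], [3.0, 0, 0]])
        assert residual(P, D) == 2.0

    def test_matches_summation_oracle(self):
        rng = np.random.default_rng(6)
        P, D = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        oracle = sum(np.linalg.norm(p - d) for p, d in zip(P, D)) / 8
        assert np.isclose(residual(P, D), oracle)


class TestIcpRegister:
    def test_identical_sets_converge_immediately(self):
        P = np.random.default_rng(2).uniform(0, 10, (30, 3))
        res = icp_register(P, P, init=RigidTransform.identity())
        assert res.converged
        assert res.residuals[0] == 0.0
        assert res.residuals[-1] < 1e-12
        np.testing.assert_allclose(res.transform.R, np.eye(3), atol=1e-12)
        assert len(res.residuals) == res.iterations + 1

    def test_infinite_mu_stops_after_first_comparison(self):
        rng = np.random.default_rng(3)
        P = rng.uniform(0, 10, (10, 3))
        Q = rng.uniform(0, 10, (20, 3))
        res = icp_register(P, Q, mu=np.inf)
        assert res.iterations == 1
        assert res.converged

    def test_classic_objective_non_increasing(self):
        rng = np.random.default_rng(4)
        Q = rng.uniform(0, 20, (200, 3))
        t = dl.random_rigid_transform(10, 2, seed=5)
        P = t.apply(Q[:150]) + rng.normal(0, 0.05, (150, 3))
        res = icp_register(P, Q, assignment="classic", mu=1e-12, max_iter=40)
        diffs = np.diff(res.objective)
        assert np.all(diffs <= 1e-12)

    def test_unique_mode_terminates_and_reports_history(self):
        rng = np.random.default_rng(5)
        Q = rng.uniform(0, 20, (100, 3))
        P = Q[:60] + rng.normal(0, 0.01, (60, 3))
        res = icp_register(P, Q, assignment="unique", max_iter=50)
        assert res.stop_reason in ("tolerance", "max_iter")
        assert len(res.residuals) == res.iterations + 1

    def test_equivariance_under_rigid_motion_of_reference(self):
        rng = np.random.default_rng(7)
        Q = rng.uniform(0, 20, (150, 3))
        P = Q[:80] + rng.normal(0, 0.02, (80, 3))
        init = dl.random_rigid_transform(5, 1, seed=1)
        res = icp_register(P, Q, init=init, assignment="classic")
        g = dl.random_rigid_transform(60, 30, seed=2)
        res_g = icp_register(
            P, g.apply(Q), init=g.compose(init), assignment="classic"
        )
        np.testing.assert_allclose(
            res_g.transform.R, g.compose(res.transform).R, atol=1e-6
        )
        np.testing.assert_allclose(
            res_g.transform.T, g.compose(res.transform).T, atol=1e-5
        )

    def test_final_residual_not_worse_than_init_across_seeds(self):
        """Refinement must not end worse than it started (20 seeds)."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            Q = rng.uniform(0, 30, (200, 3))
            truth = dl.random_rigid_transform(10, 3, seed=seed)
            P = truth.inverse().apply(Q[:120]) + rng.normal(0, 0.05, (120, 3))
            init = dl.random_rigid_transform(2, 0.5, seed=seed + 1).compose(truth)
            res = icp_register(P, Q, init=init, assignment="classic")
            assert res.residuals[-1] <= res.residuals[0] + 1e-12

    def test_too_few_points(self):
        with pytest.raises(dl.EstimationError):
            icp_register(np.zeros((2, 3)), np.zeros((5, 3)))

    def test_max_iter_reported(self):
        rng = np.random.default_rng(8)
        Q = rng.uniform(0, 20, (100, 3))
        P = Q[:50] + rng.normal(0, 0.5, (50, 3))
        res = icp_register(P, Q, mu=0.0, max_iter=3, assignment="classic")
        if not res.converged:
            assert res.stop_reason == "max_iter"
            assert res.iterations == 3


class TestMeshSurface:
    def test_closest_point_matches_brute_force(self, tetra_mesh):
        from dentalign.icp import _closest_point_triangles

        rng = np.random.default_rng(9)
        pts = rng.uniform(-1, 2, (40, 3))
        surf = MeshSurface(tetra_mesh, k=4)  # all faces as candidates
        _, d = surf.query(pts)
        tri = tetra_mesh.vertices[tetra_mesh.faces]
        cand = np.broadcast_to(tri, (40,) + tri.shape)
        cp = _closest_point_triangles(pts, cand)
        d_brute = np.sqrt(((pts[:, None] - cp) ** 2).sum(-1)).min(axis=1)
        np.testing.assert_allclose(d, d_brute, atol=1e-12)

    def test_on_surface_points_have_zero_distance(self, tetra_mesh):
        # barycentric samples of each face lie exactly on the surface
        tri = tetra_mesh.vertices[tetra_mesh.faces]
        samples = tri.mean(axis=1)
        _, d = MeshSurface(tetra_mesh).query(samples)
        np.testing.assert_allclose(d, 0, atol=1e-12)

    def test_surface_icp_recovers_on_exact_geometry(self):
        ph = dl.make_phantom(n_cusps=3, grid_res=32, seed=4)
        truth = dl.random_rigid_transform(3, 1, seed=4)
        P = truth.inverse().apply(ph.vertices[::3])
        res = icp_register_surface(
            P, ph, init=RigidTransform.identity(), mu=1e-10, max_iter=200
        )
        err = res.transform.compose(truth.inverse())
        assert err.rotation_angle_deg() < 0.2
        assert res.residuals[-1] < 0.02
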