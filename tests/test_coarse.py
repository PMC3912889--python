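"""Three-point coarse registration: constraints, frames, transform."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from itertools import combinations

import dentalign as dl
from dentalign.coarse import (
    candidate_correspondences,
    coarse_transform,
    local_frame,
    match_triple,
    select_reference_points,
    triangle_area,
    triangle_sides,
)
from dentalign.curvature import FeaturePointSet
from dentalign.errors import (
    DegenerateGeometryError,
    NoMatchError,
    SelectionError,
)


def feature_set(points, curvatures):
    """FeaturePointSet over a bare vertex cloud (no faces needed here)."""
    points = np.asarray(points, float)
    mesh = dl.TriangleMesh(points, np.empty((0, 3), dtype=int), welded=True)
    return FeaturePointSet(
        mesh, np.arange(len(points)), np.asarray(curvatures, float), 0.0
    )


class TestTriangleGeometry:
    def test_3_4_5_side_order(self):
        assert triangle_sides([0, 0, 0], [3, 0, 0], [0, 4, 0]) == (3.0, 4.0, 5.0)

    def test_coincident_points(self):
        p = [1.0, 2.0, 3.0]
        assert triangle_sides(p, p, p) == (0.0, 0.0, 0.0)

    @given(st.integers(0, 500))
    def test_sides_match_norm_oracle(self, seed):
        p = np.random.default_rng(seed).normal(size=(3, 3))
        a, b, c = triangle_sides(*p)
        assert np.isclose(a, np.linalg.norm(p[0] - p[1]))
        assert np.isclose(b, np.linalg.norm(p[0] - p[2]))
        assert np.isclose(c, np.linalg.norm(p[1] - p[2]))

    def test_equilateral_area(self):
        assert np.isclose(triangle_area(2, 2, 2), np.sqrt(3))

    def test_right_triangle_area(self):
        assert np.isclose(triangle_area(3, 4, 5), 6.0)

    def test_collinear_zero(self):
        assert triangle_area(1, 2, 3) == 0.0

    def test_inequality_violation(self):
        with pytest.raises(DegenerateGeometryError):
            triangle_area(1, 1, 5)


class TestSelectReferencePoints:
    def test_exactly_three(self):
        fs = feature_set([[0, 0, 0], [5, 0, 0], [0, 5, 1]], [1.0, 2.0, 3.0])
        assert set(select_reference_points(fs)) == {0, 1, 2}

    def test_too_few(self):
        fs = feature_set([[0, 0, 0], [1, 1, 1]], [1.0, 2.0])
        with pytest.raises(SelectionError):
            select_reference_points(fs)

    def test_three_clusters_one_point_each(self):
        """30 equal-curvature points in 3 well-separated clusters: the
        selection must agree with the exhaustive max-min-distance triple."""
        rng = np.random.default_rng(5)
        centers = np.array([[0, 0, 0], [40, 0, 3], [0, 40, 6]], float)
        pts = np.vstack(
            [c + rng.normal(0, 1.0, size=(10, 3)) for c in centers]
        )
        fs = feature_set(pts, np.full(30, 1.0) + rng.normal(0, 1e-6, 30))
        chosen = select_reference_points(fs)
        cluster_of = np.repeat([0, 1, 2], 10)
        assert set(cluster_of[chosen]) == {0, 1, 2}
        # brute-force oracle over all C(30,3) triples
        best, best_d = None, -1
        for i, j, k in combinations(range(30), 3):
            d = min(
                np.linalg.norm(pts[i] - pts[j]),
                np.linalg.norm(pts[i] - pts[k]),
                np.linalg.norm(pts[j] - pts[k]),
            )
            if d > best_d:
                best, best_d = {i, j, k}, d
        assert set(chosen) == best

    def test_collinear_triple_rejected(self):
        fs = feature_set(
            [[0, 0, 0], [1, 0, 0], [2, 0, 0]], [1.0, 1.0, 1.0]
        )
        with pytest.raises(SelectionError):
            select_reference_points(fs)


class TestCandidates:
    def test_exact_copy_is_rank_one(self):
        fs = feature_set(np.zeros((4, 3)), [0.1, 0.2, 0.3, 0.4])
        c = candidate_correspondences(0.3, fs, 0.05)
        assert c[0] == 2

    def test_decoys_beyond_tolerance_excluded(self):
        tol = 0.00015
        fs = feature_set(
            np.zeros((3, 3)), [0.01, 0.01 + 2 * tol, 0.01 - 2 * tol]
        )
        c = candidate_correspondences(0.01, fs, tol)
        # brute-force filter oracle
        assert list(c) == [0]

    def test_sorted_by_deviation(self):
        fs = feature_set(np.zeros((4, 3)), [0.10, 0.11, 0.09, 0.101])
        c = candidate_correspondences(0.1, fs, 0.05)
        devs = np.abs(fs.curvatures[c] - 0.1)
        assert np.all(np.diff(devs) >= 0)


class TestMatchTriple:
    def setup_method(self):
        rng = np.random.default_rng(42)
        self.pts = rng.uniform(0, 30, size=(40, 3))
        self.curv = rng.uniform(0.02, 0.2, size=40)
        self.ref_idx = [3, 17, 31]

    def test_recovers_transformed_copy(self):
        t = dl.random_rigid_transform(40, 15, seed=9)
        target = feature_set(t.apply(self.pts), self.curv)
        triple = match_triple(
            self.pts[self.ref_idx],
            self.curv[self.ref_idx],
            target,
            curv_tol=1e-6,
            dist_tol=0.5,
            area_tol=1.0,
        )
        np.testing.assert_array_equal(triple.target_indices, self.ref_idx)
        assert triple.side_deviations.max() < 1e-9
        assert triple.area_deviation < 1e-9

    def test_positional_decoy_rejected_by_distance_constraint(self):
        dist_tol = 0.5
        t = dl.random_rigid_transform(20, 5, seed=2)
        moved = t.apply(self.pts)
        # decoy: same curvature as ref point 0 but displaced by 3*dist_tol
        decoy_pos = moved[self.ref_idx[0]] + np.array([3 * dist_tol, 0, 0])
        pts = np.vstack([moved, decoy_pos])
        curv = np.append(self.curv, self.curv[self.ref_idx[0]])
        target = feature_set(pts, curv)
        triple = match_triple(
            self.pts[self.ref_idx],
            self.curv[self.ref_idx],
            target,
            curv_tol=1e-6,
            dist_tol=dist_tol,
            area_tol=1.0,
        )
        assert triple.target_indices[0] == self.ref_idx[0]  # decoy (index 40) lost

    def test_no_candidates_raises(self):
        target = feature_set(self.pts, self.curv + 10.0)
        with pytest.raises(NoMatchError):
            match_triple(
                self.pts[self.ref_idx],
                self.curv[self.ref_idx],
                target,
                curv_tol=1e-6,
            )

    def test_no_satisfying_triple_reports_best_residuals(self):
        # candidates exist by curvature but geometry is scaled 2x: all
        # side deviations exceed the tolerance
        target = feature_set(self.pts * 2.0, self.curv)
        with pytest.raises(NoMatchError) as exc:
            match_triple(
                self.pts[self.ref_idx],
                self.curv[self.ref_idx],
                target,
                curv_tol=1e-6,
                dist_tol=0.5,
                area_tol=1.0,
            )
        assert exc.value.best_residuals is not None

    def test_constraints_invariant_under_rigid_motion(self):
        """Side lengths and area of the matched triple are preserved under
        an arbitrary rigid motion of the target model."""
        for seed in range(10):
            t = dl.random_rigid_transform(170, 80, seed=seed)
            target = feature_set(t.apply(self.pts), self.curv)
            triple = match_triple(
                self.pts[self.ref_idx],
                self.curv[self.ref_idx],
                target,
                curv_tol=1e-6,
                dist_tol=0.5,
                area_tol=1.0,
            )
            assert triple.side_deviations.max() < 1e-9


class TestLocalFrame:
    def test_axis_aligned_example(self):
        F = local_frame([0, 0, 0], [0, 1, 0], [1, 0, 0])
        np.testing.assert_allclose(F[:, 0], [1, 0, 0], atol=1e-15)
        np.testing.assert_allclose(F[:, 1], [0, 0, 1], atol=1e-15)
        np.testing.assert_allclose(F[:, 2], [0, -1, 0], atol=1e-15)

    @given(st.integers(0, 500))
    def test_orthonormal_on_random_triples(self, seed):
        p = np.random.default_rng(seed).normal(size=(3, 3)) * 10
        if np.linalg.norm(np.cross(p[2] - p[0], p[1] - p[0])) < 1e-6:
            return
        F = local_frame(*p)
        np.testing.assert_allclose(F.T @ F, np.eye(3), atol=1e-9)

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            local_frame([0, 0, 0], [1, 0, 0], [2, 0, 0])


class TestCoarseTransform:
    TRIPLE = np.array([[0.0, 0, 0], [10, 0, 0], [3, 8, 1]])

    def test_identity(self):
        t = coarse_transform(self.TRIPLE, self.TRIPLE)
        np.testing.assert_allclose(t.R, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.T, 0, atol=1e-12)

    def test_pure_translation(self):
        t = coarse_transform(self.TRIPLE, self.TRIPLE + [1, 2, 3])
        np.testing.assert_allclose(t.R, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.T, [1, 2, 3], atol=1e-12)

    def test_rz90(self):
        Rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        t = coarse_transform(self.TRIPLE, self.TRIPLE @ Rz.T)
        np.testing.assert_allclose(t.R, Rz, atol=1e-12)

    def test_exact_rigid_pair_maps_triple(self):
        truth = dl.random_rigid_transform(120, 30, seed=8)
        t = coarse_transform(self.TRIPLE, truth.apply(self.TRIPLE))
        np.testing.assert_allclose(
            t.apply(self.TRIPLE), truth.apply(self.TRIPLE), atol=1e-9
        )

    def test_agrees_with_svd_estimator_on_exact_pairs(self):
        for seed in range(10):
            truth = dl.random_rigid_transform(100, 20, seed=seed)
            n = truth.apply(self.TRIPLE)
            t_frame = coarse_transform(self.TRIPLE, n)
            t_svd = dl.estimate_svd(self.TRIPLE, n)
            assert np.abs(t_frame.R - t_svd.R).max() < 1e-9
            assert np.linalg.norm(t_frame.T - t_svd.T) < 1e-9
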