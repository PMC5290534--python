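import numpy as np
import pytest

from mtbm.errors import DomainError, ValidationError
from mtbm.grid import SurfaceGrid, cell_areas
from mtbm.morphometry import (
    JacobianField,
    assemble_features,
    cells_to_vertices,
    compute_jacobians,
    compute_mad,
    detj_vertex_field,
    log_deformation_tensor,
    log_tensor_cells,
    log_tensor_vertex_field,
    subject_features,
)
from mtbm.shapes import cylinder_grid, sphere_grid

from conftest import rotation_matrix


class TestMAD:
    def test_cylinder_mad_equals_radius(self, cylinder):
        assert np.abs(compute_mad(cylinder) - 5.0).max() < 1e-12

    def test_sphere_mad_is_r_sin_theta(self):
        r, R = 10.0, 40
        margin = 0.5 * np.pi / R
        s = sphere_grid(r, n_rings=R, n_around=80, pole_margin=margin)
        theta = np.linspace(margin, np.pi - margin, R)[::-1]
        expected = r * np.sin(theta)
        assert np.abs(compute_mad(s) - expected[:, None]).max() < 1e-12

    def test_rigid_translation_invariance(self, small_ellipsoid):
        moved = SurfaceGrid(small_ellipsoid.vertices + np.array([4.0, 5.0, -6.0]))
        assert np.abs(compute_mad(moved) - compute_mad(small_ellipsoid)).max() < 1e-12

    def test_mad_strictly_positive(self, small_ellipsoid):
        assert (compute_mad(small_ellipsoid) > 0).all()


class TestJacobians:
    def test_identity_deformation(self, cylinder):
        jac = compute_jacobians(cylinder, cylinder)
        assert np.abs(jac.J - np.eye(2)).max() < 1e-10
        assert np.abs(jac.det - 1.0).max() < 1e-10
        assert jac.valid.all()

    def test_uniform_scale(self, cylinder):
        subject = SurfaceGrid(1.1 * cylinder.vertices)
        jac = compute_jacobians(cylinder, subject)
        assert np.abs(jac.J - 1.1 * np.eye(2)).max() < 1e-8
        assert np.abs(jac.det - 1.21).max() < 1e-8

    def test_axis_stretch_matches_area_ratio_oracle(self, cylinder):
        subject = SurfaceGrid(cylinder.vertices * np.array([1.4, 1.0, 1.0]))
        jac = compute_jacobians(cylinder, subject)
        ratio = cell_areas(subject) / cell_areas(cylinder)
        assert np.abs(jac.det - ratio).max() < 1e-6

    def test_rigid_motion_of_both_gives_identity(self, small_ellipsoid):
        R = rotation_matrix()
        t = np.array([1.0, 2.0, 3.0])
        a = SurfaceGrid(small_ellipsoid.vertices @ R.T + t)
        jac = compute_jacobians(small_ellipsoid, a)
        assert np.abs(jac.det - 1.0).max() < 1e-8
        assert np.abs(log_tensor_cells(jac)).max() < 1e-8

    def test_mismatched_grids_rejected(self, cylinder, sphere):
        with pytest.raises(ValidationError):
            compute_jacobians(cylinder, sphere)

    def test_folded_cells_masked_with_warning(self, cylinder):
        bad = cylinder.copy()
        # swap two adjacent rings locally: creates inverted cells
        bad.vertices[10:12] = bad.vertices[[11, 10]]
        with pytest.warns(UserWarning, match="folded"):
            jac = compute_jacobians(cylinder, bad)
        assert not jac.valid.all()
        assert jac.valid.sum() > 0


class TestLogTensor:
    def test_identity_maps_to_zero(self):
        assert np.abs(log_deformation_tensor(np.eye(2))).max() < 1e-12

    def test_rotation_maps_to_zero(self):
        for ang in (0.3, 1.2, -2.0):
            Rm = np.array(
                [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
            )
            assert np.abs(log_deformation_tensor(Rm)).max() < 1e-12

    def test_diagonal_stretch_analytic(self):
        got = log_deformation_tensor(np.diag([2.0, 0.5]))
        assert np.allclose(got, [np.log(2), 0.0, -np.log(2)], atol=1e-12)

    def test_unit_shear_matches_scalar_eigen_oracle(self):
        J = np.array([[1.0, 1.0], [0.0, 1.0]])
        got = log_deformation_tensor(J)
        # oracle: JtJ = [[1,1],[1,2]] has eigenvalues (3 +/- sqrt 5)/2 with
        # known eigenvectors; build log S entirely from scalars
        lam1 = (3 + np.sqrt(5)) / 2
        lam2 = (3 - np.sqrt(5)) / 2
        v1 = np.array([1.0, lam1 - 1.0])
        v1 /= np.linalg.norm(v1)
        v2 = np.array([-v1[1], v1[0]])
        L = 0.5 * (
            np.log(lam1) * np.outer(v1, v1) + np.log(lam2) * np.outer(v2, v2)
        )
        assert np.allclose(got, [L[0, 0], L[0, 1], L[1, 1]], atol=1e-12)

    def test_coaxial_stretches_add(self):
        J1 = np.diag([1.7, 0.6])
        J2 = np.diag([0.9, 1.3])
        lhs = log_deformation_tensor(J1 @ J2)
        rhs = log_deformation_tensor(J1) + log_deformation_tensor(J2)
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_nonpositive_det_rejected(self):
        with pytest.raises(DomainError):
            log_deformation_tensor(np.diag([1.0, -1.0]))

    def test_near_singular_rejected(self):
        with pytest.raises(DomainError):
            log_deformation_tensor(np.diag([1.0, 1e-9]))

    def test_frame_robustness_left_rotation_invariance(self, rng):
        # S depends on J only through JtJ: left rotations cannot change it
        J = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        ang = 0.8
        Rm = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        assert np.allclose(
            log_deformation_tensor(Rm @ J), log_deformation_tensor(J), atol=1e-12
        )

    def test_detj_equals_exp_trace_logs(self, cylinder, rng):
        subject = SurfaceGrid(
            cylinder.vertices * np.array([1.3, 1.05, 0.95])
        )
        jac = compute_jacobians(cylinder, subject)
        ls = log_tensor_cells(jac)
        assert np.abs(np.exp(ls[..., 0] + ls[..., 2]) - jac.det).max() < 1e-10


class TestVertexTransfer:
    def test_identity_gives_unit_detj_everywhere(self, cylinder):
        jac = compute_jacobians(cylinder, cylinder)
        assert np.abs(detj_vertex_field(jac) - 1.0).max() < 1e-10

    def test_uniform_scale_everywhere(self, cylinder):
        jac = compute_jacobians(cylinder, SurfaceGrid(1.1 * cylinder.vertices))
        assert np.abs(detj_vertex_field(jac) - 1.21).max() < 1e-8

    def test_checkerboard_matches_direct_weighted_mean(self, rng):
        R, M = 6, 8
        vals = np.where((np.add.outer(np.arange(R - 1), np.arange(M)) % 2) == 0, 2.0, 0.5)
        areas = rng.uniform(0.5, 2.0, size=(R - 1, M))
        jac = JacobianField(
            J=np.broadcast_to(np.eye(2), (R - 1, M, 2, 2)).copy(),
            valid=np.ones((R - 1, M), dtype=bool),
            template_areas=areas,
        )
        got = cells_to_vertices(vals, jac)
        for i in range(R):
            for j in range(M):
                num = den = 0.0
                for ci in (i - 1, i):
                    if not (0 <= ci <= R - 2):
                        continue
                    for cj in ((j - 1) % M, j):
                        num += vals[ci, cj] * areas[ci, cj]
                        den += areas[ci, cj]
                assert got[i, j] == pytest.approx(num / den, rel=1e-12)

    def test_vertex_with_no_valid_cell_flagged_nan(self, cylinder):
        jac = compute_jacobians(cylinder, cylinder)
        jac.valid[:2, :] = False  # kill all cells touching ring 0 and 1
        out = detj_vertex_field(jac)
        assert np.isnan(out[0]).all() and np.isnan(out[1]).all()
        assert np.isfinite(out[3:]).all()


class TestFeatures:
    def test_identity_on_cylinder(self, cylinder):
        f = subject_features(cylinder, cylinder)
        assert f.shape == (30, 40, 4)
        assert np.abs(f[..., 0] - 5.0).max() < 1e-12
        assert np.abs(f[..., 1:]).max() < 1e-10

    def test_uniform_scale_composition(self, cylinder):
        s = 1.1
        f = subject_features(cylinder, SurfaceGrid(s * cylinder.vertices))
        assert np.abs(f[..., 0] - s * 5.0).max() < 1e-6
        assert np.abs(f[..., 1] - np.log(s)).max() < 1e-6
        assert np.abs(f[..., 2]).max() < 1e-6
        assert np.abs(f[..., 3] - np.log(s)).max() < 1e-6

    def test_channel_count_and_shape_validation(self, cylinder):
        mad = compute_mad(cylinder)
        with pytest.raises(ValidationError):
            assemble_features(mad, np.zeros((5, 5, 3)))
        jac = compute_jacobians(cylinder, cylinder)
        f = assemble_features(mad, log_tensor_vertex_field(jac))
        assert f.shape[-1] == 4
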