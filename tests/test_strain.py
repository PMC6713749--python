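import numpy as np
import pytest

from myotrack.core import SurfaceMesh
from myotrack.lwm import fit_lwm
from myotrack.strain import (
    StrainField,
    deformation_gradient,
    displacement_gradient,
    eigen_analysis,
    lagrange_strain,
    local_directions,
    project_strain,
    strain_curves,
    track_mesh,
)


def _fit_map(fn, rng, n=60, box=24.0, direction="moving_to_reference"):
    src = rng.uniform(0, box, (400, 3))
    return fit_lwm(src, fn(src), n=n, direction=direction)


def _cylinder_mesh(radius=5.0, height=10.0, n_az=16, n_z=5):
    nodes, tris = [], []
    for k in range(n_z):
        z = height * k / (n_z - 1)
        for j in range(n_az):
            phi = 2 * np.pi * j / n_az
            nodes.append([radius * np.cos(phi), radius * np.sin(phi), z])
    for k in range(n_z - 1):
        for j in range(n_az):
            a = k * n_az + j
            b = k * n_az + (j + 1) % n_az
            c = (k + 1) * n_az + j
            d = (k + 1) * n_az + (j + 1) % n_az
            tris += [[a, c, d], [a, d, b]]
    return SurfaceMesh(np.array(nodes), np.array(tris),
                       apex=np.array([0.0, 0.0, -1.0]),
                       mitral_center=np.array([0.0, 0.0, 11.0]))


class TestGradients:
    def test_identity_zero_displacement_gradient(self, rng):
        tr = _fit_map(lambda p: p, rng)
        U = displacement_gradient(tr, np.array([12.0, 12.0, 12.0]))
        assert np.allclose(U, 0.0, atol=1e-9)

    def test_uniform_stretch(self, rng):
        # forward x = 2X, inverse X = x/2 -> U = diag(0.5)
        tr = _fit_map(lambda p: p / 2.0, rng)
        U = displacement_gradient(tr, np.array([10.0, 11.0, 12.0]))
        assert np.allclose(U, 0.5 * np.eye(3), atol=1e-8)

    def test_rigid_rotation_gives_U_I_minus_RT(self, rng):
        ang = np.deg2rad(11.0)
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        tr = _fit_map(lambda p: p @ R, rng)  # inverse map: X = R^T x -> p @ R
        U = displacement_gradient(tr, np.array([12.0, 12.0, 12.0]))
        assert np.allclose(U, np.eye(3) - R.T, atol=1e-8)

    def test_wrong_direction_raises(self, rng):
        tr = _fit_map(lambda p: p, rng, direction="reference_to_moving")
        with pytest.raises(ValueError):
            displacement_gradient(tr, np.zeros(3))

    def test_anisotropic_spacing_similarity_transform(self, rng):
        tr = _fit_map(lambda p: p / 2.0, rng)
        x = np.array([10.0, 10.0, 10.0])
        U_vox = displacement_gradient(tr, x)
        U_mm = displacement_gradient(tr, x, voxel_spacing=(1.0, 2.0, 0.5))
        S = np.diag([1.0, 2.0, 0.5])
        assert np.allclose(U_mm, S @ U_vox @ np.linalg.inv(S), atol=1e-8)


class TestDeformationAndStrain:
    def test_zero_U_gives_identity_F(self):
        assert np.allclose(deformation_gradient(np.zeros((3, 3))), np.eye(3))

    def test_scalar_inverse(self):
        F = deformation_gradient(np.diag([0.5, 0.0, 0.0]))
        assert np.allclose(F, np.diag([2.0, 1.0, 1.0]))

    def test_rotation_produces_no_strain(self):
        ang = 0.3
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        U = np.eye(3) - R.T
        F = deformation_gradient(U)
        assert np.allclose(F, R, atol=1e-12)
        assert np.allclose(lagrange_strain(F), 0.0, atol=1e-12)

    def test_singular_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            deformation_gradient(np.eye(3))  # I - U = 0

    def test_uniaxial_stretch_closed_form(self):
        E = lagrange_strain(np.diag([1.2, 1.0, 1.0]))
        assert E[0, 0] == pytest.approx(0.22, abs=1e-12)
        assert np.allclose(E - np.diag(np.diag(E)), 0.0)

    def test_shortening_closed_form(self):
        E = lagrange_strain(np.diag([1.0, 1.0, 0.9]))
        assert E[2, 2] == pytest.approx(-0.095, abs=1e-12)

    def test_simple_shear_closed_form(self):
        F = np.eye(3)
        F[0, 1] = 0.1
        E = lagrange_strain(F)
        assert E[0, 1] == pytest.approx(0.05, abs=1e-12)
        assert E[1, 1] == pytest.approx(0.005, abs=1e-12)
        assert E[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng):
        F = np.eye(3) + 0.1 * rng.standard_normal((50, 3, 3))
        E = lagrange_strain(F)
        assert np.abs(E - np.swapaxes(E, -1, -2)).max() < 1e-10


class TestObjectivityAndConsistency:
    def test_rigid_motion_zero_strain_from_exact_correspondences(self, rng):
        ang = np.deg2rad(7.0)
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        t = np.array([1.5, -2.0, 1.0])
        X = rng.uniform(0, 24, (500, 3))
        x = X @ R.T + t
        inv_tr = fit_lwm(x, X, n=80, direction="moving_to_reference")
        U = displacement_gradient(inv_tr, x[:100])
        E = lagrange_strain(deformation_gradient(U))
        assert np.abs(E).max() < 1e-8

    def test_F_matches_forward_jacobian_on_affine(self, rng):
        A = np.array([[1.15, 0.05, 0.0], [0.0, 0.92, 0.04], [0.03, 0.0, 1.08]])
        X = rng.uniform(0, 24, (500, 3))
        x = X @ A.T
        inv_tr = fit_lwm(x, X, n=80, direction="moving_to_reference")
        U = displacement_gradient(inv_tr, x[:50])
        F = deformation_gradient(U)
        assert np.abs(F - A).max() < 1e-6


class TestLocalDirections:
    def test_cylinder_directions(self):
        mesh = _cylinder_mesh()
        dirs = local_directions(mesh)
        assert np.allclose(dirs.L, [0, 0, 1])
        # radial = outward normal with axial part removed; the discrete
        # vertex normal carries a small azimuthal tilt from the triangle fan
        i = 2 * 16  # interior-ring node at angle 0 -> normal ~ +x
        assert dirs.R_dir[i] @ np.array([1, 0, 0]) > 0.99
        assert dirs.C[i] @ np.cross([0, 0, 1], [1.0, 0, 0]) > 0.99
        assert dirs.defined.all()
        # all directions unit and R perpendicular to L
        assert np.allclose(np.linalg.norm(dirs.R_dir, axis=1), 1.0)
        assert np.abs(dirs.R_dir @ dirs.L).max() < 1e-9

    def test_normal_parallel_to_L_flagged_undefined(self):
        mesh = _cylinder_mesh()
        mesh.normals[3] = np.array([0.0, 0.0, 1.0])  # force a degenerate normal
        dirs = local_directions(mesh)
        assert not dirs.defined[3]
        assert dirs.defined.sum() == mesh.n_nodes - 1


class TestProjection:
    def test_isotropic(self):
        E = 0.1 * np.eye(3)
        assert project_strain(E, np.array([0.0, 1.0, 0.0])) == pytest.approx(0.1)

    def test_diagonal_axis(self):
        E = np.diag([0.3, -0.1, 0.05])
        assert project_strain(E, np.array([1.0, 0.0, 0.0])) == pytest.approx(0.3)

    def test_double_sum_oracle(self, rng):
        E = rng.standard_normal((3, 3))
        E = 0.5 * (E + E.T)
        p = rng.standard_normal(3)
        p /= np.linalg.norm(p)
        expected = sum(p[i] * E[i, j] * p[j] for i in range(3) for j in range(3))
        assert project_strain(E, p) == pytest.approx(expected, abs=1e-12)

    def test_non_unit_direction_raises(self):
        with pytest.raises(ValueError):
            project_strain(np.eye(3), np.array([1.0, 1.0, 0.0]))


class TestTrackingAndCurves:
    def test_identity_transforms_keep_positions(self, rng):
        mesh = _cylinder_mesh()
        tracked = track_mesh(mesh, [None, None, None], (1.0, 1.0, 1.0))
        assert np.allclose(tracked.positions, mesh.nodes[None])
        assert np.allclose(tracked.displacements(2), 0.0)

    def test_translation_transform_shifts_all_nodes(self, rng):
        mesh = _cylinder_mesh()
        d = np.array([1.0, 2.0, -1.0])
        src = rng.uniform(-8, 14, (200, 3))
        fwd = fit_lwm(src, src + d, n=40, direction="reference_to_moving")
        tracked = track_mesh(mesh, [None, fwd], (1.0, 1.0, 1.0))
        assert np.allclose(tracked.positions[1], mesh.nodes + d, atol=1e-6)

    def test_wrong_direction_raises(self, rng):
        mesh = _cylinder_mesh()
        src = rng.uniform(-8, 14, (100, 3))
        bad = fit_lwm(src, src, n=30, direction="moving_to_reference")
        with pytest.raises(ValueError):
            track_mesh(mesh, [None, bad], (1.0, 1.0, 1.0))

    def test_all_zero_fields_give_zero_curves(self):
        mesh = _cylinder_mesh()
        dirs = local_directions(mesh)
        n = mesh.n_nodes
        fields = [
            StrainField(frame=t, U=np.zeros((n, 3, 3)),
                        F=np.broadcast_to(np.eye(3), (n, 3, 3)).copy(),
                        E=np.zeros((n, 3, 3)))
            for t in range(3)
        ]
        curves = strain_curves(fields, dirs)
        assert np.allclose(curves.E_L, 0.0) and np.allclose(curves.E_C, 0.0)
        assert np.allclose(curves.eigenvalues, 0.0)

    def test_uniform_diagonal_fields_recovered_in_cylinder_frame(self):
        mesh = _cylinder_mesh()
        dirs = local_directions(mesh)
        n = mesh.n_nodes
        E = np.broadcast_to(np.diag([-0.1, -0.1, 0.2]), (n, 3, 3)).copy()
        fields = [StrainField(frame=0, U=np.zeros((n, 3, 3)),
                              F=np.broadcast_to(np.eye(3), (n, 3, 3)).copy(), E=E)]
        curves = strain_curves(fields, dirs)
        # L = z: E_L = 0.2; radial/circumferential live in the xy-plane: -0.1
        assert curves.E_L[0] == pytest.approx(0.2, abs=1e-9)
        assert curves.E_C[0] == pytest.approx(-0.1, abs=1e-9)
        assert curves.E_R[0] == pytest.approx(-0.1, abs=1e-9)


class TestEigenAnalysis:
    def test_diagonal_tensor(self):
        E = np.array([np.diag([-0.1, -0.05, 0.02])])
        vals, med = eigen_analysis(StrainField(0, np.zeros((1, 3, 3)), np.eye(3)[None], E))
        assert np.allclose(vals[0], [-0.1, -0.05, 0.02])
        assert np.allclose(med, [-0.1, -0.05, 0.02])

    def test_median_per_sorted_position(self):
        tensors = np.array([np.diag(d) for d in
                            [[-0.2, 0.0, 0.1], [-0.1, 0.05, 0.2], [-0.3, -0.1, 0.3]]])
        _, med = eigen_analysis(StrainField(0, np.zeros((3, 3, 3)), np.eye(3)[None], tensors))
        assert np.allclose(med, [-0.2, 0.0, 0.2])

    def test_rayleigh_bound_contains_projections(self, rng):
        E = rng.standard_normal((20, 3, 3)) * 0.1
        E = 0.5 * (E + np.swapaxes(E, -1, -2))
        vals, _ = eigen_analysis(StrainField(0, np.zeros((20, 3, 3)), np.eye(3)[None], E))
        p = rng.standard_normal(3)
        p /= np.linalg.norm(p)
        proj = project_strain(E, np.broadcast_to(p, (20, 3)))
        assert np.all(proj >= vals[:, 0] - 1e-9)
        assert np.all(proj <= vals[:, 2] + 1e-9)

    def test_asymmetric_raises(self):
        E = np.zeros((1, 3, 3))
        E[0, 0, 1] = 0.5
        with pytest.raises(ValueError):
            eigen_analysis(StrainField(0, np.zeros((1, 3, 3)), np.eye(3)[None], E))
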