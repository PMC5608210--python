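import numpy as np
import pytest

from lungmorph import BinaryVolume
from lungmorph.curvature import (
    CurvatureField,
    SurfaceMesh,
    classify_regions,
    curvature_densities,
    ensemble_isd,
    extract_surface,
    isd_density,
    map_to_slices,
    normal_cycle_curvature,
    principal_from_HK,
    smooth_mesh,
)

from conftest import make_ball_mask


@pytest.fixture(scope="module")
def cylinder_field():
    n = 60
    z, y, x = np.mgrid[:50, :n, :n]
    cyl = (y - 30) ** 2 + (x - 30) ** 2 <= 20 * 20  # air cylinder r=20 µm along z
    mesh = smooth_mesh(extract_surface(BinaryVolume(~cyl, 1.0)), 20, 0.5)
    return normal_cycle_curvature(mesh, 5.0)


def flat_patch(n: int = 30) -> SurfaceMesh:
    gy, gx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    verts = np.column_stack([np.zeros(n * n), gy.ravel(), gx.ravel()]).astype(float)
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces += [[a, a + 1, a + n], [a + 1, a + n + 1, a + n]]
    normals = np.tile([1.0, 0.0, 0.0], (n * n, 1))
    return SurfaceMesh(verts, np.array(faces), normals, 1.0)


class TestExtractSurface:
    def test_air_ball_mesh_is_a_closed_genus_zero_surface(self):
        mesh = extract_surface(make_ball_mask(20, 1.0, 3))
        v = mesh.n_vertices
        f = len(mesh.triangles)
        e = len(mesh.to_trimesh().edges_unique)
        assert v - e + f == 2

    def test_smoothed_ball_mesh_area_close_to_analytic_sphere(self):
        # raw marching cubes on binary data carries the usual staircase
        # area excess (~8%); the pipeline's smoothing removes it
        mesh = smooth_mesh(extract_surface(make_ball_mask(20, 1.0, 3)), 20, 0.5)
        area = mesh.to_trimesh().area
        assert area == pytest.approx(4 * np.pi * 20**2, rel=0.05)

    def test_normals_point_from_air_into_tissue(self):
        mesh = extract_surface(make_ball_mask(20, 1.0, 3))
        center = np.full(3, mesh.vertices.mean())
        radial = mesh.vertices - mesh.vertices.mean(axis=0)
        radial /= np.linalg.norm(radial, axis=1)[:, None]
        assert ((radial * mesh.vertex_normals).sum(axis=1) > 0).all()

    def test_single_phase_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_surface(BinaryVolume(np.ones((4, 4, 4), dtype=bool), 1.0))


class TestSmoothMesh:
    def test_zero_iterations_is_identity(self):
        mesh = extract_surface(make_ball_mask(10, 1.0))
        out = smooth_mesh(mesh, 0, 0.5)
        np.testing.assert_array_equal(out.vertices, mesh.vertices)

    def test_smoothing_reduces_radial_roughness_of_voxel_ball(self):
        mesh = extract_surface(make_ball_mask(15, 1.0))
        smoothed = smooth_mesh(mesh, 20, 0.5)

        def rms_radial(m):
            r = np.linalg.norm(m.vertices - m.vertices.mean(axis=0), axis=1)
            return np.std(r)

        assert rms_radial(smoothed) < rms_radial(mesh)

    def test_volume_shrinkage_below_5_percent_at_defaults(self):
        mesh = extract_surface(make_ball_mask(20, 1.0, 3))
        smoothed = smooth_mesh(mesh, 20, 0.5)
        v0 = abs(mesh.to_trimesh().volume)
        v1 = abs(smoothed.to_trimesh().volume)
        assert (v0 - v1) / v0 < 0.05

    def test_smoothing_tames_the_gaussian_curvature_tail(self):
        mesh = extract_surface(make_ball_mask(15, 1.0))
        rough = normal_cycle_curvature(mesh, 5.0)
        smooth = normal_cycle_curvature(smooth_mesh(mesh, 20, 0.5), 5.0)
        p95 = lambda f: np.percentile(np.abs(f.K[f.included]), 95)
        assert p95(smooth) <= p95(rough)

    def test_invalid_step_rejected(self):
        mesh = extract_surface(make_ball_mask(8, 1.0))
        with pytest.raises(ValueError):
            smooth_mesh(mesh, 5, 1.5)


class TestNormalCycleEstimator:
    def test_flat_patch_has_zero_curvature_inside(self):
        field = normal_cycle_curvature(flat_patch(), 4.0)
        inc = field.included
        assert inc.sum() > 100
        assert np.abs(field.kappa1[inc]).max() < 1e-6
        assert np.abs(field.kappa2[inc]).max() < 1e-6

    def test_air_sphere_curvatures_match_one_over_radius(self, sphere_field):
        inc = sphere_field.included
        assert np.median(sphere_field.kappa1[inc]) == pytest.approx(0.04, rel=0.10)
        assert np.median(sphere_field.kappa2[inc]) == pytest.approx(0.04, rel=0.10)
        assert np.median(sphere_field.K[inc]) == pytest.approx(1.6e-3, rel=0.15)

    def test_cylinder_distinguishes_flat_and_bent_directions(self, cylinder_field):
        inc = cylinder_field.included
        assert np.median(np.abs(cylinder_field.kappa1[inc])) < 0.005
        assert np.median(cylinder_field.kappa2[inc]) == pytest.approx(0.05, rel=0.10)

    def test_open_cylinder_ends_are_boundary_excluded(self, cylinder_field):
        assert cylinder_field.excluded.sum() > 0

    def test_tissue_sphere_lands_in_region_4(self):
        n = 40
        z, y, x = np.mgrid[:n, :n, :n]
        ball = (z - 20) ** 2 + (y - 20) ** 2 + (x - 20) ** 2 <= 15 * 15
        mask = BinaryVolume(ball, 1.0)  # tissue ball floating in air
        field = normal_cycle_curvature(smooth_mesh(extract_surface(mask), 20, 0.5), 5.0)
        labels = classify_regions(field)
        inc = field.included
        assert (labels[inc] == 4).mean() > 0.95

    def test_scale_equivariance_of_kappa(self, sphere_mesh):
        field1 = normal_cycle_curvature(sphere_mesh, 5.0)
        doubled = SurfaceMesh(sphere_mesh.vertices * 2, sphere_mesh.triangles, sphere_mesh.vertex_normals, sphere_mesh.spacing * 2)
        field2 = normal_cycle_curvature(doubled, 10.0)
        inc = field1.included & field2.included
        np.testing.assert_allclose(field2.kappa2[inc], field1.kappa2[inc] / 2, atol=1e-6)

    def test_eq3_and_tensor_self_consistency(self, sphere_field, cylinder_field):
        for field in (sphere_field, cylinder_field):
            assert (field.kappa1 <= field.kappa2 + 1e-12).all()
            np.testing.assert_allclose(field.H, (field.kappa1 + field.kappa2) / 2, rtol=1e-9, atol=1e-15)
            np.testing.assert_allclose(field.K, field.kappa1 * field.kappa2, rtol=1e-9, atol=1e-15)
            k1, k2 = principal_from_HK(field.H, field.K)
            np.testing.assert_allclose(k1, field.kappa1, rtol=1e-6, atol=1e-9)
            np.testing.assert_allclose(k2, field.kappa2, rtol=1e-6, atol=1e-9)

    def test_invalid_radius_rejected(self, sphere_mesh):
        with pytest.raises(ValueError):
            normal_cycle_curvature(sphere_mesh, 0.0)


class TestPrincipalFromHK:
    @pytest.mark.parametrize(
        "H,K,expected",
        [
            (1.0, 1.0, (1.0, 1.0)),  # umbilic
            (0.0, -1.0, (-1.0, 1.0)),  # symmetric saddle
            (2.0, 3.0, (1.0, 3.0)),
        ],
    )
    def test_closed_form_pairs(self, H, K, expected):
        k1, k2 = principal_from_HK(H, K)
        assert (k1, k2) == pytest.approx(expected)

    def test_negative_discriminant_clamped_to_umbilic(self):
        k1, k2 = principal_from_HK(1.0, 1.0 + 1e-12)
        assert k1 == pytest.approx(k2)


class TestRegions:
    def make_field(self, k1, k2):
        k1 = np.atleast_1d(np.asarray(k1, dtype=float))
        k2 = np.atleast_1d(np.asarray(k2, dtype=float))
        return CurvatureField(k1, k2, (k1 + k2) / 2, k1 * k2, 1.0, np.zeros(k1.shape, bool))

    def test_quadrant_labels(self):
        field = self.make_field([0.02, -0.02, -0.01], [0.02, -0.02, 0.03])
        labels = classify_regions(field)
        assert labels.tolist() == [1, 4, 3]

    def test_saddle_split_and_tie_rule(self):
        field = self.make_field([-0.03, -0.01, -0.02], [0.01, 0.03, 0.02])
        assert classify_regions(field).tolist() == [2, 3, 2]

    def test_boundary_excluded_gets_label_zero(self):
        field = self.make_field([0.02], [0.02])
        field.excluded[:] = True
        assert classify_regions(field).tolist() == [0]


class TestDensities:
    def test_sphere_isd_mass_concentrates_in_region_1(self, sphere_field):
        isd = isd_density(sphere_field)
        pos = (isd.grid_k1 > 0)[:, None] & (isd.grid_k2 > 0)[None, :]
        mass_r1 = np.trapezoid(np.trapezoid(np.where(pos, isd.density, 0.0), isd.grid_k2, axis=1), isd.grid_k1)
        assert mass_r1 >= 0.95

    def test_isd_mass_above_diagonal_is_zero_and_normalised(self, sphere_field):
        isd = isd_density(sphere_field)
        above = isd.grid_k1[:, None] > isd.grid_k2[None, :]
        assert np.abs(isd.density[above]).max() <= 1e-6
        assert isd.integral == pytest.approx(1.0, abs=1e-2)

    def test_sphere_H_and_K_density_modes_at_analytic_values(self, sphere_field):
        dens_h, dens_k = curvature_densities(sphere_field)
        assert abs(dens_h.mode - 0.04) <= max(dens_h.bandwidth, 0.004)
        assert abs(dens_k.mode - 1.6e-3) <= max(dens_k.bandwidth, 2.4e-4)
        assert dens_h.integral == pytest.approx(1.0, abs=1e-3)
        assert dens_k.integral == pytest.approx(1.0, abs=1e-3)

    def test_too_few_vertices_rejected(self):
        field = CurvatureField(np.zeros(5), np.zeros(5), np.zeros(5), np.zeros(5), 1.0, np.zeros(5, bool))
        with pytest.raises(ValueError):
            isd_density(field)

    def test_ensemble_of_identical_isds_has_zero_std_and_stays_normalised(self, sphere_field):
        isd = isd_density(sphere_field)
        mean, std = ensemble_isd([isd, isd, isd])
        np.testing.assert_allclose(std, 0.0, atol=1e-9)
        assert mean.integral == pytest.approx(1.0, abs=1e-3)

    def test_inconsistent_isd_grids_rejected(self, sphere_field):
        a = isd_density(sphere_field)
        g = a.grid_k1 + 0.01
        b = isd_density(sphere_field, g, a.grid_k2)
        with pytest.raises(ValueError):
            ensemble_isd([a, b])


class TestGeodesicCoarsening:
    def test_dimpled_alveolus_absorbed_into_region_1_with_larger_radius(self):
        n = 56
        z, y, x = np.mgrid[:n, :n, :n]
        c = n // 2
        air = (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= 20 * 20
        dimple = (z - c) ** 2 + (y - c) ** 2 + (x - (c + 20)) ** 2 <= 5 * 5
        mask = BinaryVolume(~(air & ~dimple), 1.0)  # a small inward bump on the cavity wall
        mesh = smooth_mesh(extract_surface(mask), 20, 0.5)
        fractions = []
        for radius in (2.0, 5.0, 10.0):
            field = normal_cycle_curvature(mesh, radius)
            labels = classify_regions(field)
            inc = field.included
            fractions.append((labels[inc] == 1).mean())
        assert fractions[0] <= fractions[1] + 0.02
        assert fractions[1] <= fractions[2] + 0.02
        assert fractions[2] > fractions[0]


class TestMapToSlices:
    def test_single_vertex_labels_its_voxel_only(self):
        mesh = SurfaceMesh(np.array([[2.0, 3.0, 4.0]]), np.zeros((0, 3), dtype=int), np.array([[0.0, 0.0, 1.0]]), 1.0)
        out = map_to_slices(mesh, np.array([2]), (6, 6, 6))
        assert out[2, 3, 4] == 2
        assert out.sum() == 2

    def test_sphere_labels_form_thin_shell_with_valid_values(self, sphere_mesh, sphere_field):
        labels = classify_regions(sphere_field)
        shape = (60, 60, 60)
        out = map_to_slices(sphere_mesh, labels, shape)
        assert set(np.unique(out)) <= {0, 1, 2, 3, 4}
        filled = out > 0
        from scipy import ndimage

        dist_in = ndimage.distance_transform_edt(filled)
        assert dist_in.max() <= 2.0  # shell at most ~2 voxels thick

    def test_out_of_bounds_vertices_rejected(self):
        mesh = SurfaceMesh(np.array([[9.0, 0.0, 0.0]]), np.zeros((0, 3), dtype=int), np.array([[1.0, 0.0, 0.0]]), 1.0)
        with pytest.raises(ValueError):
            map_to_slices(mesh, np.array([1]), (4, 4, 4))
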