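"""Willard-Chandler density fields, isosurfaces and bilayer geometry."""

import numpy as np
import pytest

from conftest import icosphere
from micellekit.errors import (
    DegenerateSurfaceError,
    NoSurfaceError,
    NotABilayerError,
    OpenMeshError,
)
from micellekit.structures import Box
from micellekit.surface import (
    WCParams,
    aggregate_surface,
    area_per_headgroup,
    bilayer_thickness,
    gaussian_density_grid,
    mesh_area_volume,
    mesh_from_arrays,
    per_surfactant_metrics,
    split_bilayer_leaflets,
    willard_chandler_surface,
)

BOX = Box(60.0, 60.0, 60.0)
WC = WCParams()


class TestDensityField:
    def test_single_point_peak_at_nearest_node(self):
        field = gaussian_density_grid([[30.0, 30.0, 30.0]], BOX, WC)
        idx = np.unravel_index(np.argmax(field.values), field.values.shape)
        np.testing.assert_allclose(np.array(idx) * field.spacings, [30.0, 30.0, 30.0])

    def test_two_distant_points_superpose(self):
        field = gaussian_density_grid([[10.0, 30, 30], [50.0, 30, 30]], BOX, WC)
        v = field.values
        i1 = v[5, 15, 15]
        i2 = v[25, 15, 15]
        assert i1 == pytest.approx(i2, rel=1e-9)
        assert field.rho_max == pytest.approx(i1, rel=1e-6)

    @pytest.mark.parametrize("truncation,bound", [(4.0, 1e-2), (5.0, 1e-3)],
                             ids=["default-4h", "extended-5h"])
    def test_truncation_against_untruncated_oracle(self, truncation, bound):
        """Truncated scatter matches an untruncated double loop.

        The truncation error at radius t*h scales as exp(-t^2/2) relative to
        a unit kernel; at nodes holding a tenth of the peak density of a
        random gas this amounts to <1% for the default 4h and <0.1% at 5h.
        """
        rng = np.random.default_rng(0)
        box = Box(40.0, 40.0, 40.0)
        pts = rng.uniform(0, 40, size=(50, 3))
        params = WCParams(spacing=2.0, truncation=truncation)
        field = gaussian_density_grid(pts, box, params, mode="supercell")
        n = field.values.shape[0]
        axes = np.arange(n) * field.spacings[0]
        gx, gy, gz = np.meshgrid(axes, axes, axes, indexing="ij")
        nodes = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
        ref = np.zeros(nodes.shape[0])
        shifts = np.array([[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1)
                           for k in (-1, 0, 1)]) * box.lengths
        for p in pts:
            for s in shifts:
                d2 = ((nodes - (p + s)) ** 2).sum(axis=1)
                ref += np.exp(-d2 / (2 * params.bandwidth ** 2))
        ref = ref.reshape(field.values.shape)
        mask = ref > ref.max() / 10.0
        rel = np.abs(field.values - ref)[mask] / ref[mask]
        assert rel.max() < bound

    def test_supercell_and_minimum_image_agree_for_compact_cluster(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(loc=30.0, scale=4.0, size=(80, 3))
        f_sc = gaussian_density_grid(pts, BOX, WC, mode="supercell")
        f_mi = gaussian_density_grid(pts, BOX, WC, mode="minimum_image")
        assert np.abs(f_sc.values - f_mi.values).max() < 1e-10 * f_sc.rho_max


class TestWillardChandler:
    def test_single_gaussian_isocontour_radius(self):
        """exp(-r^2/2h^2) = 1/3 crosses at r = h sqrt(2 ln 3) ~ 5.93 A."""
        field = gaussian_density_grid([[30.0, 30.0, 30.0]], BOX, WC)
        mesh = willard_chandler_surface(field, WC)
        r = np.linalg.norm(mesh.vertices - 30.0, axis=1)
        analytic = 4.0 * np.sqrt(2.0 * np.log(3.0))
        assert np.abs(r - analytic).max() < WC.spacing

    def test_periodic_translation_invariance(self):
        pt = np.array([[30.0, 30.0, 30.0]])
        base = willard_chandler_surface(gaussian_density_grid(pt, BOX, WC), WC)
        a0, v0 = mesh_area_volume(base)
        # grid-commensurate shift wrapping the blob through the box corner
        shifted = pt + [58.0, 58.0, 58.0]
        mesh = willard_chandler_surface(gaussian_density_grid(shifted, BOX, WC), WC)
        a1, v1 = mesh_area_volume(mesh)
        assert a1 == pytest.approx(a0, rel=0.01)
        assert v1 == pytest.approx(v0, rel=0.01)

    def test_aggregate_surface_invariant_under_any_translation(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(loc=30.0, scale=3.0, size=(60, 3))
        a0, v0 = mesh_area_volume(aggregate_surface(pts, BOX, WC))
        a1, v1 = mesh_area_volume(aggregate_surface(pts + [41.137, -8.2, 17.77], BOX, WC))
        # recentring makes the geometry identical up to fp round-off
        assert a1 == pytest.approx(a0, rel=1e-6)
        assert v1 == pytest.approx(v0, rel=1e-6)

    def test_vesicle_shell_has_two_nested_components(self):
        from micellekit import synthetic

        frame, truth = synthetic.make_vesicle(r_outer=50.0, shell_thickness=20.0, seed=1)
        mesh = aggregate_surface(frame.coordinates, frame.box, WC)
        assert mesh.n_components == 2
        vols = np.sort(mesh.component_volume)
        assert vols[0] < 0 < vols[1]  # inner cavity subtracts
        _, material = mesh_area_volume(mesh)
        assert material == pytest.approx(truth["shell_volume"], rel=0.15)

    def test_empty_level_set_is_an_error(self):
        from micellekit.surface import DensityField

        field = DensityField(values=np.ones((4, 4, 4)), box=Box(8, 8, 8),
                             spacings=np.array([2.0, 2.0, 2.0]), mode="supercell")
        with pytest.raises(NoSurfaceError):
            willard_chandler_surface(field, WC)

    def test_grid_refinement_convergence(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(loc=30.0, scale=5.0, size=(150, 3))
        coarse = mesh_area_volume(aggregate_surface(pts, BOX, WCParams(spacing=2.0)))
        fine = mesh_area_volume(aggregate_surface(pts, BOX, WCParams(spacing=1.0)))
        assert coarse[0] == pytest.approx(fine[0], rel=0.05)
        assert coarse[1] == pytest.approx(fine[1], rel=0.05)


class TestMeshMetrics:
    def test_unit_cube_closed_form(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                      [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float) + 1.0
        f = np.array([
            [0, 2, 1], [0, 3, 2],        # bottom (z=0), outward -z
            [4, 5, 6], [4, 6, 7],        # top, outward +z
            [0, 1, 5], [0, 5, 4],        # y=0 face
            [2, 3, 7], [2, 7, 6],        # y=1 face
            [1, 2, 6], [1, 6, 5],        # x=1 face
            [3, 0, 4], [3, 4, 7],        # x=0 face
        ])
        mesh = mesh_from_arrays(v, f, Box(10, 10, 10))
        area, vol = mesh_area_volume(mesh)
        assert area == pytest.approx(6.0)
        assert vol == pytest.approx(1.0)

    def test_icosphere_refinement_matches_closed_form(self):
        v, f = icosphere(radius=10.0, depth=4)
        mesh = mesh_from_arrays(v, f, Box(100, 100, 100))
        area, vol = mesh_area_volume(mesh)
        assert area == pytest.approx(4 * np.pi * 100.0, rel=0.02)
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * 1000.0, rel=0.02)

    def test_nested_reversed_sphere_subtracts_cavity(self):
        vo, fo = icosphere(radius=10.0, depth=3)
        vi, fi = icosphere(radius=5.0, depth=3)
        fi = fi[:, ::-1]  # reversed: normals into the cavity
        v = np.concatenate([vo, vi])
        f = np.concatenate([fo, fi + vo.shape[0]])
        mesh = mesh_from_arrays(v, f, Box(100, 100, 100))
        _, vol = mesh_area_volume(mesh)
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * (1000.0 - 125.0), rel=0.02)

    def test_open_mesh_reports_boundary_edges(self):
        v, f = icosphere(radius=10.0, depth=1)
        mesh = mesh_from_arrays(v, f[:-2], Box(100, 100, 100))
        with pytest.raises(OpenMeshError) as err:
            mesh_area_volume(mesh)
        assert err.value.n_boundary_edges > 0

    def test_per_surfactant_metrics(self):
        assert per_surfactant_metrics(200.0, 50.0, 2)[0] == 100.0
        a2, v2, _ = per_surfactant_metrics(200.0, 50.0, 4)
        assert (a2, v2) == (50.0, 12.5)
        # sphere of radius 10: SA/V = 3/r
        _, _, sav = per_surfactant_metrics(4 * np.pi * 100, 4 / 3 * np.pi * 1000, 7)
        assert sav == pytest.approx(0.3)
        with pytest.raises(DegenerateSurfaceError):
            per_surfactant_metrics(10.0, 0.0, 1)


def flat_sheet_mesh(z, box, nx=20):
    """Open square-lattice sheet at height z spanning the box in x and y."""
    xs = np.linspace(0, box.lx, nx)
    ys = np.linspace(0, box.ly, nx)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    v = np.column_stack([gx.ravel(), gy.ravel(), np.full(nx * nx, float(z))])
    faces = []
    for i in range(nx - 1):
        for j in range(nx - 1):
            k = i * nx + j
            faces.append([k, k + nx, k + 1])
            faces.append([k + 1, k + nx, k + nx + 1])
    return v, np.array(faces)


class TestBilayer:
    def make_two_sheet_mesh(self, z_lo=10.0, z_hi=30.0, box=Box(100, 100, 50)):
        v1, f1 = flat_sheet_mesh(z_lo, box)
        v2, f2 = flat_sheet_mesh(z_hi, box)
        v = np.concatenate([v1, v2])
        f = np.concatenate([f1, f2 + v1.shape[0]])
        return mesh_from_arrays(v, f, box)

    def test_split_orders_by_mean_z(self):
        mesh = self.make_two_sheet_mesh()
        upper, lower = split_bilayer_leaflets(mesh)
        assert upper.vertices[:, 2].mean() == pytest.approx(30.0)
        assert lower.vertices[:, 2].mean() == pytest.approx(10.0)

    def test_single_component_is_not_a_bilayer(self):
        v, f = icosphere(radius=10.0, depth=2)
        mesh = mesh_from_arrays(v, f, Box(100, 100, 100))
        with pytest.raises(NotABilayerError):
            split_bilayer_leaflets(mesh)

    def test_extra_component_warns_and_keeps_two_largest(self):
        box = Box(100, 100, 50)
        v1, f1 = flat_sheet_mesh(10.0, box)
        v2, f2 = flat_sheet_mesh(30.0, box)
        v3, f3 = icosphere(radius=4.0, depth=1, center=(50, 50, 20))
        v = np.concatenate([v1, v2, v3])
        f = np.concatenate([f1, f2 + len(v1), f3 + len(v1) + len(v2)])
        mesh = mesh_from_arrays(v, f, box)
        with pytest.warns(UserWarning, match="components"):
            upper, lower = split_bilayer_leaflets(mesh)
        assert upper.vertices[:, 2].mean() == pytest.approx(30.0)
        assert lower.vertices[:, 2].mean() == pytest.approx(10.0)

    def test_parallel_sheet_thickness(self):
        mesh = self.make_two_sheet_mesh(z_lo=10.0, z_hi=30.0)
        upper, lower = split_bilayer_leaflets(mesh)
        d = bilayer_thickness(upper, lower)
        assert np.abs(d - 20.0).max() < WC.spacing
        # pooling is symmetric under swapping the surfaces
        d_swapped = bilayer_thickness(lower, upper)
        assert np.sort(d).tolist() == pytest.approx(np.sort(d_swapped).tolist())

    def test_matched_corrugation_preserves_mean_separation(self):
        box = Box(100, 100, 60)
        nx = 40
        v1, f1 = flat_sheet_mesh(15.0, box, nx=nx)
        v2, f2 = flat_sheet_mesh(35.0, box, nx=nx)
        ripple1 = 4.0 * np.sin(2 * np.pi * v1[:, 0] / box.lx)
        ripple2 = 4.0 * np.sin(2 * np.pi * v2[:, 0] / box.lx)
        v1[:, 2] += ripple1
        v2[:, 2] += ripple2
        mesh = mesh_from_arrays(np.concatenate([v1, v2]),
                                np.concatenate([f1, f2 + len(v1)]), box)
        upper, lower = split_bilayer_leaflets(mesh)
        d = bilayer_thickness(upper, lower)
        assert d.mean() == pytest.approx(20.0, abs=0.5)

    def test_area_per_headgroup_and_scaling(self):
        mesh = self.make_two_sheet_mesh()
        upper, lower = split_bilayer_leaflets(mesh)
        assert area_per_headgroup(upper, lower, 400) == pytest.approx(50.0, rel=1e-6)
        assert area_per_headgroup(upper, lower, 800) == pytest.approx(25.0, rel=1e-6)
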