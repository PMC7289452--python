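"""Geometry: shape construction, volumes, regions, tessellation, export."""

import numpy as np
import pytest
import trimesh

import cavidose as cv
from cavidose.geometry import fibonacci_directions


def closed_form_radius_mm(volume_ml):
    return (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


class TestShapeConstruction:
    @pytest.mark.parametrize("volume_ml", [48.5, 173.0])
    def test_sphere_radius_matches_closed_form(self, volume_ml):
        g = cv.make_bladder_shape("sphere", volume_ml)
        assert g.base_params[0] == pytest.approx(closed_form_radius_mm(volume_ml), rel=1e-9)
        assert g.void_volume_mm3 == pytest.approx(volume_ml * 1000.0, rel=0.01)

    @pytest.mark.parametrize(
        "kind,params",
        [
            ("ellipsoid", {"aspect": (1.0, 0.7, 1.4)}),
            ("superellipsoid", {"aspect": (1.0, 0.9, 1.1), "exponent": 3.0}),
            ("lobulated", {"n_lobes": 5, "amplitude": 0.2}),
        ],
    )
    def test_volume_calibration_all_kinds(self, kind, params):
        g = cv.make_bladder_shape(kind, 120.0, shape_params=params, seed=7)
        assert g.void_volume_mm3 == pytest.approx(120_000.0, rel=0.01)

    def test_lobulated_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-40, 40, size=(500, 3))
        a = cv.make_bladder_shape("lobulated", 100.0, seed=11)
        b = cv.make_bladder_shape("lobulated", 100.0, seed=11)
        assert np.array_equal(a.implicit_fn(pts), b.implicit_fn(pts))
        c = cv.make_bladder_shape("lobulated", 100.0, seed=12)
        assert not np.array_equal(a.implicit_fn(pts), c.implicit_fn(pts))

    def test_rejects_nonphysical_parameters(self):
        with pytest.raises(ValueError):
            cv.make_bladder_shape("sphere", -10.0)
        with pytest.raises(ValueError):
            cv.make_bladder_shape("torus", 50.0)
        with pytest.raises(ValueError):
            cv.make_bladder_shape("sphere", 50.0, wall_thickness_mm=0.0)

    def test_star_shapedness_ray_casting(self):
        """Every centroid ray crosses the inner surface exactly once."""
        g = cv.make_bladder_shape(
            "lobulated", 90.0, shape_params={"amplitude": 0.25, "n_lobes": 6}, seed=3
        )
        rng = np.random.default_rng(42)
        dirs = rng.normal(size=(1000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        ts = np.linspace(1e-3, 2.0 * g.r_max, 400)
        for d in dirs[:: max(1, len(dirs) // 1000)]:
            u = g.implicit_fn(np.outer(ts, d))
            crossings = np.sum(np.diff(np.sign(u)) != 0)
            assert crossings == 1


class TestSphereEquivalentRadius:
    def test_printed_value_100ml(self):
        r = cv.sphere_equivalent_radius(100.0)
        assert r == pytest.approx(2.879, abs=1e-3)
        assert round(r) == 3

    def test_unit_sphere(self):
        assert cv.sphere_equivalent_radius(4.0 * np.pi / 3.0) == pytest.approx(1.0)

    def test_48p5_ml(self):
        assert cv.sphere_equivalent_radius(48.5) == pytest.approx(2.26, abs=0.005)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            cv.sphere_equivalent_radius(0.0)


class TestRegions:
    def test_labels_partition_space(self, sphere48):
        r = sphere48.base_params[0]
        assert cv.region_at(sphere48, [0, 0, 0]) == "void"
        assert cv.region_at(sphere48, [0, 0, r + 1.5]) == "wall"
        assert cv.region_at(sphere48, [0, 0, r + 3.0 + 6.0]) == "adipose"
        assert cv.region_at(sphere48, [0, 0, 500.0]) == "outside"

    def test_consistent_with_layers_along_any_ray(self):
        g = cv.make_bladder_shape("ellipsoid", 80.0, {"aspect": (1.0, 0.8, 1.2)})
        d = np.array([0.3, -0.8, 0.52])
        d /= np.linalg.norm(d)
        r = g.directional_radius(d)
        assert cv.region_at(g, d * (r - 0.1)) == "void"
        assert cv.region_at(g, d * (r + g.wall_thickness_mm / 2)) == "wall"

    def test_nonfinite_point_rejected(self, sphere48):
        with pytest.raises(ValueError):
            cv.region_at(sphere48, [np.nan, 0, 0])


class TestTessellation:
    def test_sphere_area_closed_form(self, sphere48, sphere48_patches):
        expect = 4.0 * np.pi * sphere48.base_params[0] ** 2
        assert sphere48_patches.total_area == pytest.approx(expect, rel=0.01)

    def test_patch_count_and_quasi_uniformity(self, sphere48):
        p = cv.tessellate_surface(sphere48, 12)
        assert p.n_patches == 12
        p200 = cv.tessellate_surface(sphere48, 200)
        mean = p200.patch_areas.mean()
        assert np.all(np.abs(p200.patch_areas - mean) < 0.2 * mean)

    def test_ellipsoid_area_against_mesh_oracle(self):
        """Quadrature patch areas vs an independent triangulated-surface
        area (deformed icosphere, trimesh)."""
        g = cv.make_bladder_shape("ellipsoid", 100.0, {"aspect": (1.0, 0.7, 1.3)})
        p = cv.tessellate_surface(g, 150)
        base = trimesh.creation.icosphere(subdivisions=5, radius=1.0)
        dirs = base.vertices / np.linalg.norm(base.vertices, axis=1, keepdims=True)
        mesh = trimesh.Trimesh(
            vertices=dirs * g.directional_radius(dirs)[:, None],
            faces=base.faces,
            process=False,
        )
        assert p.total_area == pytest.approx(mesh.area, rel=0.01)

    def test_every_direction_maps_to_one_patch(self, sphere48_patches):
        rng = np.random.default_rng(5)
        d = rng.normal(size=(2000, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        owners = sphere48_patches.assign(d)
        assert owners.shape == (2000,)
        assert owners.min() >= 0 and owners.max() < 200

    def test_minimum_patch_count_enforced(self, sphere48):
        with pytest.raises(ValueError):
            cv.tessellate_surface(sphere48, 6)


class TestExport:
    def test_vtk_polydata_one_cell_per_patch(self, sphere48, sphere48_patches, tmp_path):
        path = tmp_path / "surf.vtk"
        cv.export_geometry(
            sphere48,
            sphere48_patches,
            path,
            format="vtk",
            scalars={"irradiance": np.linspace(0, 1, 200)},
        )
        text = path.read_text()
        assert text.startswith("# vtk DataFile Version")
        assert "POINTS 200 float" in text
        assert "VERTICES 200 400" in text
        assert "SCALARS irradiance float 1" in text

    def test_ply_roundtrip_vertex_count(self, tmp_path):
        g = cv.make_bladder_shape("lobulated", 60.0, seed=2)
        p = cv.tessellate_surface(g, 50)
        path = tmp_path / "surf.ply"
        cv.export_geometry(g, p, path, format="ply")
        header = path.read_text().splitlines()
        assert header[0] == "ply"
        mesh = trimesh.load(str(path))
        n_expected = trimesh.creation.icosphere(subdivisions=3).vertices.shape[0]
        assert mesh.vertices.shape[0] == n_expected

    def test_unknown_format_rejected(self, sphere48, sphere48_patches, tmp_path):
        with pytest.raises(ValueError):
            cv.export_geometry(sphere48, sphere48_patches, tmp_path / "x.obj", "obj")


def test_fibonacci_directions_are_unit_and_spread():
    d = fibonacci_directions(500)
    assert np.allclose(np.linalg.norm(d, axis=1), 1.0)
    # mean direction of a balanced lattice is near zero
    assert np.linalg.norm(d.mean(axis=0)) < 0.01
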