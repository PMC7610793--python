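"""Mesh/voxel geometry: gyral thickness, masks, ribbon volumes, normals."""

import numpy as np
import pytest
import trimesh

import gyralfield as gf
from gyralfield.surface_geometry import (
    CorticalRibbon,
    MaskVolume,
    ScalarVolume,
    TriangleMesh,
    VoxelGrid,
    compute_gyral_thickness,
    deep_anchor_point,
    deep_mask_from_gyral,
    hemisphere_directions,
    mid_surface,
    threshold_gyral_mask,
    triangle_cortical_volumes,
    triangle_normals_areas,
)


def _grid(shape, voxel=1.0, origin=(0.0, 0.0, 0.0)):
    aff = np.diag([voxel, voxel, voxel, 1.0])
    aff[:3, 3] = origin
    return VoxelGrid(shape, aff)


def _rect_sheet(x, y0, y1, z0, z1, n=6):
    """Planar rectangle perpendicular to x, triangulated."""
    ys = np.linspace(y0, y1, n)
    zs = np.linspace(z0, z1, n)
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    verts = np.column_stack([np.full(yy.size, x), yy.ravel(), zz.ravel()])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + n, a + n + 1])
            faces.append([a, a + n + 1, a + 1])
    return verts, np.array(faces)


class TestTriangleMesh:
    def test_index_validation(self):
        with pytest.raises(ValueError, match="out of range"):
            TriangleMesh(np.zeros((3, 3)), [[0, 1, 3]])

    def test_repeated_vertex_rejected(self):
        with pytest.raises(ValueError, match="repeated"):
            TriangleMesh(np.eye(3), [[0, 1, 1]])


class TestGyralThickness:
    def test_slab_interior_equals_width(self):
        """Two parallel boundary planes 8 mm apart -> interior thickness 8."""
        v1, f1 = _rect_sheet(0.0, -20, 20, -20, 20)
        v2, f2 = _rect_sheet(8.0, -20, 20, -20, 20)
        mesh = TriangleMesh(np.vstack([v1, v2]), np.vstack([f1, f2 + len(v1)]))
        grid = _grid((9, 5, 5), origin=(0, -2, -2))
        mask = np.zeros(grid.shape, bool)
        mask[4, 2, 2] = True  # centre voxel at (4, 0, 0)
        thick = compute_gyral_thickness(mesh, grid, MaskVolume(grid, mask), 64, 50.0)
        assert thick.values[4, 2, 2] == pytest.approx(8.0, rel=1e-9)
        assert np.isnan(thick.values[0, 0, 0])  # non-WM voxel -> NaN sentinel

    def test_sphere_centre_equals_diameter(self):
        sph = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
        mesh = TriangleMesh(np.array(sph.vertices), np.array(sph.faces))
        grid = _grid((3, 3, 3), origin=(-1, -1, -1))
        mask = np.zeros(grid.shape, bool)
        mask[1, 1, 1] = True
        thick = compute_gyral_thickness(mesh, grid, MaskVolume(grid, mask), 32, 50.0)
        assert thick.values[1, 1, 1] == pytest.approx(10.0, rel=0.01)

    def test_blade_thinner_than_below_fundus(self, gyrus):
        """Oracle at 10x direction density: the blade between opposing walls
        is thinner than the white matter below the fundus."""
        ribbon, grid, wm = gyrus
        probe = np.zeros(grid.shape, bool)
        blade = tuple(np.round(grid.world_to_voxel([0.0, 6.0, 4.0])[0]).astype(int))
        below = tuple(np.round(grid.world_to_voxel([0.0, 6.0, -10.0])[0]).astype(int))
        probe[blade] = probe[below] = True
        thick = compute_gyral_thickness(ribbon.white, grid, MaskVolume(grid, probe), 640, 50.0)
        assert thick.values[blade] < thick.values[below]
        # blade thickness matches the analytic chord width of the cosine fold
        assert thick.values[blade] == pytest.approx(16 / np.pi * np.arccos(0.5), rel=0.02)

    def test_doubling_directions_never_increases(self, gyrus):
        """Prefix-stable direction sampling: refinement only tightens the minimum."""
        ribbon, grid, wm = gyrus
        probe = np.zeros(grid.shape, bool)
        idx = np.argwhere(wm.values)[:: max(wm.n_voxels // 40, 1)]
        probe[tuple(idx.T)] = True
        pm = MaskVolume(grid, probe)
        t32 = compute_gyral_thickness(ribbon.white, grid, pm, 32, 50.0)
        t64 = compute_gyral_thickness(ribbon.white, grid, pm, 64, 50.0)
        sel = probe
        assert np.all(t64.values[sel] <= t32.values[sel] + 1e-12)
        assert np.allclose(hemisphere_directions(32), hemisphere_directions(64)[:32])

    def test_empty_mask_rejected(self, gyrus):
        ribbon, grid, _ = gyrus
        with pytest.raises(ValueError, match="empty"):
            compute_gyral_thickness(ribbon.white, grid, MaskVolume(grid, np.zeros(grid.shape, bool)), 8, 50.0)


class TestThresholdMask:
    def _vols(self, value):
        grid = _grid((4, 4, 4))
        wm = MaskVolume(grid, np.ones(grid.shape, bool))
        return ScalarVolume(grid, np.full(grid.shape, float(value))), wm

    def test_all_below_threshold(self):
        thick, wm = self._vols(5.0)
        assert threshold_gyral_mask(thick, wm, 10.0).n_voxels == wm.n_voxels

    def test_all_above_threshold(self):
        thick, wm = self._vols(15.0)
        assert threshold_gyral_mask(thick, wm, 10.0).n_voxels == 0

    def test_slab_plus_basin_phantom(self):
        grid = _grid((6, 4, 8))
        wm = MaskVolume(grid, np.ones(grid.shape, bool))
        vals = np.full(grid.shape, 20.0)
        vals[:, :, 4:] = 4.0  # the "blade" half
        gyral = threshold_gyral_mask(ScalarVolume(grid, vals), wm, 10.0)
        assert np.array_equal(gyral.values, vals < 10.0)

    def test_partition_of_white_matter(self, gyrus, thickness, masks):
        _, _, wm = gyrus
        gyral, deep = masks
        assert not np.any(gyral.values & deep.values)
        assert np.array_equal(gyral.values | deep.values, wm.values)

    def test_nonpositive_threshold_rejected(self):
        thick, wm = self._vols(5.0)
        with pytest.raises(ValueError):
            threshold_gyral_mask(thick, wm, 0.0)


class TestRibbonVolumes:
    def _ribbon(self, white_v, pial_v, faces):
        return CorticalRibbon(TriangleMesh(white_v, faces), TriangleMesh(pial_v, faces))

    def test_prism_volume(self):
        w = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        ribbon = self._ribbon(w, w + [0, 0, 2.0], np.array([[0, 1, 2]]))
        assert ribbon.triangle_volumes[0] == pytest.approx(0.5 * 2.0, rel=1e-12)

    def test_coincident_surfaces_zero(self):
        w = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        ribbon = self._ribbon(w, w.copy(), np.array([[0, 1, 2]]))
        assert ribbon.triangle_volumes[0] == 0.0

    def test_matches_convex_hull_for_convex_wedges(self):
        """Oblique frusta (pial = scaled + translated white) are convex, so
        the tetrahedral decomposition must equal the hull volume."""
        from scipy.spatial import ConvexHull

        rng = np.random.default_rng(42)
        faces = np.array([[0, 1, 2]])
        for _ in range(10):
            w = rng.uniform(-1, 1, (3, 3))
            c = rng.uniform(0.4, 1.8)
            t = rng.uniform(-1, 1, 3) + [0, 0, 3.0]
            p = c * w + t
            ribbon = self._ribbon(w, p, faces)
            hull = ConvexHull(np.vstack([w, p]))
            assert ribbon.triangle_volumes[0] == pytest.approx(hull.volume, rel=1e-9)

    def test_inverted_wedge_warns(self):
        w = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        p = w + [0, 0, -1.0]
        p[0, 2] = 1.0  # one pial vertex on the other side
        with pytest.warns(UserWarning, match="inverted"):
            self._ribbon(w, p, np.array([[0, 1, 2]]))

    def test_total_volume_matches_voxelised_ribbon(self):
        """Sum of wedge volumes vs 0.5 mm voxel counting on a gentle fold
        (no pial fold-over, so the ribbon is bounded by two graphs)."""
        spec = gf.GyrusSpec(wavelength=16, amplitude=3.0, thickness=1.5)
        ribbon, _, _ = gf.make_gyrus(spec)
        h = 0.5
        xs = np.arange(-8 + h / 2, 8, h)
        zs = np.arange(-4, 6, h)
        xx, zz = np.meshgrid(xs, zs, indexing="ij")
        white_h = spec.amplitude * np.cos(2 * np.pi * xx / spec.wavelength)
        # pial surface as a graph, interpolated from offset vertices at fixed y
        sel = np.isclose(ribbon.pial.vertices[:, 1], 0.0)
        px = ribbon.pial.vertices[sel, 0]
        pz = ribbon.pial.vertices[sel, 2]
        order = np.argsort(px)
        pial_h = np.interp(xx, px[order], pz[order])
        inside = (zz >= white_h) & (zz < pial_h)
        vox_volume = inside.sum() * h * h * spec.extrusion
        assert ribbon.total_volume == pytest.approx(vox_volume, rel=0.02)


class TestMidSurface:
    def test_halfway(self, gyrus):
        ribbon, _, _ = gyrus
        mid = mid_surface(ribbon)
        dw = np.linalg.norm(mid.vertices - ribbon.white.vertices, axis=1)
        dp = np.linalg.norm(mid.vertices - ribbon.pial.vertices, axis=1)
        assert np.allclose(dw, dp, atol=1e-12)
        assert np.array_equal(mid.faces, ribbon.white.faces)

    def test_planar_sheets(self):
        v, f = _rect_sheet(0.0, 0, 1, 0, 1, n=3)
        w = v.copy()
        w[:, 0] = 0.0
        p = v.copy()
        p[:, 0] = 2.0
        ribbon = CorticalRibbon(TriangleMesh(w, f), TriangleMesh(p, f))
        assert np.allclose(ribbon.mid.vertices[:, 0], 1.0)

    def test_mismatched_vertex_counts_rejected(self):
        w = TriangleMesh(np.eye(3), [[0, 1, 2]])
        p = TriangleMesh(np.vstack([np.eye(3), [0, 0, 1]]), [[0, 1, 2]])
        with pytest.raises(ValueError):
            CorticalRibbon(w, p)


class TestNormalsAreas:
    def test_unit_right_triangle(self):
        mesh = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        n, a = triangle_normals_areas(mesh)
        assert np.allclose(n[0], [0, 0, 1])
        assert a[0] == pytest.approx(0.5)

    def test_reversed_winding_flips_normal(self):
        mesh = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 2, 1]])
        n, _ = triangle_normals_areas(mesh)
        assert np.allclose(n[0], [0, 0, -1])

    def test_icosphere_total_area(self):
        sph = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
        mesh = TriangleMesh(np.array(sph.vertices), np.array(sph.faces))
        _, areas = triangle_normals_areas(mesh)
        assert areas.sum() == pytest.approx(4 * np.pi * 4.0, rel=0.01)

    def test_degenerate_face_named(self):
        mesh = TriangleMesh([[0, 0, 0], [1, 0, 0], [2, 0, 0]], [[0, 1, 2]])
        with pytest.raises(ValueError, match="face"):
            triangle_normals_areas(mesh)


class TestDeepAnchor:
    def test_cube_centroid(self):
        grid = _grid((5, 5, 5), origin=(-2, -2, -2))
        mask = MaskVolume(grid, np.ones(grid.shape, bool))
        assert np.allclose(deep_anchor_point(mask), [0, 0, 0])

    def test_two_voxel_mask_snaps(self):
        grid = _grid((3, 1, 1))
        m = np.zeros(grid.shape, bool)
        m[0, 0, 0] = m[2, 0, 0] = True
        anchor = deep_anchor_point(MaskVolume(grid, m))
        # centroid (1,0,0) is not a masked voxel -> nearest of the two
        assert any(np.allclose(anchor, c) for c in ([0, 0, 0], [2, 0, 0]))

    def test_c_shape_stays_inside(self):
        grid = _grid((7, 7, 3))
        m = np.zeros(grid.shape, bool)
        m[:, 0, :] = True
        m[0, :, :] = True
        m[:, 6, :] = True  # C-shape opening in +x
        mask = MaskVolume(grid, m)
        anchor = deep_anchor_point(mask)
        ijk = np.round(grid.world_to_voxel(anchor)).astype(int)[0]
        assert mask.values[tuple(ijk)]

    def test_empty_mask_rejected(self):
        grid = _grid((2, 2, 2))
        with pytest.raises(ValueError):
            deep_anchor_point(MaskVolume(grid, np.zeros(grid.shape, bool)))
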