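"""Wedge-ROI machinery: distance maps, bands, boundaries, masks, areas."""

import numpy as np
import pytest

import cortmag as cm
from cortmag.wedge import (DistanceMap, RetinotopyMap, angular_offset,
                           hemisphere_meridians)


def flat_grid_mesh(nx=15, ny=10, spacing=1.0):
    """Flat regular strip, triangulated, with dummy retinotopy."""
    xs, ys = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing,
                         indexing="ij")
    vertices = np.column_stack([xs.ravel(), ys.ravel()])
    idx = np.arange(nx * ny).reshape(nx, ny)
    a = idx[:-1, :-1].ravel()
    b = idx[:-1, 1:].ravel()
    c = idx[1:, :-1].ravel()
    d = idx[1:, 1:].ravel()
    faces = np.vstack([np.column_stack([a, b, c]),
                       np.column_stack([b, d, c])])
    return cm.CorticalMesh(
        hemisphere="left", depth="midgray", vertices=vertices, faces=faces,
        vertex_area=np.ones(nx * ny), polar_angle=np.zeros(nx * ny),
        eccentricity=np.ones(nx * ny))


class TestDistanceMap:
    def test_seed_vertices_at_zero(self, iso_mesh):
        seeds = np.array([0, 57, 300])
        dist = cm.cortical_distance_map(iso_mesh, seeds)
        assert np.all(dist.distances[seeds] == 0.0)

    def test_matches_perpendicular_distance_on_flat_grid(self):
        mesh = flat_grid_mesh(spacing=2.0)
        seeds = np.flatnonzero(mesh.vertices[:, 0] == 0.0)  # straight line
        dist = cm.cortical_distance_map(mesh, seeds)
        exact = mesh.vertices[:, 0]
        assert np.all(np.abs(dist.distances - exact) <= 2.0 + 1e-9)

    def test_shortest_path_triangle_inequality(self, iso_mesh):
        dist = cm.cortical_distance_map(iso_mesh, np.array([10]))
        edges = iso_mesh.edges()
        lengths = np.linalg.norm(iso_mesh.vertices[edges[:, 0]]
                                 - iso_mesh.vertices[edges[:, 1]], axis=1)
        gap = np.abs(dist.distances[edges[:, 0]]
                     - dist.distances[edges[:, 1]])
        assert np.all(gap <= lengths + 1e-9)

    def test_empty_seed_set_rejected(self, iso_mesh):
        with pytest.raises(ValueError):
            cm.cortical_distance_map(iso_mesh, np.array([], dtype=int))


class TestLogBands:
    def test_default_band_edges(self):
        edges = cm.log_spaced_bands()
        assert edges.shape == (11,)
        assert edges[0] == pytest.approx(1.0)
        assert edges[-1] == pytest.approx(8.0)
        ratios = edges[1:] / edges[:-1]
        assert np.allclose(ratios, 8 ** 0.1)

    def test_single_band(self):
        assert np.allclose(cm.log_spaced_bands(n_bands=1), [1.0, 8.0])

    @pytest.mark.parametrize("kwargs", [
        {"n_bands": 0}, {"ecc_min": 0.0}, {"ecc_min": 9.0, "ecc_max": 8.0}])
    def test_invalid_bands_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cm.log_spaced_bands(**kwargs)


class TestMeridianLine:
    def test_line_vertices_lie_on_meridian(self, iso_mesh):
        retino = RetinotopyMap.from_mesh(iso_mesh)
        line = cm.meridian_line_vertices(retino, iso_mesh, "HM_right",
                                         angle_tol=2.0)
        assert line.size > 0
        assert np.all(angular_offset(iso_mesh.polar_angle[line], 0.0) <= 2.0)

    def test_line_spans_eccentricity_range(self, iso_mesh):
        retino = RetinotopyMap.from_mesh(iso_mesh)
        line = cm.meridian_line_vertices(retino, iso_mesh, "UVM",
                                         angle_tol=2.0, ecc_range=(1.0, 8.0))
        ecc = iso_mesh.eccentricity[line]
        ring_ratio = 12.0 / 0.2
        ring_step = ring_ratio ** (1 / 95)  # one generator ring spacing
        assert ecc.min() <= 1.0 * ring_step
        assert ecc.max() >= 8.0 / ring_step

    def test_zero_tolerance_raises_on_generic_map(self, iso_mesh):
        retino = RetinotopyMap.from_mesh(iso_mesh)
        jittered = RetinotopyMap(retino.polar_angle + 0.37,
                                 retino.eccentricity, retino.included)
        with pytest.raises(ValueError, match="angle_tol"):
            cm.meridian_line_vertices(jittered, iso_mesh, "HM_right",
                                      angle_tol=0.0)


class TestBoundaryDistance:
    def _retino(self, angles, eccs):
        return RetinotopyMap(np.asarray(angles, float),
                             np.asarray(eccs, float),
                             np.ones(len(angles), dtype=bool))

    def test_constant_distance_pool_returns_it(self):
        retino = self._retino([15.0] * 5, [2.0] * 5)
        dist = DistanceMap(np.full(5, 3.25), "HM_right", np.array([0]))
        d = cm.isoangle_boundary_distance((1.0, 4.0), dist, retino, 0.0)
        assert d == pytest.approx(3.25)

    def test_linear_angle_distance_relation(self):
        """offset = c * distance exactly, pool uniform on [7, 23] -> 15/c."""
        c = 4.0
        angles = np.linspace(7.0, 23.0, 33)
        retino = self._retino(angles, np.full(33, 2.0))
        dist = DistanceMap(angles / c, "HM_right", np.array([0]))
        d = cm.isoangle_boundary_distance((1.0, 4.0), dist, retino, 0.0)
        assert d == pytest.approx(15.0 / c, rel=1e-9)

    def test_empty_pool_returns_none(self):
        retino = self._retino([40.0, 50.0], [2.0, 2.0])
        dist = DistanceMap(np.array([1.0, 2.0]), "HM_right", np.array([0]))
        assert cm.isoangle_boundary_distance((1.0, 4.0), dist, retino, 0.0,
                                             pool_half_width=0.0) is None


@pytest.fixture(scope="module")
def iso_setup(iso_mesh):
    retino = RetinotopyMap.from_mesh(iso_mesh)
    seeds = cm.meridian_line_vertices(retino, iso_mesh, "HM_right",
                                      angle_tol=2.0, ecc_range=(1, 8))
    dist = cm.cortical_distance_map(iso_mesh, seeds, "HM_right")
    return retino, dist


class TestWedgeMasks:
    def test_mask_vertices_respect_wedge_angle(self, iso_mesh, iso_setup):
        retino, dist = iso_setup
        mask = cm.build_wedge_mask(dist, retino, cm.WedgeConfig(),
                                   "HM_right")
        offs = angular_offset(iso_mesh.polar_angle[mask.vertex_indices], 0.0)
        assert np.mean(offs <= 15.0 + 1e-9) >= 0.95

    def test_wider_boundary_gives_superset(self, iso_mesh, iso_setup):
        retino, dist = iso_setup
        narrow = cm.build_wedge_mask(dist, retino, cm.WedgeConfig(),
                                     "HM_right")
        wide = cm.build_wedge_mask(dist, retino,
                                   cm.WedgeConfig(half_width=20.0),
                                   "HM_right")
        assert set(narrow.vertex_indices) <= set(wide.vertex_indices)

    def test_surface_area_sums_member_vertices(self, iso_mesh, iso_setup):
        retino, dist = iso_setup
        mask = cm.build_wedge_mask(dist, retino, cm.WedgeConfig(),
                                   "HM_right")
        expected = iso_mesh.vertex_area[mask.vertex_indices].sum()
        assert cm.wedge_surface_area(mask, iso_mesh) == pytest.approx(
            expected)

    def test_meridian_wedges_are_pairwise_disjoint(self, iso_mesh):
        _, masks = cm.measure_wedge_areas(iso_mesh)
        sets = {m: set(mask.vertex_indices) for m, mask in masks.items()}
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert not sets[a] & sets[b], f"{a} overlaps {b}"


class TestCombineAndV1:
    def test_combination_arithmetic(self):
        a = 10.0
        left = {"HM_right": 2 * a, "UVM": a, "LVM": a}
        right = {"HM_left": 2 * a, "UVM": a, "LVM": a}
        out = cm.combine_meridian_areas(left, right)
        assert out["HM"] == pytest.approx(4 * a)
        assert out["UVM"] == pytest.approx(2 * a)
        assert out["VM"] == pytest.approx(4 * a)

    def test_zero_uvm_makes_vm_equal_lvm(self):
        left = {"HM_right": 1.0, "UVM": 0.0, "LVM": 2.0}
        right = {"HM_left": 1.0, "UVM": 0.0, "LVM": 2.0}
        out = cm.combine_meridian_areas(left, right)
        assert out["VM"] == out["LVM"]

    def test_missing_hemisphere_data_rejected(self):
        with pytest.raises(ValueError, match="hemisphere"):
            cm.combine_meridian_areas({"UVM": 1.0, "LVM": 1.0},
                                      {"HM_left": 1.0, "UVM": 1, "LVM": 1})

    def test_v1_area_edge_cases(self, iso_mesh):
        assert cm.v1_total_area(iso_mesh, ecc_max=99.0) == pytest.approx(
            iso_mesh.total_area())
        assert cm.v1_total_area(iso_mesh, ecc_max=0.0) == 0.0

    def test_v1_area_matches_analytic_sector(self, iso_mesh):
        model = cm.MagnificationModel()
        exact = cm.sector_area_analytic(model, -90.0, 90.0, (0.2, 8.0))
        assert cm.v1_total_area(iso_mesh, ecc_max=8.0) == pytest.approx(
            exact, rel=0.03)

    def test_hemisphere_meridian_tables(self):
        assert set(hemisphere_meridians("left")) == {"HM_right", "UVM",
                                                     "LVM"}
        assert set(hemisphere_meridians("right")) == {"HM_left", "UVM",
                                                      "LVM"}
        with pytest.raises(ValueError):
            hemisphere_meridians("middle")


class TestDepthConsistency:
    def test_wedge_areas_scale_with_depth_factor(self, iso_mesh):
        """Depth surfaces reuse the mask; areas scale by the depth field."""
        depths = cm.make_depth_surfaces(iso_mesh, modulation_amp=0.0, seed=0)
        mid, _ = cm.measure_wedge_areas(depths["midgray"])
        pial, _ = cm.measure_wedge_areas(depths["pial"])
        for meridian in mid:
            assert pial[meridian] == pytest.approx(1.2 * mid[meridian],
                                                   rel=1e-9)
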