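"""Covariate extraction: buffers, kernel density, road density, TRI and
refuge pattern metrics, checked against direct enumeration."""

import math

import numpy as np
import pytest
from shapely import box as shapely_box
from shapely.geometry import LineString

from wolfmove.landscape import (
    InfluenceArea,
    buffer_track,
    label_patches,
    raster_mean_over_area,
    refuge_metrics,
    road_density,
    settlement_kernel_density,
    terrain_ruggedness,
)
from wolfmove.raster import Raster
from wolfmove.validation import oracle_patch_analysis, oracle_tri


def full_area(nx, ny, res):
    return InfluenceArea(track_id="all", polygon=shapely_box(0, 0, nx * res, ny * res), radius_km=0.0)


class TestBuffer:
    def test_single_fix_gives_unit_disk(self):
        a = buffer_track([3.0], [3.0], radius_km=1.0)
        assert a.area_km2 == pytest.approx(math.pi, rel=1e-3)

    def test_straight_segment_rectangle_plus_caps(self):
        a = buffer_track([0.0, 2.0], [0.0, 0.0], radius_km=1.0)
        assert a.area_km2 == pytest.approx(2 * 2 * 1 + math.pi, rel=1e-3)

    def test_buffer_contains_all_fixes(self):
        rng = np.random.default_rng(3)
        xs, ys = rng.uniform(0, 5, 12), rng.uniform(0, 5, 12)
        a = buffer_track(xs, ys, radius_km=1.0)
        import shapely

        assert shapely.contains_xy(a.polygon, xs, ys).all()


class TestKernelDensity:
    def setup_method(self):
        self.template = Raster(np.zeros((200, 200)), 0.0, 0.0, 0.05)

    def test_surface_integrates_to_total_weight(self):
        pts = np.array([[5.0, 5.0]])
        r = settlement_kernel_density(pts, np.array([37.0]), 1.0, self.template)
        assert r.values.sum() * r.cell_area_km2 == pytest.approx(37.0, rel=1e-3)

    def test_compact_support(self):
        pts = np.array([[5.0, 5.0]])
        r = settlement_kernel_density(pts, None, 1.0, self.template)
        far = r.sample(np.array([8.0]), np.array([8.0]))
        assert far[0] == 0.0

    def test_linearity_in_weights(self):
        pts = np.array([[4.0, 4.0], [6.0, 6.0]])
        r1 = settlement_kernel_density(pts, np.array([1.0, 2.0]), 1.0, self.template)
        r2 = settlement_kernel_density(pts, np.array([2.0, 4.0]), 1.0, self.template)
        assert np.allclose(r2.values, 2 * r1.values)

    def test_no_settlements_gives_zero_surface(self):
        r = settlement_kernel_density(np.empty((0, 2)), None, 1.0, self.template)
        assert (r.values == 0).all()

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            settlement_kernel_density(np.array([[1.0, 1.0]]), None, 0.0, self.template)


class TestRoadDensity:
    def test_no_roads_is_zero(self):
        a = buffer_track([5.0], [5.0], radius_km=1.0)
        assert road_density({"primary": []}, a, "primary") == 0.0

    def test_chord_through_disk_center(self):
        a = buffer_track([5.0], [5.0], radius_km=1.0)
        roads = {"primary": [LineString([(0, 5.0), (10, 5.0)])]}
        assert road_density(roads, a, "primary") == pytest.approx(2.0 / a.area_km2, rel=1e-4)

    def test_additive_under_polyline_split(self):
        a = buffer_track([5.0], [5.0], radius_km=1.0)
        whole = {"s": [LineString([(3, 5.0), (7, 5.0)])]}
        split = {"s": [LineString([(3, 5.0), (5, 5.0)]), LineString([(5, 5.0), (7, 5.0)])]}
        assert road_density(whole, a, "s") == pytest.approx(road_density(split, a, "s"), abs=1e-12)

    def test_unknown_class_rejected(self):
        a = buffer_track([5.0], [5.0], radius_km=1.0)
        with pytest.raises(KeyError):
            road_density({"primary": []}, a, "tertiary")


class TestTRI:
    def test_flat_raster_zero_everywhere(self):
        tri = terrain_ruggedness(Raster(np.full((10, 10), 7.0), 0, 0, 0.01))
        assert (tri.values == 0).all()

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        z = rng.random((15, 15)) * 50
        tri = terrain_ruggedness(Raster(z, 0, 0, 0.01))
        assert np.abs(tri.values - oracle_tri(z)).max() < 1e-9

    def test_nonnegative(self):
        rng = np.random.default_rng(5)
        tri = terrain_ruggedness(Raster(rng.random((8, 8)), 0, 0, 0.01))
        assert (tri.values >= 0).all()

    def test_too_small_raster_rejected(self):
        with pytest.raises(ValueError):
            terrain_ruggedness(Raster(np.zeros((2, 5)), 0, 0, 0.01))


class TestPatches:
    res = 0.01

    def test_empty_raster_no_patches(self):
        patches, n = label_patches(Raster(np.zeros((10, 10)), 0, 0, self.res), full_area(10, 10, self.res))
        assert patches == [] and n == 100

    def test_diagonal_cells_are_one_patch_under_8_connectivity(self):
        g = np.zeros((10, 10), dtype=np.uint8)
        g[2, 2] = g[3, 3] = 1
        patches, _ = label_patches(Raster(g, 0, 0, self.res), full_area(10, 10, self.res))
        assert len(patches) == 1 and patches[0].cell_count == 2

    def test_3x3_block_area_and_perimeter(self):
        g = np.zeros((10, 10), dtype=np.uint8)
        g[2:5, 2:5] = 1
        patches, _ = label_patches(Raster(g, 0, 0, self.res), full_area(10, 10, self.res))
        assert patches[0].cell_count == 9
        assert patches[0].perimeter_edges == 12

    @pytest.mark.parametrize("size", [1, 2, 4, 7])
    def test_square_patch_fdi_is_one(self, size):
        g = np.zeros((12, 12), dtype=np.uint8)
        g[1 : 1 + size, 1 : 1 + size] = 1
        patches, _ = label_patches(Raster(g, 0, 0, self.res), full_area(12, 12, self.res))
        assert patches[0].fractal_dimension == pytest.approx(1.0, abs=1e-12)

    def test_single_cell_patch_cohesion_zero(self):
        g = np.zeros((12, 12), dtype=np.uint8)
        g[5, 5] = 1
        area = full_area(12, 12, self.res)
        patches, n = label_patches(Raster(g, 0, 0, self.res), area)
        assert refuge_metrics(patches, area, n).mean_cohesion == pytest.approx(0.0, abs=1e-12)

    def test_fully_covered_buffer(self):
        g = np.ones((12, 12), dtype=np.uint8)
        area = full_area(12, 12, self.res)
        patches, n = label_patches(Raster(g, 0, 0, self.res), area)
        rm = refuge_metrics(patches, area, n)
        assert rm.refuge_cover_pct == pytest.approx(100.0)
        assert rm.n_patches == 1

    def test_zero_patches_flagged(self):
        area = full_area(10, 10, self.res)
        rm = refuge_metrics([], area, 100)
        assert rm.refuge_cover_pct == 0.0 and rm.n_patches == 0
        assert math.isnan(rm.mean_fdi)

    def test_oracle_equivalence_random_rasters(self):
        rng = np.random.default_rng(6)
        for _ in range(60):
            g = (rng.random((20, 20)) < rng.uniform(0.2, 0.7)).astype(np.uint8)
            area = full_area(20, 20, self.res)
            patches, n = label_patches(Raster(g, 0, 0, self.res), area)
            oracle = oracle_patch_analysis(g)
            assert sorted((p.cell_count, p.perimeter_edges) for p in patches) == sorted(
                (o["cells"], o["perimeter"]) for o in oracle
            )
            rm = refuge_metrics(patches, area, n)
            if rm.n_patches:
                assert rm.refuge_cover_pct == pytest.approx(100.0 * g.sum() / g.size, abs=1e-9)

    def test_cover_monotone_when_cells_added(self):
        rng = np.random.default_rng(7)
        g = (rng.random((20, 20)) < 0.3).astype(np.uint8)
        area = full_area(20, 20, self.res)
        covers = []
        for _ in range(5):
            patches, n = label_patches(Raster(g, 0, 0, self.res), area)
            covers.append(refuge_metrics(patches, area, n).refuge_cover_pct if patches else 0.0)
            zeros = np.argwhere(g == 0)
            if len(zeros) == 0:
                break
            add = zeros[rng.integers(0, len(zeros), 10)]
            g[add[:, 0], add[:, 1]] = 1
        assert all(a <= b + 1e-12 for a, b in zip(covers, covers[1:]))

    def test_fdi_bounds_for_multicell_patches(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            g = (rng.random((20, 20)) < 0.4).astype(np.uint8)
            patches, _ = label_patches(Raster(g, 0, 0, self.res), full_area(20, 20, self.res))
            for p in patches:
                if p.cell_count >= 2:
                    assert 1.0 - 1e-9 <= p.fractal_dimension <= 2.0 + 1e-9


class TestRasterMeans:
    def test_area_mean_of_constant_raster(self):
        r = Raster(np.full((100, 100), 4.2), 0, 0, 0.1)
        a = buffer_track([5.0], [5.0], radius_km=1.0)
        assert raster_mean_over_area(r, a) == pytest.approx(4.2)
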