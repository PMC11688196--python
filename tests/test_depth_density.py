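import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from nisslcolumn import depth_density as dd
from nisslcolumn import stereology as st
from nisslcolumn import synthetic_cortex as sc
from conftest import small_spec


def point_table(xy, image_id="img"):
    xy = np.asarray(xy, float)
    n = len(xy)
    return pd.DataFrame({
        "image_id": image_id, "cell_id": [f"c{i}" for i in range(n)],
        "x_um": xy[:, 0], "y_um": xy[:, 1],
        "d_max_um": 8.0, "d_min_um": 6.0, "dist_pia_um": xy[:, 1].clip(0),
    })


def ray_casting_inside(poly_xy, point):
    """Independent even-odd ray-casting point-in-polygon oracle."""
    x, y = point
    inside = False
    n = len(poly_xy)
    for i in range(n):
        x1, y1 = poly_xy[i]
        x2, y2 = poly_xy[(i + 1) % n]
        # on-edge check
        if (min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12
                and abs((x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)) < 1e-9
                and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12):
            return True
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


class TestFilterInPolygon:
    def test_unit_square_basic_and_boundary(self):
        square = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        cells = point_table([(0.5, 0.5), (2.0, 2.0), (0.0, 0.5)])
        kept = dd.filter_in_polygon(cells, square)
        assert set(kept["cell_id"]) == {"c0", "c2"}  # boundary point retained

    def test_matches_ray_casting_oracle(self, rng):
        poly_xy = [(0, 0), (4, -1), (6, 2), (5, 5), (2, 6), (-1, 3)]
        poly = Polygon(poly_xy)
        pts = np.column_stack([rng.uniform(-2, 7, 400), rng.uniform(-2, 7, 400)])
        kept = set(dd.filter_in_polygon(point_table(pts), poly)["cell_id"])
        expected = {f"c{i}" for i, p in enumerate(pts)
                    if ray_casting_inside(poly_xy, p)}
        assert kept == expected


class TestCheckConvex:
    def test_square_is_convex(self):
        assert dd.check_convex([(0, 0), (1, 0), (1, 1), (0, 1)])

    def test_dart_is_concave(self):
        # arrowhead: TL,TR,BR,BL ordering with a reflex corner
        assert not dd.check_convex([(0, 0), (2, 0), (1, 0.2), (1, 1)])

    def test_collinear_degenerate_allowed(self):
        assert dd.check_convex([(0, 0), (1, 0), (2, 0), (1, 1)])

    def test_repeated_points_rejected(self):
        with pytest.raises(ValueError, match="repeated"):
            dd.check_convex([(0, 0), (0, 0), (1, 1), (0, 1)])


class TestBuildGrid:
    def test_rectangle_degenerates_to_congruent_bins(self):
        spec = small_spec(width=1000.0)
        regions = sc.make_geometry(spec)
        grid = dd.build_depth_grid(regions)
        expected = 1000.0 * spec.total_height_um / 200
        np.testing.assert_allclose(grid.bin_area_um2, expected, rtol=1e-6)

    def test_rectangle_binning_matches_direct_oracle(self, rng):
        spec = small_spec(width=1000.0)
        regions = sc.make_geometry(spec)
        grid = dd.build_depth_grid(regions)
        H = spec.total_height_um
        pts = np.column_stack([rng.uniform(0, 1000, 500) ,
                               rng.uniform(0, H, 500)])
        # keep points away from bin edges so the oracle is unambiguous
        col = np.floor(pts[:, 0] / 100).astype(int)
        row = np.floor(pts[:, 1] / (H / 20)).astype(int)
        edge = (np.abs(pts[:, 0] / 100 - np.round(pts[:, 0] / 100)) < 1e-6)
        pts, col, row = pts[~edge], col[~edge], row[~edge]
        filled = dd.bin_densities(grid, point_table(pts), 50.0)
        counts = np.zeros((10, 20))
        np.add.at(counts, (col, row), 1)
        np.testing.assert_array_equal(filled.counts, counts)

    @pytest.mark.parametrize("curvature", [0.0, 120.0])
    def test_tiling_conserves_area(self, curvature):
        regions = sc.make_geometry(small_spec(curvature=curvature))
        grid = dd.build_depth_grid(regions)
        ratio = grid.bin_area_um2.sum() / regions.s1hl.area
        assert 0.995 <= ratio <= 1.005

    def test_concave_region_refused(self):
        regions = sc.make_geometry(small_spec())
        Pt = type(regions.corners["TR"])
        # dart quadrilateral: BR is a reflex corner
        regions.corners.update(
            TL=Pt(0, 0), TR=Pt(500, 0), BR=Pt(250, 400), BL=Pt(250, 1917))
        with pytest.raises(dd.ConcaveRegionError, match="concave"):
            dd.build_depth_grid(regions)


class TestBinDensities:
    def test_density_arithmetic(self):
        # 100 cells in a 0.01 mm^2 bin x 50 um -> 200,000 cells/mm^3
        area_um2 = 0.01 * 1e6
        side = np.sqrt(area_um2)
        square = Polygon([(0, 0), (side, 0), (side, side), (0, side)])
        grid = dd.DepthGrid(n_cols=1, n_rows=1, polygons=[[square]],
                            bin_area_um2=np.array([[area_um2]]))
        rng = np.random.default_rng(0)
        pts = rng.uniform(1, side - 1, size=(100, 2))
        filled = dd.bin_densities(grid, point_table(pts), 50.0)
        assert filled.density_cells_mm3[0, 0] == pytest.approx(200_000.0)

    def test_count_conservation(self, rect_column):
        _, regions, cells = rect_column
        grid = dd.build_depth_grid(regions)
        inside = dd.filter_in_polygon(cells, regions.s1hl)
        filled = dd.bin_densities(grid, inside, 50.0)
        assert filled.counts.sum() == pytest.approx(len(inside))

    def test_zero_probability_exclusion_changes_nothing(self, rect_column):
        _, regions, cells = rect_column
        grid = dd.build_depth_grid(regions)
        inside = dd.filter_in_polygon(cells, regions.s1hl)
        excl = st.ExclusionResult(
            n_iterations=2, thickness_um=50.0,
            per_iteration_excluded_fraction=np.zeros(2),
            mean_fraction=0.0, sd_fraction=0.0,
            per_cell_exclusion_probability=np.zeros(len(inside)))
        a = dd.bin_densities(grid, inside, 50.0)
        b = dd.bin_densities(grid, inside, 50.0, exclusion=excl)
        np.testing.assert_array_equal(a.density_cells_mm3, b.density_cells_mm3)

    def test_zero_area_bin_reports_missing(self):
        grid = dd.DepthGrid(n_cols=1, n_rows=1, polygons=[[Polygon()]],
                            bin_area_um2=np.array([[0.0]]))
        filled = dd.bin_densities(grid, point_table(np.empty((0, 2))), 50.0)
        assert np.isnan(filled.density_cells_mm3[0, 0])

    def test_homogeneous_poisson_unbiased(self):
        # density estimator relative bias < 2% on homogeneous input
        from test_synthetic_cortex import one_layer_spec
        spec = one_layer_spec(100_000.0, seed=11, width=2000.0, height=1000.0)
        regions, cells = sc.make_column(spec)
        grid = dd.build_depth_grid(regions)
        filled = dd.bin_densities(grid, dd.filter_in_polygon(cells, regions.s1hl))
        mean_density = np.nanmean(filled.density_cells_mm3)
        assert abs(mean_density / 100_000.0 - 1) < 0.02


class TestDepthProfile:
    def test_single_image_sd_zero_flagged(self, rect_column):
        _, regions, cells = rect_column
        grid = dd.build_depth_grid(regions)
        filled = dd.bin_densities(grid, dd.filter_in_polygon(cells, regions.s1hl))
        prof = dd.depth_profile([filled])
        assert prof.n_images == 1
        np.testing.assert_array_equal(prof.sd_density, 0.0)
        assert len(prof.depth_percent) == 20
        np.testing.assert_allclose(prof.depth_percent[:2], [2.5, 7.5])

    def test_two_image_mean_and_sd(self):
        rows_a = np.full(20, 100_000.0)
        rows_b = np.full(20, 120_000.0)
        prof = dd.depth_profile([rows_a, rows_b])
        np.testing.assert_allclose(prof.mean_density, 110_000.0)
        np.testing.assert_allclose(prof.sd_density, 14_142.135, rtol=1e-4)

    def test_inconsistent_rows_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            dd.depth_profile([np.zeros(20), np.zeros(19)])

    def test_profile_recovers_generating_densities(self):
        # step-like profile whose plateaus match the per-layer intensities
        profiles = []
        spec0 = small_spec(seed=0, width=800.0)
        for seed in range(3):
            spec = small_spec(seed=seed, width=800.0, image_id=f"img_{seed}")
            regions, cells = sc.make_column(spec)
            grid = dd.build_depth_grid(regions)
            filled = dd.bin_densities(
                grid, dd.filter_in_polygon(cells, regions.s1hl))
            profiles.append(filled)
        prof = dd.depth_profile(profiles)
        # depth band fully inside Layer V (depth 783-1300 um of 1917)
        total = spec0.total_height_um
        lo, hi = 783 / total * 100, 1300 / total * 100
        sel = (prof.depth_percent > lo + 3) & (prof.depth_percent < hi - 3)
        lv = 72_005.0
        n_cells = lv * 1e-9 * 50 * 800 * total / 20  # per-bin-row expectation
        se = lv / np.sqrt(n_cells * 3)
        assert abs(prof.mean_density[sel].mean() - lv) < 3 * se
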