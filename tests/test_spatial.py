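import logging

import numpy as np
import pytest

from tidemarsh import slr
from tidemarsh.spatial import (
    Grid,
    GridSpec,
    HabitatClass,
    classify_habitat,
    idw_surface,
    navd_to_mhhw,
    project_grid,
    rasterize_polygons,
    read_ascii_grid,
    summarize_areas,
    vegetation_correction,
)
from tidemarsh.tables import build_response_table, project_elevation


def grid_of(values, cell=5.0, units="m"):
    values = np.asarray(values, dtype=float)
    spec = GridSpec(0.0, values.shape[0] * cell, cell, *values.shape)
    return Grid(values, spec, units)


class TestIdwSurface:
    def test_single_point_gives_constant_surface(self):
        spec = GridSpec(0, 100, 10, 10, 10)
        g = idw_surface(np.array([[55.0, 45.0]]), [3.3], spec)
        assert np.allclose(g.values, 3.3)

    def test_equal_values_normalize_out(self):
        spec = GridSpec(0, 100, 10, 10, 10)
        pts = np.array([[10.0, 90.0], [80.0, 20.0], [50.0, 50.0]])
        g = idw_surface(pts, [7.0, 7.0, 7.0], spec)
        assert np.allclose(g.values, 7.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 200, (10, 2))
        vals = rng.normal(size=10)
        spec = GridSpec(0, 200, 10, 20, 20)
        g = idw_surface(pts, vals, spec)
        X, Y = spec.cell_centers()
        for i in range(0, 20, 3):
            for j in range(0, 20, 3):
                d2 = (X[i, j] - pts[:, 0]) ** 2 + (Y[i, j] - pts[:, 1]) ** 2
                w = d2**-1.0
                expected = (w * vals).sum() / w.sum()
                assert g.values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_coincident_point_is_exact(self):
        spec = GridSpec(0, 100, 10, 10, 10)
        # cell (0,0) center is (5, 95)
        pts = np.array([[5.0, 95.0], [60.0, 30.0]])
        g = idw_surface(pts, [1.0, 2.0], spec)
        assert g.values[0, 0] == 1.0

    def test_empty_point_set_raises(self):
        with pytest.raises(ValueError):
            idw_surface(np.empty((0, 2)), [], GridSpec(0, 10, 1, 10, 10))


class TestNavdToMhhw:
    def test_formula_arithmetic(self):
        elev = grid_of([[2.0]])
        out = navd_to_mhhw(elev, grid_of([[0.1]]), grid_of([[1.9]]))
        assert out.values[0, 0] == pytest.approx(0.2)

    def test_zero_offsets_identity(self):
        elev = grid_of(np.random.default_rng(0).normal(size=(4, 4)))
        z = grid_of(np.zeros((4, 4)))
        assert np.allclose(navd_to_mhhw(elev, z, z).values, elev.values)

    def test_elementwise_oracle_and_nodata(self):
        rng = np.random.default_rng(1)
        a, b, c = (rng.normal(size=(5, 5)) for _ in range(3))
        a[2, 2] = np.nan
        out = navd_to_mhhw(grid_of(a), grid_of(b), grid_of(c))
        assert np.array_equal(out.values, a + b - c, equal_nan=True)
        assert np.isnan(out.values[2, 2])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            navd_to_mhhw(grid_of(np.zeros((4, 4))),
                         grid_of(np.zeros((5, 5))),
                         grid_of(np.zeros((4, 4))))


class TestVegetationCorrection:
    def test_zero_correction_unchanged(self):
        elev = grid_of(np.ones((3, 3)))
        veg = grid_of(np.ones((3, 3)), units="class")
        out = vegetation_correction(elev, veg, {1: 0.0})
        assert np.array_equal(out.values, elev.values)

    def test_class_offset_applied(self):
        elev = grid_of(np.zeros((3, 3)))
        veg_arr = np.zeros((3, 3))
        veg_arr[1, :] = 2  # tule-mat-like class
        out = vegetation_correction(elev, grid_of(veg_arr, units="class"),
                                    {2: -0.3})
        assert np.allclose(out.values[1, :], -0.3)
        assert np.allclose(out.values[0, :], 0.0)

    def test_nodata_and_unmapped_classes_unchanged(self, caplog):
        elev = grid_of(np.zeros((2, 2)))
        veg_arr = np.array([[np.nan, 5.0], [0.0, 0.0]])
        with caplog.at_level(logging.WARNING, "tidemarsh.spatial"):
            out = vegetation_correction(elev, grid_of(veg_arr, units="class"),
                                        {1: -0.1})
        assert np.allclose(out.values, 0.0)
        assert any("no correction factor" in r.message for r in caplog.records)


class TestClassifyHabitat:
    @pytest.mark.parametrize(
        "elev,expected",
        [
            (0.0, HabitatClass.MID_MARSH),
            (-1.0, HabitatClass.MUDFLAT),
            (0.5, HabitatClass.UPLAND),
            (-2.0, HabitatClass.SUBTIDAL),
            (0.25, HabitatClass.HIGH_MARSH),
            (-0.4, HabitatClass.LOW_MARSH),
            (-0.23, HabitatClass.MID_MARSH),  # rounds to -0.2
            (0.14, HabitatClass.MID_MARSH),   # rounds to 0.1
            (-0.55, HabitatClass.MUDFLAT),    # half away from zero: -0.6
        ],
    )
    def test_band_examples(self, elev, expected):
        assert classify_habitat(elev) is expected

    def test_rounded_bands_tile_the_axis(self):
        xs = np.arange(-4.0, 2.0, 0.01)
        cls = classify_habitat(xs)
        assert np.all(cls > 0)
        # class codes are nondecreasing with elevation
        assert np.all(np.diff(cls) >= 0)


@pytest.fixture(scope="module")
def mini_tables(tide, datums, lookup):
    t1 = build_response_table(150.0, 1.0, slr.HIGH, tide,
                              lookup=lookup, datums=datums)
    t2 = build_response_table(250.0, 3.0, slr.HIGH, tide,
                              lookup=lookup, datums=datums)
    return {(150.0, 1.0, "high"): t1, (250.0, 3.0, "high"): t2}


class TestProjectGrid:
    def test_constant_raster_stays_constant(self, mini_tables):
        elev = grid_of(np.full((8, 8), -0.5), units="m MHHW")
        sub = grid_of(np.ones((8, 8)), units="class")
        out = project_grid(elev, sub, {1: (150.0, 1.0, "high")}, 60.0,
                           mini_tables)
        vals = out.values[np.isfinite(out.values)]
        assert np.allclose(vals, vals[0])
        expected = project_elevation(-0.5, mini_tables[(150.0, 1.0, "high")],
                                     60.0)
        assert vals[0] == pytest.approx(expected)

    def test_matches_per_pixel_scalar_oracle(self, mini_tables):
        rng = np.random.default_rng(3)
        elev = grid_of(rng.uniform(-5, 2.5, (12, 12)), units="m MHHW")
        sub_arr = np.ones((12, 12))
        sub_arr[6:, :] = 2
        sub = grid_of(sub_arr, units="class")
        mapping = {1: (150.0, 1.0, "high"), 2: (250.0, 3.0, "high")}
        out = project_grid(elev, sub, mapping, 100.0, mini_tables)
        for i in range(12):
            for j in range(12):
                table = mini_tables[mapping[int(sub_arr[i, j])]]
                expected = project_elevation(elev.values[i, j], table, 100.0)
                assert out.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_deep_subtidal_keeps_pace(self, mini_tables):
        elev = grid_of(np.full((5, 5), -4.6), units="m MHHW")
        sub = grid_of(np.ones((5, 5)), units="class")
        out = project_grid(elev, sub, {1: (150.0, 1.0, "high")}, 100.0,
                           mini_tables)
        assert np.allclose(out.values, -4.6)

    def test_unassigned_pixels_become_nodata(self, mini_tables, caplog):
        elev = grid_of(np.zeros((4, 4)), units="m MHHW")
        sub_arr = np.ones((4, 4))
        sub_arr[0, 0] = np.nan
        with caplog.at_level(logging.WARNING, "tidemarsh.spatial"):
            out = project_grid(elev, grid_of(sub_arr), {1: (150.0, 1.0, "high")},
                               20.0, mini_tables)
        assert np.isnan(out.values[0, 0])
        assert np.isfinite(out.values[1:, :]).all()
        assert any("no subregion" in r.message for r in caplog.records)


class TestSummarizeAreas:
    def make_inputs(self):
        classes = np.full((20, 20), HabitatClass.MID_MARSH, dtype=float)
        sub = np.ones((20, 20))
        zeros = np.zeros((20, 20))
        return (grid_of(classes, units="class"), grid_of(sub),
                grid_of(zeros), grid_of(zeros.copy()))

    def test_400_pixels_at_5m_is_one_hectare(self):
        classes, sub, diked, urban = self.make_inputs()
        df = summarize_areas(classes, sub, diked, urban)
        mid_tidal = df[(df.habitat == "mid_marsh") & (df.land_status == "tidal")]
        assert mid_tidal.area_ha.sum() == pytest.approx(1.0)

    def test_empty_urban_mask_gives_zero_urban_rows(self):
        classes, sub, diked, urban = self.make_inputs()
        df = summarize_areas(classes, sub, diked, urban)
        assert df[df.land_status == "urban"].area_ha.sum() == 0.0

    def test_conservation_and_precedence_on_toy_bay(self, toy_bay):
        classes = toy_bay.truth_mhhw.copy(
            values=classify_habitat(toy_bay.truth_mhhw.values).astype(float),
            units="class",
        )
        sub = toy_bay.truth_mhhw.copy(
            values=np.where(
                np.isfinite(toy_bay.truth_mhhw.values),
                1.0 + (np.arange(200)[None, :] >= 100), np.nan),
        )
        df = summarize_areas(classes, sub, toy_bay.diked, toy_bay.urban)
        cell_ha = 25.0 / 1e4
        total = toy_bay.truth_mhhw.values.size * cell_ha
        assert df.area_ha.sum() == pytest.approx(total)
        # brute-force stratum count
        urban = toy_bay.urban.values > 0
        diked = (toy_bay.diked.values > 0) & ~urban
        expected_diked = diked.sum() * cell_ha
        assert df[df.land_status == "diked"].area_ha.sum() == pytest.approx(
            expected_diked
        )
        # urban wins over diked: no pixel is counted twice
        expected_urban = urban.sum() * cell_ha
        assert df[df.land_status == "urban"].area_ha.sum() == pytest.approx(
            expected_urban
        )


class TestAsciiRoundTrip:
    def test_write_read_preserves_grid(self, tmp_path):
        rng = np.random.default_rng(5)
        g = grid_of(rng.normal(size=(7, 9)).round(4))
        g.values[3, 4] = np.nan
        path = tmp_path / "g.asc"
        g.to_ascii(path)
        back = read_ascii_grid(path)
        assert back.spec == g.spec
        assert np.allclose(back.values, g.values, atol=1e-4, equal_nan=True)


class TestRasterizePolygons:
    def test_cell_center_containment(self):
        spec = GridSpec(0, 100, 10, 10, 10)
        feat = {
            "type": "Feature",
            "geometry": {
                "type": "Polygon",
                "coordinates": [[[0, 0], [50, 0], [50, 100], [0, 100], [0, 0]]],
            },
            "properties": {"id": 4},
        }
        g = rasterize_polygons([feat], spec)
        assert np.all(g.values[:, :5] == 4)
        assert np.all(np.isnan(g.values[:, 5:]))
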