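import numpy as np
import pytest

from conftest import make_test_cube
from paleocvd.extraction import (
    ExtractionError,
    buffered_value,
    extract_mid_value,
    extract_occupation_series,
    extract_site_series,
    load_cube,
    locate_cell,
    nearest_land,
    snap_ka,
)
from paleocvd.occupations import Occupation, site_spans


def occ(lo, hi, lon=12.0, lat=2.0):
    return Occupation(
        site_id="S1", layer_id="L1", region="EAST", lon=lon, lat=lat,
        age_min=lo, age_max=hi, age_mid=(lo + hi) / 2,
    )


class TestSnap:
    @pytest.mark.parametrize(
        "age,expected",
        [(50.0, 50), (50.4, 50), (52.6, 53), (51.5, 52), (50.5, 51)],
    )
    def test_nearest_with_older_ties(self, age, expected):
        assert snap_ka(age) == expected


class TestLocateCell:
    def test_cell_center(self, constant_cube):
        # centers at lon 10..14, lat 0..4, res 1
        assert locate_cell(constant_cube, 12.0, 3.0) == (3, 2)

    def test_edge_goes_to_larger_index(self, constant_cube):
        # shared edge between cols 1 and 2 is at lon 11.5
        assert locate_cell(constant_cube, 11.5, 0.0) == (0, 2)

    def test_outside_extent(self, constant_cube):
        with pytest.raises(ExtractionError):
            locate_cell(constant_cube, 20.0, 0.0)

    def test_descending_latitude(self):
        vals = np.zeros((3, 4, 4))
        cube = make_test_cube({"v": vals}, np.ones((4, 4), bool),
                              lat_descending=True)
        row, col = locate_cell(cube, 10.0, 3.0)
        assert cube.lat_axis[row] == 3.0


class TestNearestLand:
    def test_identity_on_land(self, constant_cube):
        assert nearest_land(constant_cube, 2, 2) == (2, 2)

    def test_single_neighbor(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 2] = True
        cube = make_test_cube({"v": np.zeros((2, 3, 3))}, mask)
        assert nearest_land(cube, 1, 1) == (1, 2)

    def test_tie_break_smaller_row_then_col(self):
        # land at (0, 1) and (2, 1): both 1 cell from sea at (1, 1) and,
        # on a meridian, equidistant great-circle; tie -> smaller row
        mask = np.zeros((3, 3), bool)
        mask[0, 1] = mask[2, 1] = True
        cube = make_test_cube({"v": np.zeros((2, 3, 3))}, mask, lat0=-1.0)
        assert nearest_land(cube, 1, 1) == (0, 1)

    def test_all_sea_is_error(self):
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = True
        cube = make_test_cube({"v": np.zeros((2, 2, 2))}, mask)
        cube.land_mask[:] = False
        with pytest.raises(ExtractionError):
            nearest_land(cube, 0, 0)


class TestBufferedValue:
    def test_constant_field(self, constant_cube):
        assert buffered_value(constant_cube, "v", 2, 2, 10) == pytest.approx(7.0)

    def test_focal_plus_single_land_neighbor(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = mask[1, 2] = True
        vals = np.zeros((2, 3, 3))
        vals[:, 1, 1] = 10.0
        vals[:, 1, 2] = 20.0
        cube = make_test_cube({"v": vals}, mask)
        assert buffered_value(cube, "v", 1, 1, 0) == pytest.approx(15.0)

    def test_corner_cell(self):
        # corner (0,0): in-grid neighborhood is 4 cells; (1,1) is sea
        mask = np.ones((3, 3), bool)
        mask[1, 1] = False
        vals = np.zeros((1, 3, 3))
        vals[0] = [[1.0, 2.0, 9.0], [3.0, 9.0, 9.0], [9.0, 9.0, 9.0]]
        cube = make_test_cube({"v": vals}, mask)
        assert buffered_value(cube, "v", 0, 0, 0) == pytest.approx(2.0)

    def test_sea_focal_rejected(self):
        mask = np.ones((2, 2), bool)
        mask[0, 0] = False
        cube = make_test_cube({"v": np.zeros((1, 2, 2))}, mask)
        with pytest.raises(ExtractionError):
            buffered_value(cube, "v", 0, 0, 0)


class TestSeries:
    def test_inclusive_slice_count(self, constant_cube):
        s = extract_occupation_series(constant_cube, "v", occ(50, 52))
        assert len(s) == 3
        assert (s.t_start, s.t_end) == (50, 52)

    def test_snapping_both_ends(self, constant_cube):
        s = extract_occupation_series(constant_cube, "v", occ(50.4, 52.6))
        assert (s.t_start, s.t_end) == (50, 53)
        assert len(s) == 4

    def test_constant_cube_constant_series(self, constant_cube):
        s = extract_occupation_series(constant_cube, "v", occ(10, 30))
        np.testing.assert_allclose(s.values, 7.0)

    def test_no_overlap_is_error(self, constant_cube):
        with pytest.raises(ExtractionError):
            extract_occupation_series(constant_cube, "v", occ(200, 300))

    def test_oldest_first_orientation(self):
        vals = np.arange(100, dtype=float)[:, None, None] * np.ones((1, 2, 2))
        cube = make_test_cube({"v": vals}, np.ones((2, 2), bool))
        s = extract_occupation_series(cube, "v", occ(10, 12, lon=10.0, lat=0.0))
        np.testing.assert_allclose(s.values, [12.0, 11.0, 10.0])

    def test_latitude_orientation_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(20, 4, 4))
        mask = rng.random((4, 4)) > 0.3
        mask[1, 1] = True
        up = make_test_cube({"v": vals}, mask)
        down = make_test_cube({"v": vals}, mask, lat_descending=True)
        o = occ(5, 12, lon=11.0, lat=1.0)
        np.testing.assert_allclose(
            extract_occupation_series(up, "v", o).values,
            extract_occupation_series(down, "v", o).values,
        )


class TestMidValue:
    def test_mid_slice(self, constant_cube):
        vals = np.arange(100, dtype=float)[:, None, None] * np.ones((1, 3, 3))
        cube = make_test_cube({"v": vals}, np.ones((3, 3), bool))
        assert extract_mid_value(cube, "v", occ(50, 52, lon=11, lat=1)) == 51.0

    def test_tie_goes_older(self):
        vals = np.arange(100, dtype=float)[:, None, None] * np.ones((1, 3, 3))
        cube = make_test_cube({"v": vals}, np.ones((3, 3), bool))
        assert extract_mid_value(cube, "v", occ(50, 53, lon=11, lat=1)) == 52.0

    def test_constant_value(self, constant_cube):
        assert extract_mid_value(constant_cube, "v", occ(50, 52)) == 7.0

    def test_matches_series_element(self, constant_cube):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(100, 5, 5))
        cube = make_test_cube({"v": vals}, np.ones((5, 5), bool))
        o = occ(40, 60)
        s = extract_occupation_series(cube, "v", o)
        mid = extract_mid_value(cube, "v", o)
        idx = s.t_end - snap_ka(o.age_mid)  # series is oldest-first
        assert mid == pytest.approx(s.values[idx])


def test_site_series(constant_cube):
    occs = [occ(10, 30), occ(50, 80)]
    (site,) = site_spans(occs)
    s = extract_site_series(constant_cube, "v", site)
    assert (s.t_start, s.t_end) == (10, 80)
    assert len(s) == 71


def test_netcdf_round_trip(tmp_path, small_sim):
    _, cube, _, _ = small_sim
    path = tmp_path / "cube.nc"
    cube.to_netcdf(path)
    back = load_cube(path)
    np.testing.assert_allclose(back.lon_axis, cube.lon_axis)
    np.testing.assert_array_equal(back.land_mask, cube.land_mask)
    for name, arr in cube.variables.items():
        np.testing.assert_allclose(back.variables[name], arr, equal_nan=True)


def test_time_step_validated():
    from paleocvd.extraction import ClimateCube

    with pytest.raises(ValueError):
        ClimateCube(
            lon_axis=np.array([0.0, 1.0]),
            lat_axis=np.array([0.0, 1.0]),
            time_axis=np.array([0, 2, 4]),
            variables={"v": np.zeros((3, 2, 2))},
            land_mask=np.ones((2, 2), bool),
        )
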