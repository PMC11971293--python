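"""Space-time extraction of climate series from gridded time-cubes.

A :class:`ClimateCube` holds one or more variables on a regular
lon/lat grid at 1 ka time steps, with a boolean land mask. Extraction
at an occupation or site applies, in order:

1. cell location (half-open cell bounds),
2. relocation to the nearest land cell (great-circle distance between
   cell centers) if the point falls on a sea cell,
3. neighborhood buffering: the value at a slice is the mean over the
   focal cell and its 8 in-grid land neighbors ("directions = 8"),
4. snapping of ka ages to the integer time axis (nearest slice;
   midpoint ties toward the older slice).

Series are oriented oldest -> youngest internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .occupations import Occupation, Site

__all__ = [
    "ClimateCube",
    "SeriesSample",
    "locate_cell",
    "nearest_land",
    "buffered_value",
    "buffered_series",
    "extract_occupation_series",
    "extract_mid_value",
    "extract_site_series",
    "snap_ka",
    "load_cube",
    "pastclim_adapter",
]

_EARTH_RADIUS_KM = 6371.0


class ExtractionError(ValueError):
    pass


def snap_ka(age: float) -> int:
    """Snap an age in ka to the nearest integer slice, ties toward older
    (i.e. larger ka BP)."""
    return int(np.floor(age + 0.5))


@dataclass
class ClimateCube:
    """Gridded multi-variable climate time series at 1 ka steps.

    ``lon_axis`` must be ascending; ``lat_axis`` may be ascending or
    descending (orientation is preserved). ``time_axis`` is integer ka
    BP with step exactly 1. Variable arrays are (time, lat, lon); sea
    cells hold NaN.
    """

    lon_axis: np.ndarray
    lat_axis: np.ndarray
    time_axis: np.ndarray
    variables: dict
    land_mask: np.ndarray
    resolution: float = field(default=None)  # degrees, inferred if None

    def __post_init__(self):
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.time_axis = np.asarray(self.time_axis)
        if np.any(np.diff(self.time_axis) != 1):
            raise ValueError("time axis must step by exactly 1 ka")
        if self.lon_axis.size > 1 and np.any(np.diff(self.lon_axis) <= 0):
            raise ValueError("lon axis must be ascending")
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        shape = (self.time_axis.size, self.lat_axis.size, self.lon_axis.size)
        for name, arr in self.variables.items():
            if arr.shape != shape:
                raise ValueError(
                    f"variable {name!r} has shape {arr.shape}, expected {shape}"
                )
        if self.land_mask.shape != shape[1:]:
            raise ValueError("land mask must be (lat, lon)")
        if self.resolution is None:
            axis = self.lon_axis if self.lon_axis.size > 1 else self.lat_axis
            self.resolution = float(np.abs(np.diff(axis)).mean())

    @property
    def t_min(self) -> int:
        return int(self.time_axis.min())

    @property
    def t_max(self) -> int:
        return int(self.time_axis.max())

    def time_index(self, t: int) -> int:
        idx = int(t) - int(self.time_axis[0])
        if not 0 <= idx < self.time_axis.size:
            raise ExtractionError(
                f"slice {t} ka outside cube time axis "
                f"[{self.t_min}, {self.t_max}]"
            )
        return idx

    def to_dataset(self) -> xr.Dataset:
        coords = {
            "time": ("time", self.time_axis, {"units": "ka BP"}),
            "lat": ("lat", self.lat_axis, {"units": "degrees_north"}),
            "lon": ("lon", self.lon_axis, {"units": "degrees_east"}),
        }
        data = {
            name: (("time", "lat", "lon"), arr)
            for name, arr in self.variables.items()
        }
        data["mask"] = (("lat", "lon"), self.land_mask.astype(np.int8))
        ds = xr.Dataset(data, coords=coords)
        ds.attrs["resolution_deg"] = self.resolution
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "ClimateCube":
        mask = ds["mask"].values.astype(bool)
        variables = {
            str(name): ds[name].values.astype(float)
            for name in ds.data_vars
            if name != "mask"
        }
        return cls(
            lon_axis=ds["lon"].values,
            lat_axis=ds["lat"].values,
            time_axis=ds["time"].values.astype(int),
            variables=variables,
            land_mask=mask,
            resolution=float(ds.attrs.get("resolution_deg"))
            if "resolution_deg" in ds.attrs
            else None,
        )


def load_cube(path) -> ClimateCube:
    """Read a cube from a netCDF file written by :meth:`ClimateCube.to_netcdf`."""
    with xr.open_dataset(path, decode_times=False) as ds:
        return ClimateCube.from_dataset(ds.load())


def pastclim_adapter(path, variable_map=None) -> ClimateCube:  # pragma: no cover
    """Adapter hook for external reconstruction exports.

    Intended signature for converting a pastclim/HadCM3-style netCDF
    export (arbitrary variable naming, time in years BP) into this
    package's cube layout. Not implemented: the external reconstruction
    is not distributed with the package.
    """
    raise NotImplementedError(
        "conversion of external reconstruction exports is an adapter "
        "point; supply a cube in the documented layout instead"
    )


@dataclass(frozen=True)
class SeriesSample:
    entity_id: str
    variable: str
    t_start: int  # youngest slice, ka BP
    t_end: int  # oldest slice, ka BP
    values: np.ndarray  # oriented oldest -> youngest
    orientation: str = "oldest_to_youngest"

    def __len__(self):
        return self.values.size


def _axis_cell(axis: np.ndarray, value: float, res: float, name: str) -> int:
    """Index of the cell containing ``value`` on a center axis, half-open
    bounds: an edge point belongs to the cell with the larger index."""
    ascending = axis.size < 2 or axis[1] > axis[0]
    a = axis if ascending else axis[::-1]
    lo_edge = a[0] - res / 2.0
    hi_edge = a[-1] + res / 2.0
    if not (lo_edge <= value <= hi_edge):
        raise ExtractionError(
            f"{name}={value} outside cube extent [{lo_edge}, {hi_edge}]"
        )
    idx = int(np.floor((value - lo_edge) / res))
    idx = min(idx, a.size - 1)  # point exactly on the top edge
    return idx if ascending else a.size - 1 - idx


def locate_cell(cube: ClimateCube, lon: float, lat: float):
    """Return (row, col) of the grid cell containing the point."""
    col = _axis_cell(cube.lon_axis, lon, cube.resolution, "lon")
    row = _axis_cell(cube.lat_axis, lat, cube.resolution, "lat")
    return row, col


def _great_circle_km(lat1, lon1, lat2, lon2):
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlat = p2 - p1
    dlon = np.radians(lon2 - lon1)
    h = np.sin(dlat / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def nearest_land(cube: ClimateCube, row: int, col: int):
    """Relocate a sea cell to the nearest land cell (great-circle
    distance between cell centers; ties broken by smaller row then
    smaller col). Land cells are returned unchanged."""
    if cube.land_mask[row, col]:
        return row, col
    rows, cols = np.nonzero(cube.land_mask)
    if rows.size == 0:
        raise ExtractionError("cube has no land cells")
    d = _great_circle_km(
        cube.lat_axis[row],
        cube.lon_axis[col],
        cube.lat_axis[rows],
        cube.lon_axis[cols],
    )
    order = np.lexsort((cols, rows, d))  # distance, then row, then col
    best = order[0]
    return int(rows[best]), int(cols[best])


def _buffer_indices(cube: ClimateCube, row: int, col: int):
    """Land cells in the 3x3 neighborhood (focal included), in-grid only."""
    nrow, ncol = cube.land_mask.shape
    rr, cc = [], []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            r, c = row + dr, col + dc
            if 0 <= r < nrow and 0 <= c < ncol and cube.land_mask[r, c]:
                rr.append(r)
                cc.append(c)
    return np.array(rr), np.array(cc)


def buffered_value(cube: ClimateCube, variable: str, row: int, col: int, t: int):
    """Mean of a variable over the focal land cell and its in-grid land
    neighbors at one slice."""
    if not cube.land_mask[row, col]:
        raise ExtractionError(
            f"cell ({row}, {col}) is sea; relocate with nearest_land first"
        )
    ti = cube.time_index(t)
    rr, cc = _buffer_indices(cube, row, col)
    return float(cube.variables[variable][ti, rr, cc].mean())


def buffered_series(cube: ClimateCube, variable: str, row: int, col: int):
    """Buffered values at *every* slice, aligned with ``cube.time_axis``;
    used to precompute extraction once before resampling."""
    if not cube.land_mask[row, col]:
        raise ExtractionError(
            f"cell ({row}, {col}) is sea; relocate with nearest_land first"
        )
    rr, cc = _buffer_indices(cube, row, col)
    return cube.variables[variable][:, rr, cc].mean(axis=1)


def _land_cell_for(cube: ClimateCube, lon: float, lat: float):
    row, col = locate_cell(cube, lon, lat)
    return nearest_land(cube, row, col)


def _slice_range(cube: ClimateCube, lo_ka: float, hi_ka: float, what: str):
    t_lo, t_hi = snap_ka(lo_ka), snap_ka(hi_ka)
    if t_hi < cube.t_min or t_lo > cube.t_max:
        raise ExtractionError(
            f"{what}: range [{lo_ka}, {hi_ka}] ka does not overlap cube "
            f"time axis [{cube.t_min}, {cube.t_max}]"
        )
    return max(t_lo, cube.t_min), min(t_hi, cube.t_max)


def _extract(cube, variable, entity_id, lon, lat, lo_ka, hi_ka) -> SeriesSample:
    row, col = _land_cell_for(cube, lon, lat)
    t_lo, t_hi = _slice_range(cube, lo_ka, hi_ka, entity_id)
    # oldest -> youngest means descending ka
    values = np.array(
        [buffered_value(cube, variable, row, col, t) for t in range(t_hi, t_lo - 1, -1)]
    )
    return SeriesSample(
        entity_id=entity_id, variable=variable, t_start=t_lo, t_end=t_hi,
        values=values,
    )


def extract_occupation_series(
    cube: ClimateCube, variable: str, occ: Occupation
) -> SeriesSample:
    """Buffered series over an occupation's inclusive snapped date range."""
    return _extract(
        cube, variable, f"{occ.site_id}/{occ.layer_id}", occ.lon, occ.lat,
        occ.age_min, occ.age_max,
    )


def extract_mid_value(cube: ClimateCube, variable: str, occ: Occupation) -> float:
    """Buffered value at the slice nearest the occupation mid-age
    (ties toward the older slice)."""
    row, col = _land_cell_for(cube, occ.lon, occ.lat)
    t = snap_ka(occ.age_mid)
    t = min(max(t, cube.t_min), cube.t_max)
    return buffered_value(cube, variable, row, col, t)


def extract_site_series(cube: ClimateCube, variable: str, site: Site) -> SeriesSample:
    """Buffered series over a site's combined occupation span."""
    return _extract(
        cube, variable, site.site_id, site.lon, site.lat,
        site.span_min, site.span_max,
    )


def series_to_frame(samples) -> pd.DataFrame:
    """Long-format table ``entity_id, variable, t_ka, value``."""
    rows = []
    for s in samples:
        for t, v in zip(range(s.t_end, s.t_start - 1, -1), s.values):
            rows.append(
                {"entity_id": s.entity_id, "variable": s.variable,
                 "t_ka": t, "value": v}
            )
    return pd.DataFrame(rows)
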