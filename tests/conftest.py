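import io

import numpy as np
import pytest

from paleocvd.extraction import ClimateCube
from paleocvd.occupations import read_occupation_table
from paleocvd.synthetic import GeneratorConfig, make_climate_cube, make_occupations


def make_test_cube(values_by_var, land_mask, t0=0, lon0=10.0, lat0=0.0, res=1.0,
                   lat_descending=False):
    """Small hand-built cube from explicit (time, lat, lon) arrays."""
    some = next(iter(values_by_var.values()))
    nt, nlat, nlon = some.shape
    lon = lon0 + res * np.arange(nlon)
    lat = lat0 + res * np.arange(nlat)
    variables = {k: np.asarray(v, dtype=float).copy() for k, v in values_by_var.items()}
    mask = np.asarray(land_mask, dtype=bool)
    for arr in variables.values():
        arr[:, ~mask] = np.nan
    if lat_descending:
        lat = lat[::-1]
        mask = mask[::-1]
        variables = {k: v[:, ::-1] for k, v in variables.items()}
    return ClimateCube(
        lon_axis=lon,
        lat_axis=lat,
        time_axis=np.arange(t0, t0 + nt),
        variables=variables,
        land_mask=mask,
        resolution=res,
    )


@pytest.fixture
def constant_cube():
    """5x5 all-land cube, variable 'v' constant at 7.0, times 0..99."""
    vals = np.full((100, 5, 5), 7.0)
    return make_test_cube({"v": vals}, np.ones((5, 5), bool))


@pytest.fixture(scope="session")
def small_sim():
    """Session-scoped scaled-down synthetic run (cube, truth, occupations)."""
    cfg = GeneratorConfig(
        seed=42,
        resolution=5.0,
        t_span_ka=120,
        n_sites={"EAST": 6, "NORTHWEST": 5},
        occupations_per_site=2,
        long_span_fraction=0.9,
        f_noise_by_region={"EAST": 0.8, "NORTHWEST": 0.2},
    )
    cube, truth = make_climate_cube(cfg)
    occ_df = make_occupations(cfg, cube)
    buf = io.StringIO()
    occ_df.to_csv(buf, index=False)
    buf.seek(0)
    occs = read_occupation_table(buf)
    return cfg, cube, truth, occs
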