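"""Synthetic climate cubes and occupation tables with known ground truth.

The generator emits a 1 ka-resolution multi-variable cube whose land
cells carry, per driver series, a deterministic signal (a ~100 ka
"change" sinusoid plus a 23 ka precession sinusoid whose phase flips by
pi across the equator) and an unpredictable noise term (white or AR(1))
scaled so that a *known* fraction ``f_noise`` of the series variance is
noise. Monthly temperature/precipitation stacks are constructed so the
emitted bio variables derive exactly from them via :mod:`.bioclim`.

Because the noise fraction per cell is recorded in
:class:`SyntheticTruth`, the change/variability decomposition can be
validated end-to-end: its percent-variability estimate should track
``100 * f_noise`` for white noise.

Occupation tables are placed on land inside the region boxes, with
engineered exact duplicates (to exercise deduplication) and a stated
fraction of sites whose combined span covers a full precession cycle
(to exercise site-level eligibility).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bioclim
from .extraction import ClimateCube
from .regional_stats import EAST_BOX, NORTHWEST_BOX

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "make_climate_cube",
    "make_occupations",
    "PRECESSION_PERIOD_KA",
    "LONG_CYCLE_PERIOD_KA",
]

PRECESSION_PERIOD_KA = 23.0
LONG_CYCLE_PERIOD_KA = 100.0

#: Deterministic monthly shape (full cosine cycle; sums to zero).
_MONTH_PHASE = np.cos(2.0 * np.pi * (np.arange(12) + 0.5) / 12.0)

#: Driver series and the (offset, scale) mapping them to physical units.
_DRIVERS = {
    "tmean": (18.0, 4.0),   # degC
    "ptot": (1100.0, 180.0),  # mm/yr
    "npp": (1400.0, 250.0),  # gC/m2/yr additive noise scale
}


@dataclass
class GeneratorConfig:
    lon_min: float = -15.0
    lon_max: float = 55.0
    lat_min: float = -10.0
    lat_max: float = 40.0
    resolution: float = 2.5
    t_span_ka: int = 300
    sea_fraction: float = 0.15
    noise_model: str = "white"  # or "ar1"
    ar1_rho: float = 0.6
    f_noise_default: float = 0.5
    #: region name -> noise fraction, applied to cells in that region's box
    f_noise_by_region: dict = field(default_factory=dict)
    region_boxes: dict = field(
        default_factory=lambda: {"EAST": EAST_BOX, "NORTHWEST": NORTHWEST_BOX}
    )
    emit_monthly: bool = True
    n_sites: dict = field(
        default_factory=lambda: {"EAST": 37, "NORTHWEST": 21}
    )
    occupations_per_site: int = 3
    duplicate_fraction: float = 0.1
    long_span_fraction: float = 0.5
    seed: int = 0

    def validate(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.t_span_ka < 30:
            raise ValueError("t_span_ka must be >= 30")
        if not 0.0 <= self.sea_fraction < 1.0:
            raise ValueError("sea_fraction must be in [0, 1)")
        if self.noise_model not in ("white", "ar1"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if not 0.0 <= self.f_noise_default <= 1.0:
            raise ValueError("f_noise_default must be in [0, 1]")
        for v in self.f_noise_by_region.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("f_noise values must be in [0, 1]")
        if self.occupations_per_site < 1 or any(
            n < 1 for n in self.n_sites.values()
        ):
            raise ValueError("counts must be >= 1")
        return self


@dataclass
class SyntheticTruth:
    seed: int
    f_noise: np.ndarray  # (lat, lon), NaN on sea
    precession_amp: np.ndarray  # (lat, lon) in driver (z) units
    precession_phase: np.ndarray  # (lat, lon), radians
    long_amp: np.ndarray  # (lat, lon)
    lat_axis: np.ndarray
    lon_axis: np.ndarray
    t_axis: np.ndarray
    region_f_noise: dict = field(default_factory=dict)

    def precession_component(self, row: int, col: int) -> np.ndarray:
        """Reconstruct the (unnormalized) precession signal of one cell."""
        return self.precession_amp[row, col] * np.sin(
            2.0 * np.pi * self.t_axis / PRECESSION_PERIOD_KA
            + self.precession_phase[row, col]
        )


def _axis(lo: float, hi: float, res: float) -> np.ndarray:
    n = max(1, int(round((hi - lo) / res)))
    return lo + res * (np.arange(n) + 0.5)


def _orthogonal_noise(rng, n: int, model: str, rho: float, signal: np.ndarray):
    """Unit-variance noise with the mean and signal direction projected
    out, so realized variance fractions are exact."""
    e = rng.standard_normal(n)
    if model == "ar1":
        for i in range(1, n):
            e[i] = rho * e[i - 1] + np.sqrt(1 - rho * rho) * e[i]
    e = e - e.mean()
    s = signal - signal.mean()
    denom = float(s @ s)
    if denom > 0:
        e = e - (e @ s) / denom * s
    sd = e.std()
    if sd < 1e-12:
        raise ValueError("degenerate noise draw; series too short")
    return e / sd


def _cell_series(rng, t, amp_prec, phase_prec, amp_long, phase_long, f_noise,
                 model, rho):
    """Unit-variance driver series with exact noise-variance fraction."""
    signal = amp_long * np.sin(
        2.0 * np.pi * t / LONG_CYCLE_PERIOD_KA + phase_long
    ) + amp_prec * np.sin(2.0 * np.pi * t / PRECESSION_PERIOD_KA + phase_prec)
    s = signal - signal.mean()
    s_sd = s.std()
    if f_noise >= 1.0:
        return _orthogonal_noise(rng, t.size, model, rho, s), signal
    s_unit = s / s_sd
    if f_noise <= 0.0:
        return s_unit, signal
    e = _orthogonal_noise(rng, t.size, model, rho, s)
    return np.sqrt(1.0 - f_noise) * s_unit + np.sqrt(f_noise) * e, signal


def make_climate_cube(config: GeneratorConfig):
    """Generate a :class:`ClimateCube` plus its :class:`SyntheticTruth`.

    Emitted variables: ``bio01, bio04, bio12, bio15, npp`` and (if
    ``emit_monthly``) consistent ``temp_monthly``/``prec_monthly``
    stacks with a ``month`` dimension stored alongside the cube.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lon = _axis(config.lon_min, config.lon_max, config.resolution)
    lat = _axis(config.lat_min, config.lat_max, config.resolution)
    t = np.arange(config.t_span_ka + 1)
    nt, nlat, nlon = t.size, lat.size, lon.size

    land = rng.random((nlat, nlon)) >= config.sea_fraction
    if not land.any():
        land[nlat // 2, nlon // 2] = True

    f_noise = np.full((nlat, nlon), np.nan)
    f_noise[land] = config.f_noise_default
    for region, value in config.f_noise_by_region.items():
        lo_lon, hi_lon, lo_lat, hi_lat = config.region_boxes[region]
        box = (
            (lon[None, :] >= lo_lon) & (lon[None, :] <= hi_lon)
            & (lat[:, None] >= lo_lat) & (lat[:, None] <= hi_lat)
        )
        f_noise[box & land] = value

    prec_amp = np.full((nlat, nlon), np.nan)
    prec_phase = np.full((nlat, nlon), np.nan)
    long_amp = np.full((nlat, nlon), np.nan)

    tmean = np.full((nt, nlat, nlon), np.nan)
    ptot = np.full((nt, nlat, nlon), np.nan)
    npp = np.full((nt, nlat, nlon), np.nan)
    tamp = np.full((nt, nlat, nlon), np.nan)
    pconc = np.full((nt, nlat, nlon), np.nan)

    month_sd = _MONTH_PHASE.std(ddof=1)

    for row in range(nlat):
        hemisphere_phase = 0.0 if lat[row] >= 0 else np.pi
        for col in range(nlon):
            if not land[row, col]:
                continue
            a_prec = rng.uniform(0.6, 1.0)
            a_long = rng.uniform(0.6, 1.0)
            phi_long = rng.uniform(0, 2 * np.pi)
            prec_amp[row, col] = a_prec
            prec_phase[row, col] = hemisphere_phase
            long_amp[row, col] = a_long
            f = f_noise[row, col]
            args = (t, a_prec, hemisphere_phase, a_long, phi_long, f,
                    config.noise_model, config.ar1_rho)

            z_t, _ = _cell_series(rng, *args)
            z_p, _ = _cell_series(rng, *args)
            z_n, npp_signal = _cell_series(rng, *args)

            off_t, sc_t = _DRIVERS["tmean"]
            off_p, sc_p = _DRIVERS["ptot"]
            tmean[:, row, col] = off_t + sc_t * z_t
            ptot[:, row, col] = np.maximum(0.0, off_p + sc_p * z_p)
            # NPP: Miami-like saturating response to the deterministic
            # precipitation signal, plus noise at the cell's fraction
            s_unit = (npp_signal - npp_signal.mean()) / max(
                npp_signal.std(), 1e-12
            )
            npp_det = 3000.0 * (1.0 - np.exp(-0.000664 * (off_p + sc_p * s_unit)))
            if f <= 0:
                npp[:, row, col] = npp_det
            elif f >= 1:
                e = _orthogonal_noise(
                    rng, nt, config.noise_model, config.ar1_rho, npp_det
                )
                npp[:, row, col] = npp_det.mean() + e * _DRIVERS["npp"][1]
            else:
                e = _orthogonal_noise(
                    rng, nt, config.noise_model, config.ar1_rho, npp_det
                )
                npp[:, row, col] = npp_det + e * npp_det.std() * np.sqrt(
                    f / (1.0 - f)
                )

            # seasonal-shape drivers (small precession modulation + noise)
            z_a, _ = _cell_series(rng, *args)
            z_c, _ = _cell_series(rng, *args)
            tamp[:, row, col] = 6.0 + 1.5 * z_a
            pconc[:, row, col] = np.clip(0.5 + 0.15 * z_c, 0.0, 0.95)

    variables = {}
    if config.emit_monthly:
        # (time, lat, lon, month) during construction
        temp_m = tmean[..., None] + tamp[..., None] * _MONTH_PHASE
        prec_m = ptot[..., None] / 12.0 * (
            1.0 + pconc[..., None] * _MONTH_PHASE
        )
        bio = bioclim.monthly_to_bio(temp_m, prec_m)
        variables.update(bio)
        variables["temp_monthly"] = temp_m
        variables["prec_monthly"] = prec_m
    else:
        variables["bio01"] = tmean
        variables["bio04"] = 100.0 * tamp * month_sd
        variables["bio12"] = ptot
        variables["bio15"] = 100.0 * pconc * month_sd
    variables["npp"] = npp

    monthly = {
        k: variables.pop(k)
        for k in ("temp_monthly", "prec_monthly")
        if k in variables
    }
    cube = ClimateCube(
        lon_axis=lon,
        lat_axis=lat,
        time_axis=t,
        variables=variables,
        land_mask=land,
        resolution=config.resolution,
    )
    cube.monthly = monthly  # kept in memory; not part of netCDF layout
    truth = SyntheticTruth(
        seed=config.seed,
        f_noise=f_noise,
        precession_amp=prec_amp,
        precession_phase=prec_phase,
        long_amp=long_amp,
        lat_axis=lat,
        lon_axis=lon,
        t_axis=t,
        region_f_noise={
            region: config.f_noise_by_region.get(
                region, config.f_noise_default
            )
            for region in config.region_boxes
        },
    )
    return cube, truth


def _land_cells_in_box(cube: ClimateCube, box):
    lo_lon, hi_lon, lo_lat, hi_lat = box
    in_box = (
        (cube.lon_axis[None, :] >= lo_lon) & (cube.lon_axis[None, :] <= hi_lon)
        & (cube.lat_axis[:, None] >= lo_lat) & (cube.lat_axis[:, None] <= hi_lat)
    )
    return np.nonzero(in_box & cube.land_mask)


def make_occupations(config: GeneratorConfig, cube: ClimateCube) -> pd.DataFrame:
    """Long-format occupation table (one row per date) placed on land.

    Sites are drawn without replacement from land cells inside each
    region box; a ``long_span_fraction`` of sites get occupations whose
    combined span is >= 23 ka; ``duplicate_fraction`` of layers are
    emitted twice under a new layer id (exact duplicates).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    t_hi = config.t_span_ka
    rows = []
    for region in sorted(config.region_boxes):
        box = config.region_boxes[region]
        rr, cc = _land_cells_in_box(cube, box)
        n_sites = config.n_sites.get(region, 0)
        if rr.size < n_sites:
            raise ValueError(
                f"only {rr.size} land cells in {region} box; "
                f"need {n_sites} sites"
            )
        chosen = rng.choice(rr.size, size=n_sites, replace=False)
        for s_idx, cell in enumerate(chosen):
            site_id = f"{region[:2]}-{s_idx + 1:03d}"
            lon = float(cube.lon_axis[cc[cell]])
            lat = float(cube.lat_axis[rr[cell]])
            long_span = rng.random() < config.long_span_fraction
            base_age = rng.uniform(40.0, t_hi - 45.0)
            layer_rows = []
            for k in range(config.occupations_per_site):
                if long_span and k == config.occupations_per_site - 1:
                    age = base_age + 30.0  # forces combined span >= 23 ka
                else:
                    age = base_age + rng.uniform(-4.0, 4.0)
                sd = rng.uniform(1.0, 4.0)
                layer_id = f"L{k + 1}"
                n_dates = rng.integers(1, 4)
                for d in range(n_dates):
                    layer_rows.append(
                        {
                            "site_id": site_id,
                            "layer_id": layer_id,
                            "region": region,
                            "lon": lon,
                            "lat": lat,
                            "age": round(age + rng.uniform(-1.0, 1.0), 3),
                            "age_sd": round(sd, 3),
                        }
                    )
            rows.extend(layer_rows)
            if rng.random() < config.duplicate_fraction:
                # exact duplicate of the first layer under a fresh id
                first_layer = layer_rows[0]["layer_id"]
                for r in [
                    dict(r) for r in layer_rows if r["layer_id"] == first_layer
                ]:
                    r["layer_id"] = f"{first_layer}-dup"
                    rows.append(r)
    return pd.DataFrame(rows)
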