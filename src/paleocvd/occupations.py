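"""Occupation inventories: reading, validation, date ranges, dedup, site spans.

Ages are in ka BP (thousands of years before present), positive and
increasing into the past. A dated layer either carries one or more
radiometric dates with standard deviations, or precomputed min/max
bounds. The date-range protocol takes the oldest date plus ``k`` sd as
the maximum age and the youngest date minus ``k`` sd as the minimum age
(clipped at 0), with ``k = 1`` by default; the mid-age is the arithmetic
midpoint and is the value used for point-in-time statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DatedLayer",
    "Occupation",
    "Site",
    "derive_date_range",
    "dedupe_occupations",
    "site_spans",
    "read_occupation_table",
    "occupations_to_frame",
    "sites_to_frame",
    "PRECESSION_SPAN_KA",
]

#: Minimum combined span (ka) for a series to cover one precession cycle.
PRECESSION_SPAN_KA = 23.0

#: Coordinate rounding (decimal degrees) used for duplicate detection.
_COORD_DECIMALS = 4

REGIONS = ("EAST", "NORTHWEST")


class ValidationError(ValueError):
    """Raised when an input table or record violates the schema."""


@dataclass(frozen=True)
class DatedLayer:
    site_id: str
    layer_id: str
    region: str
    lon: float
    lat: float
    #: list of (age ka BP, sd ka); empty if precomputed bounds are given
    dates: tuple = ()
    age_min: float | None = None
    age_max: float | None = None

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValidationError(
                f"region must be one of {REGIONS}, got {self.region!r}"
            )
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"lon {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"lat {self.lat} outside [-90, 90]")
        for age, sd in self.dates:
            if sd < 0:
                raise ValidationError(f"negative sd {sd} for {self.site_id}")
        if self.age_min is not None and self.age_max is not None:
            if self.age_min > self.age_max:
                raise ValidationError(
                    f"age_min {self.age_min} > age_max {self.age_max} "
                    f"for {self.site_id}/{self.layer_id}"
                )


@dataclass(frozen=True)
class Occupation:
    site_id: str
    layer_id: str
    region: str
    lon: float
    lat: float
    age_min: float
    age_max: float
    age_mid: float

    def __post_init__(self):
        if not self.age_min <= self.age_mid <= self.age_max:
            raise ValidationError(
                f"mid-age {self.age_mid} outside [{self.age_min}, {self.age_max}]"
            )


@dataclass(frozen=True)
class Site:
    site_id: str
    region: str
    lon: float
    lat: float
    occupations: tuple = field(default_factory=tuple)
    span_min: float = np.nan
    span_max: float = np.nan

    @property
    def covers_precession(self) -> bool:
        """True if the combined span covers at least one precession cycle."""
        return bool(self.span_max - self.span_min >= PRECESSION_SPAN_KA)


def derive_date_range(layer: DatedLayer, k: float = 1.0):
    """Return (age_min, age_max, age_mid) in ka for one dated layer.

    With dated samples, the maximum age is the oldest ``age + k*sd`` and
    the minimum age the youngest ``age - k*sd`` (floored at 0).
    Precomputed bounds pass through unchanged.
    """
    if layer.age_min is not None and layer.age_max is not None:
        lo, hi = float(layer.age_min), float(layer.age_max)
    elif layer.dates:
        ages = np.array([a for a, _ in layer.dates], dtype=float)
        sds = np.array([s for _, s in layer.dates], dtype=float)
        hi = float(np.max(ages + k * sds))
        lo = float(max(0.0, np.min(ages - k * sds)))
    else:
        raise ValidationError(
            f"layer {layer.site_id}/{layer.layer_id} has no dates and no bounds"
        )
    return lo, hi, (lo + hi) / 2.0


def layer_to_occupation(layer: DatedLayer, k: float = 1.0) -> Occupation:
    lo, hi, mid = derive_date_range(layer, k=k)
    return Occupation(
        site_id=layer.site_id,
        layer_id=layer.layer_id,
        region=layer.region,
        lon=layer.lon,
        lat=layer.lat,
        age_min=lo,
        age_max=hi,
        age_mid=mid,
    )


def _dedupe_key(occ: Occupation):
    return (
        round(occ.lon, _COORD_DECIMALS),
        round(occ.lat, _COORD_DECIMALS),
        occ.age_min,
        occ.age_max,
    )


def dedupe_occupations(occs):
    """Collapse occupations sharing (lon, lat, age_min, age_max).

    The first record (in sorted order) of each duplicate group survives
    unchanged. Output is sorted by (site_id, age_min, layer_id) and so
    is deterministic regardless of input order.
    """
    ordered = sorted(occs, key=lambda o: (o.site_id, o.age_min, o.layer_id))
    seen = {}
    for occ in ordered:
        seen.setdefault(_dedupe_key(occ), occ)
    return sorted(
        seen.values(), key=lambda o: (o.site_id, o.age_min, o.layer_id)
    )


def region_counts(occs) -> dict:
    counts = {r: 0 for r in REGIONS}
    for occ in occs:
        counts[occ.region] += 1
    return counts


def site_spans(occs):
    """Group occupations into sites with combined min/max date spans.

    All occupations sharing a ``site_id`` must share coordinates (after
    rounding used for dedup); a conflict raises ``ValidationError``.
    """
    by_site: dict[str, list[Occupation]] = {}
    for occ in occs:
        by_site.setdefault(occ.site_id, []).append(occ)
    sites = []
    for site_id in sorted(by_site):
        group = sorted(by_site[site_id], key=lambda o: (o.age_min, o.layer_id))
        coords = {
            (round(o.lon, _COORD_DECIMALS), round(o.lat, _COORD_DECIMALS))
            for o in group
        }
        if len(coords) > 1:
            raise ValidationError(
                f"site {site_id} has conflicting coordinates: {sorted(coords)}"
            )
        sites.append(
            Site(
                site_id=site_id,
                region=group[0].region,
                lon=group[0].lon,
                lat=group[0].lat,
                occupations=tuple(group),
                span_min=min(o.age_min for o in group),
                span_max=max(o.age_max for o in group),
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Tabular I/O

_LONG_COLS = {"site_id", "layer_id", "region", "lon", "lat", "age", "age_sd"}
_BOUNDS_COLS = {"site_id", "layer_id", "region", "lon", "lat", "age_min", "age_max"}


def read_occupation_table(path_or_buf, k: float = 1.0, dedupe: bool = True):
    """Read a CSV occupation inventory and return normalized occupations.

    Two schemas are accepted: long format with one row per date
    (``age``, ``age_sd`` columns) or precomputed bounds (``age_min``,
    ``age_max``). Rows in long format are grouped by
    (site_id, layer_id) before applying the date-range protocol.
    """
    df = pd.read_csv(path_or_buf)
    cols = set(df.columns)
    if _LONG_COLS <= cols:
        layers = []
        for (site_id, layer_id), grp in df.groupby(
            ["site_id", "layer_id"], sort=True
        ):
            first = grp.iloc[0]
            layers.append(
                DatedLayer(
                    site_id=str(site_id),
                    layer_id=str(layer_id),
                    region=str(first["region"]),
                    lon=float(first["lon"]),
                    lat=float(first["lat"]),
                    dates=tuple(
                        (float(a), float(s))
                        for a, s in zip(grp["age"], grp["age_sd"])
                    ),
                )
            )
    elif _BOUNDS_COLS <= cols:
        layers = [
            DatedLayer(
                site_id=str(r.site_id),
                layer_id=str(r.layer_id),
                region=str(r.region),
                lon=float(r.lon),
                lat=float(r.lat),
                age_min=float(r.age_min),
                age_max=float(r.age_max),
            )
            for r in df.itertuples(index=False)
        ]
    else:
        raise ValidationError(
            "unrecognised columns; expected long format "
            f"{sorted(_LONG_COLS)} or bounds format {sorted(_BOUNDS_COLS)}"
        )
    occs = [layer_to_occupation(lay, k=k) for lay in layers]
    return dedupe_occupations(occs) if dedupe else sorted(
        occs, key=lambda o: (o.site_id, o.age_min, o.layer_id)
    )


def occupations_to_frame(occs) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": o.site_id,
                "layer_id": o.layer_id,
                "region": o.region,
                "lon": o.lon,
                "lat": o.lat,
                "age_min": o.age_min,
                "age_max": o.age_max,
                "age_mid": o.age_mid,
            }
            for o in occs
        ]
    )


def sites_to_frame(sites) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "region": s.region,
                "lon": s.lon,
                "lat": s.lat,
                "n_occupations": len(s.occupations),
                "span_min": s.span_min,
                "span_max": s.span_max,
                "covers_precession": s.covers_precession,
            }
            for s in sites
        ]
    )
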