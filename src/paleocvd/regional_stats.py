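"""Two-region comparison tests and resampling nulls.

Provides the two nonparametric tests used for regional comparison
(Mann-Whitney U for location, Ansari-Bradley for dispersion), the
coefficient of variation, the dating-uncertainty sensitivity
permutation (re-running a test with each occupation's value drawn from
a random 1 ka slice inside its date range), and the space-time
background resampling null (observed mid-age values vs values sampled
uniformly over land cells in a region box and slices in a time window).

All resampling is driven by a root seed that spawns one independent
substream per iteration, so results are bit-reproducible and invariant
to occupation input order (inputs are sorted internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .extraction import (
    ClimateCube,
    buffered_series,
    locate_cell,
    nearest_land,
    snap_ka,
)

__all__ = [
    "RegionalComparison",
    "SensitivityResult",
    "BackgroundResult",
    "mann_whitney",
    "ansari_bradley",
    "coef_variation",
    "compare_regions",
    "sensitivity_permutation",
    "background_resample",
    "EAST_BOX",
    "NORTHWEST_BOX",
]

#: (lon_min, lon_max, lat_min, lat_max) region bounding boxes.
EAST_BOX = (30.0, 55.0, -9.0, 20.0)
NORTHWEST_BOX = (-15.0, 35.0, 18.0, 39.0)

MANN_WHITNEY = "MANN_WHITNEY"
ANSARI_BRADLEY = "ANSARI_BRADLEY"

_EXACT_MAX_N = 8


@dataclass(frozen=True)
class RegionalComparison:
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class SensitivityResult:
    test: str
    n_iter: int
    seed: int
    statistics: np.ndarray
    p_values: np.ndarray
    mid_age_statistic: float
    mid_age_p: float
    n_significant: int
    percentile_of_mid_statistic: float
    alpha: float = 0.05


@dataclass(frozen=True)
class BackgroundResult:
    test: str
    n_iter: int
    seed: int
    region_box: tuple
    p_values: np.ndarray
    directions: np.ndarray  # sign of median(observed) - median(sample)
    n_significant: int
    summary_direction: int
    alpha: float = 0.05


def _check_sample(x, name: str, min_n: int = 1):
    arr = np.asarray(x, dtype=float)
    if arr.size < min_n:
        raise ValueError(f"sample {name} needs >= {min_n} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"sample {name} contains non-finite values")
    return arr


def _has_ties(a, b) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size


def mann_whitney(a, b, alpha: float = 0.05) -> RegionalComparison:
    """Two-sided Mann-Whitney U test.

    Exact p-value when the smaller sample has <= 8 values and the
    pooled data are tie-free; tie-corrected normal approximation
    otherwise.
    """
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    exact = min(a.size, b.size) <= _EXACT_MAX_N and not _has_ties(a, b)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return RegionalComparison(
        test=MANN_WHITNEY,
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_a=a.size,
        n_b=b.size,
        alpha=alpha,
    )


def ansari_bradley(a, b, alpha: float = 0.05) -> RegionalComparison:
    """Two-sided Ansari-Bradley dispersion test (exact for small untied
    samples, normal approximation otherwise)."""
    a = _check_sample(a, "a", min_n=2)
    b = _check_sample(b, "b", min_n=2)
    res = stats.ansari(a, b, alternative="two-sided")
    return RegionalComparison(
        test=ANSARI_BRADLEY,
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_a=a.size,
        n_b=b.size,
        alpha=alpha,
    )


_TESTS = {MANN_WHITNEY: mann_whitney, ANSARI_BRADLEY: ansari_bradley}


def coef_variation(values) -> float:
    """Coefficient of variation: 100 x sample sd / mean (signed mean).

    Unstable for near-zero-mean variables (e.g. temperatures in degC
    near 0); a zero mean is an error rather than a silent infinity.
    """
    arr = _check_sample(values, "values", min_n=2)
    mean = arr.mean()
    if mean == 0:
        raise ValueError(
            "coefficient of variation undefined for zero-mean data; "
            "consider an absolute-scale variable"
        )
    return float(100.0 * arr.std(ddof=1) / mean)


def compare_regions(
    values_by_region: dict, test: str = MANN_WHITNEY, alpha: float = 0.05
) -> RegionalComparison:
    """Run the chosen two-sample test on two regions' values."""
    if len(values_by_region) != 2:
        raise ValueError(
            f"need exactly two regions, got {sorted(values_by_region)}"
        )
    keys = sorted(values_by_region)
    a, b = values_by_region[keys[0]], values_by_region[keys[1]]
    return _TESTS[test](a, b, alpha=alpha)


# ---------------------------------------------------------------------------
# Resampling procedures


def _occ_sort_key(occ):
    return (occ.site_id, occ.age_min, occ.layer_id)


def _occ_slice_table(cube: ClimateCube, variable: str, occs):
    """Per occupation: region, full buffered series (aligned with the
    cube time axis), inclusive slice-index range, and mid-slice index."""
    records = []
    cache: dict = {}
    for occ in sorted(occs, key=_occ_sort_key):
        row, col = locate_cell(cube, occ.lon, occ.lat)
        row, col = nearest_land(cube, row, col)
        key = (row, col)
        if key not in cache:
            cache[key] = buffered_series(cube, variable, row, col)
        lo = cube.time_index(max(snap_ka(occ.age_min), cube.t_min))
        hi = cube.time_index(min(snap_ka(occ.age_max), cube.t_max))
        mid = cube.time_index(
            min(max(snap_ka(occ.age_mid), cube.t_min), cube.t_max)
        )
        records.append((occ.region, cache[key], lo, hi, mid))
    return records


def sensitivity_permutation(
    occs,
    cube: ClimateCube,
    variable: str,
    test: str = MANN_WHITNEY,
    n_iter: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> SensitivityResult:
    """Dating-uncertainty sensitivity analysis.

    Each iteration redraws, for every occupation independently, one
    1 ka slice uniformly from its inclusive date range, re-extracts the
    buffered value and re-runs the regional test. The mid-age result is
    located within the permuted statistic distribution as a percentile
    (mean-rank tie convention).
    """
    table = _occ_slice_table(cube, variable, occs)
    regions = sorted({r for r, *_ in table})
    if len(regions) != 2:
        raise ValueError(f"need two regions, got {regions}")
    run = _TESTS[test]

    def split(values):
        return (
            np.array([v for (r, *_), v in zip(table, values) if r == regions[0]]),
            np.array([v for (r, *_), v in zip(table, values) if r == regions[1]]),
        )

    mid_values = [series[mid] for _, series, _, _, mid in table]
    a, b = split(mid_values)
    mid_res = run(a, b, alpha=alpha)

    rng = np.random.default_rng(seed)
    streams = rng.spawn(n_iter)
    statistics = np.empty(n_iter)
    p_values = np.empty(n_iter)
    for i, sub in enumerate(streams):
        draws = [
            series[sub.integers(lo, hi + 1)]
            for _, series, lo, hi, _ in table
        ]
        a, b = split(draws)
        res = run(a, b, alpha=alpha)
        statistics[i] = res.statistic
        p_values[i] = res.p_value

    less = np.count_nonzero(statistics < mid_res.statistic)
    ties = np.count_nonzero(statistics == mid_res.statistic)
    percentile = 100.0 * (less + 0.5 * ties) / n_iter
    return SensitivityResult(
        test=test,
        n_iter=n_iter,
        seed=seed,
        statistics=statistics,
        p_values=p_values,
        mid_age_statistic=mid_res.statistic,
        mid_age_p=mid_res.p_value,
        n_significant=int(np.count_nonzero(p_values < alpha)),
        percentile_of_mid_statistic=float(percentile),
        alpha=alpha,
    )


def background_resample(
    cube: ClimateCube,
    region_box,
    observed_mid_values,
    t_min: int,
    t_max: int,
    variable: str = "bio01",
    n_iter: int = 1000,
    seed: int = 0,
    test: str = MANN_WHITNEY,
    alpha: float = 0.05,
) -> BackgroundResult:
    """Space-time background null for observed mid-age values.

    Each iteration samples ``len(observed)`` (land cell, slice) pairs
    uniformly with replacement from the region box and time window,
    extracts buffered values and tests them against the observed
    sample; direction is the sign of median(observed) - median(sample).
    """
    observed = _check_sample(observed_mid_values, "observed")
    lon_min, lon_max, lat_min, lat_max = region_box
    in_box = (
        (cube.lon_axis[None, :] >= lon_min)
        & (cube.lon_axis[None, :] <= lon_max)
        & (cube.lat_axis[:, None] >= lat_min)
        & (cube.lat_axis[:, None] <= lat_max)
    )
    rows, cols = np.nonzero(in_box & cube.land_mask)
    if rows.size == 0:
        raise ValueError(f"no land cells inside region box {region_box}")
    lo = cube.time_index(t_min)
    hi = cube.time_index(t_max)
    if lo > hi:
        lo, hi = hi, lo
    # precompute buffered series for every candidate cell
    series = np.stack(
        [buffered_series(cube, variable, r, c) for r, c in zip(rows, cols)]
    )
    run = _TESTS[test]
    rng = np.random.default_rng(seed)
    streams = rng.spawn(n_iter)
    n = observed.size
    p_values = np.empty(n_iter)
    directions = np.empty(n_iter, dtype=int)
    obs_median = np.median(observed)
    for i, sub in enumerate(streams):
        cell_idx = sub.integers(0, rows.size, size=n)
        t_idx = sub.integers(lo, hi + 1, size=n)
        sample = series[cell_idx, t_idx]
        res = run(observed, sample, alpha=alpha)
        p_values[i] = res.p_value
        directions[i] = int(np.sign(obs_median - np.median(sample)))
    return BackgroundResult(
        test=test,
        n_iter=n_iter,
        seed=seed,
        region_box=tuple(region_box),
        p_values=p_values,
        directions=directions,
        n_significant=int(np.count_nonzero(p_values < alpha)),
        summary_direction=int(np.sign(np.median(directions))),
        alpha=alpha,
    )
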