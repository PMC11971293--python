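"""Bioclimatic variables derived from monthly climatologies.

Implements the four variables used throughout the pipeline:

* ``bio01`` -- mean annual temperature (mean of 12 monthly means, degC)
* ``bio04`` -- temperature seasonality (sd of monthly means x 100)
* ``bio12`` -- total annual precipitation (sum of monthly totals, mm)
* ``bio15`` -- precipitation seasonality (CV of monthly totals, %)

All functions accept either a single 12-vector or an array whose *last*
axis has length 12, in which case they reduce over that axis.

The standard-deviation denominator is configurable (``ddof=1`` by
default, matching common bioclim implementations); ``bio15`` uses the
plain mean in the denominator (no "+1" offset) and returns 0 for
all-zero precipitation so hyper-arid cells stay finite downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MonthlyClimatology",
    "bio01",
    "bio04",
    "bio12",
    "bio15",
    "monthly_to_bio",
]

_N_MONTHS = 12


def _as_monthly(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape[-1:] != (_N_MONTHS,):
        raise ValueError(
            f"{name} must have 12 monthly values on the last axis, "
            f"got shape {arr.shape}"
        )
    if np.any(np.isinf(arr)):
        raise ValueError(f"{name} contains infinite values")
    # NaN is allowed and propagates: masked (sea) cells in gridded input
    return arr


@dataclass(frozen=True)
class MonthlyClimatology:
    """One year of monthly mean temperatures (degC) and precip totals (mm)."""

    temp: np.ndarray
    prec: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "temp", _as_monthly(self.temp, "temp"))
        prec = _as_monthly(self.prec, "prec")
        if np.any(prec < 0):
            raise ValueError("prec must be non-negative")
        object.__setattr__(self, "prec", prec)


def bio01(temp) -> np.ndarray | float:
    """Mean annual temperature: arithmetic mean of the 12 monthly means."""
    t = _as_monthly(temp, "temp")
    return t.mean(axis=-1)


def bio04(temp, ddof: int = 1) -> np.ndarray | float:
    """Temperature seasonality: sd of monthly means, multiplied by 100."""
    t = _as_monthly(temp, "temp")
    return 100.0 * t.std(axis=-1, ddof=ddof)


def bio12(prec) -> np.ndarray | float:
    """Total annual precipitation: sum of the 12 monthly totals."""
    p = _as_monthly(prec, "prec")
    if np.any(p < 0):
        raise ValueError("prec must be non-negative")
    return p.sum(axis=-1)


def bio15(prec, ddof: int = 1) -> np.ndarray | float:
    """Precipitation seasonality: 100 x sd / mean of monthly totals.

    All-zero months yield 0 rather than NaN (degenerate-input rule).
    """
    p = _as_monthly(prec, "prec")
    if np.any(p < 0):
        raise ValueError("prec must be non-negative")
    mean = p.mean(axis=-1)
    sd = p.std(axis=-1, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, 100.0 * sd / np.where(mean > 0, mean, 1.0), 0.0)
        cv = np.where(np.isnan(mean), np.nan, cv)
    return cv[()] if cv.ndim == 0 else cv


def monthly_to_bio(temp, prec, ddof: int = 1) -> dict:
    """Compute all four bio variables from monthly stacks in one call."""
    return {
        "bio01": bio01(temp),
        "bio04": bio04(temp, ddof=ddof),
        "bio12": bio12(prec),
        "bio15": bio15(prec, ddof=ddof),
    }
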