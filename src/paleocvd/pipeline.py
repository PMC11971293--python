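"""Orchestration of the full analysis: occupation report and
predictability report, with a reproducible run manifest."""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cvd import ConstantSeriesError, cvd_decompose
from .extraction import (
    ClimateCube,
    extract_mid_value,
    extract_occupation_series,
    extract_site_series,
)
from .occupations import (
    PRECESSION_SPAN_KA,
    occupations_to_frame,
    site_spans,
    sites_to_frame,
)
from .regional_stats import (
    ANSARI_BRADLEY,
    MANN_WHITNEY,
    background_resample,
    coef_variation,
    compare_regions,
    sensitivity_permutation,
)

__all__ = ["RunConfig", "run_occupation_report", "run_predictability_report"]

DEFAULT_VARIABLES = ("bio01", "bio04", "bio12", "bio15", "npp")
CVD_VARIABLES = ("bio01", "bio12", "npp")


@dataclass
class RunConfig:
    variables: tuple = DEFAULT_VARIABLES
    cvd_variables: tuple = CVD_VARIABLES
    M: int = 23
    alpha: float = 0.05
    n_iter: int = 1000
    seed: int = 0
    region_boxes: dict = field(default_factory=dict)
    run_sensitivity: bool = True
    run_background: bool = True
    run_cvd: bool = True

    def validate(self):
        if self.M < 2:
            raise ValueError("M must be >= 2")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        return self

    def digest(self) -> str:
        payload = json.dumps(
            {k: sorted(v.items()) if isinstance(v, dict) else list(v)
             if isinstance(v, tuple) else v
             for k, v in vars(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _mid_values_by_region(cube, variable, occs):
    out: dict[str, list] = {}
    for occ in occs:
        out.setdefault(occ.region, []).append(
            extract_mid_value(cube, variable, occ)
        )
    return {k: np.asarray(v) for k, v in out.items()}


def run_occupation_report(config: RunConfig, cube: ClimateCube, occs) -> dict:
    """Per-occupation climate values plus regional comparison statistics.

    Returns a dict of DataFrames: ``occupations`` (mid/min/max per
    variable), ``comparisons`` (both tests per variable, with CVs) and
    optionally ``sensitivity`` and ``background`` summaries.
    """
    config.validate()
    caught: list[str] = []
    occ_frame = occupations_to_frame(occs)
    for variable in config.variables:
        mids, lows, highs = [], [], []
        for occ in occs:
            sample = extract_occupation_series(cube, variable, occ)
            mids.append(extract_mid_value(cube, variable, occ))
            lows.append(float(sample.values.min()))
            highs.append(float(sample.values.max()))
        occ_frame[f"{variable}_mid"] = mids
        occ_frame[f"{variable}_min"] = lows
        occ_frame[f"{variable}_max"] = highs

    comparisons = []
    for variable in config.variables:
        by_region = _mid_values_by_region(cube, variable, occs)
        for test in (MANN_WHITNEY, ANSARI_BRADLEY):
            res = compare_regions(by_region, test=test, alpha=config.alpha)
            row = {
                "variable": variable,
                "test": test,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.significant,
            }
            comparisons.append(row)
        for region, values in sorted(by_region.items()):
            try:
                cv = coef_variation(values)
            except ValueError as exc:
                cv = np.nan
                caught.append(f"CV undefined for {variable}/{region}: {exc}")
            comparisons.append(
                {"variable": variable, "test": f"CV_{region}",
                 "statistic": cv, "p_value": np.nan, "significant": False}
            )

    out = {
        "occupations": occ_frame,
        "comparisons": pd.DataFrame(comparisons),
        "warnings": caught,
    }

    if config.run_sensitivity:
        rows = []
        for variable in config.variables:
            for test in (MANN_WHITNEY, ANSARI_BRADLEY):
                res = sensitivity_permutation(
                    occs, cube, variable, test=test,
                    n_iter=config.n_iter, seed=config.seed,
                    alpha=config.alpha,
                )
                rows.append(
                    {
                        "variable": variable,
                        "test": test,
                        "mid_age_statistic": res.mid_age_statistic,
                        "mid_age_p": res.mid_age_p,
                        "n_significant": res.n_significant,
                        "n_iter": res.n_iter,
                        "percentile_of_mid_statistic":
                            res.percentile_of_mid_statistic,
                    }
                )
        out["sensitivity"] = pd.DataFrame(rows)

    if config.run_background and config.region_boxes:
        rows = []
        t_lo = int(min(o.age_min for o in occs))
        t_hi = int(max(o.age_max for o in occs))
        t_lo = max(t_lo, cube.t_min)
        t_hi = min(t_hi, cube.t_max)
        for variable in config.variables:
            by_region = _mid_values_by_region(cube, variable, occs)
            for region, box in sorted(config.region_boxes.items()):
                if region not in by_region:
                    continue
                res = background_resample(
                    cube, box, by_region[region], t_lo, t_hi,
                    variable=variable, n_iter=config.n_iter,
                    seed=config.seed, alpha=config.alpha,
                )
                rows.append(
                    {
                        "variable": variable,
                        "region": region,
                        "n_significant": res.n_significant,
                        "n_iter": res.n_iter,
                        "direction": res.summary_direction,
                    }
                )
        out["background"] = pd.DataFrame(rows)
    return out


def _cvd_rows(cube, variables, entity_id, region, extract, M, alpha, caught):
    row = {"entity_id": entity_id, "region": region}
    for variable in variables:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = cvd_decompose(extract(variable).values, M=M, alpha=alpha)
        except ConstantSeriesError as exc:
            caught.append(f"CVD skipped for {entity_id}/{variable}: {exc}")
            row[f"{variable}_pct_change"] = np.nan
            row[f"{variable}_pct_variability"] = np.nan
            row[f"{variable}_w"] = -1
            continue
        row[f"{variable}_pct_change"] = result.pct_change
        row[f"{variable}_pct_variability"] = result.pct_variability
        row[f"{variable}_w"] = result.w
    return row


def run_predictability_report(config: RunConfig, cube: ClimateCube, occs) -> dict:
    """Change/variability decomposition tables plus regional tests.

    Occupation-level rows cover occupations whose own date range spans
    >= 23 ka; site-level rows cover sites whose combined span does.
    Regional comparisons are run on site-level percent variability.
    """
    config.validate()
    caught: list[str] = []
    occ_rows = []
    for occ in occs:
        if occ.age_max - occ.age_min < PRECESSION_SPAN_KA:
            continue
        occ_rows.append(
            _cvd_rows(
                cube, config.cvd_variables, f"{occ.site_id}/{occ.layer_id}",
                occ.region,
                lambda v, o=occ: extract_occupation_series(cube, v, o),
                config.M, config.alpha, caught,
            )
        )

    sites = site_spans(occs)
    site_rows = []
    for site in sites:
        if not site.covers_precession:
            continue
        site_rows.append(
            _cvd_rows(
                cube, config.cvd_variables, site.site_id, site.region,
                lambda v, s=site: extract_site_series(cube, v, s),
                config.M, config.alpha, caught,
            )
        )
    site_frame = pd.DataFrame(site_rows)

    comparisons = []
    if len(site_frame) and site_frame["region"].nunique() == 2:
        for variable in config.cvd_variables:
            col = f"{variable}_pct_variability"
            groups = {
                region: grp[col].dropna().to_numpy()
                for region, grp in site_frame.groupby("region")
            }
            if any(len(v) < 2 for v in groups.values()):
                continue
            for test in (MANN_WHITNEY, ANSARI_BRADLEY):
                res = compare_regions(groups, test=test, alpha=config.alpha)
                comparisons.append(
                    {
                        "variable": variable,
                        "test": test,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "significant": res.significant,
                    }
                )
            for region, vals in sorted(groups.items()):
                comparisons.append(
                    {
                        "variable": variable,
                        "test": f"MEAN_PCT_VARIABILITY_{region}",
                        "statistic": float(np.mean(vals)),
                        "p_value": np.nan,
                        "significant": False,
                    }
                )
    return {
        "occupation_cvd": pd.DataFrame(occ_rows),
        "site_cvd": site_frame,
        "sites": sites_to_frame(sites),
        "comparisons": pd.DataFrame(comparisons),
        "warnings": caught,
    }


def write_manifest(path, config: RunConfig, stages: dict, extra=None):
    """Persist seed, config hash and per-stage timings next to outputs."""
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stage_seconds": stages,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2))
    return manifest
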