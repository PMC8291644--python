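"""Drought exposure from gridded rainfall.

For each respondent the exposure is the trailing-12-month rainfall total
(the 12 calendar months strictly preceding the interview month), ranked
against the baseline distribution of same-window totals from all prior
years, and discretized into ordinal categories:

* extreme  : percentile < 0.025
* severe   : 0.025 <= percentile < 0.10
* moderate : 0.10  <= percentile < 0.30
* none     : percentile >= 0.30

The binary recode used in subgroup analyses is drought iff
percentile < 0.30.  Intervals are lower-inclusive half-open; the
mid-rank empirical percentile handles ties symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .geo import unit_vectors, chord_sq_matrix
from .simulate import RainfallGrid

CATEGORIES = ("none", "moderate", "severe", "extreme")
EXTREME_CUT = 0.025
SEVERE_CUT = 0.10
MODERATE_CUT = 0.30


class MonthlySeries(NamedTuple):
    """A single cell's monthly rainfall, month 0 = January of start_year."""

    values: np.ndarray
    start_year: int


@dataclass(frozen=True)
class DroughtExposure:
    trailing_total: float
    percentile: float
    category: str
    binary: str  # "drought" | "normal"


def extract_cluster_series(grid: RainfallGrid, lat: float, lon: float) -> MonthlySeries:
    """Monthly series of the grid cell nearest to (lat, lon).

    Nearest by great-circle distance; exact ties go to the lower
    (lat-major) flat index.  Coordinates outside the grid extent padded
    by half a cell raise ``ValueError`` — lookups never extrapolate.
    """
    if not grid.contains(lat, lon):
        raise ValueError(f"coordinate ({lat}, {lon}) outside grid extent (+half-cell pad)")
    cell_lat = np.repeat(grid.lat_axis, grid.lon_axis.size)
    cell_lon = np.tile(grid.lon_axis, grid.lat_axis.size)
    d2 = chord_sq_matrix(unit_vectors([lat], [lon]), unit_vectors(cell_lat, cell_lon))[0]
    flat = int(np.argmin(d2))  # argmin takes the first minimum: lower flat index
    i, j = divmod(flat, grid.lon_axis.size)
    return MonthlySeries(values=grid.values[:, i, j].copy(), start_year=grid.start_year)


def _window_end_index(series: MonthlySeries, year: int, month: int) -> int:
    """Index one past the last month of the trailing window ending before
    (year, month)."""
    return (year - series.start_year) * 12 + (month - 1)


def trailing_annual_rainfall(series: MonthlySeries, interview_year: int, interview_month: int) -> float:
    """Sum of the 12 monthly values ending with the month before the interview."""
    if not 1 <= interview_month <= 12:
        raise ValueError("interview_month must be in 1..12")
    end = _window_end_index(series, interview_year, interview_month)
    if end - 12 < 0 or end > series.values.size:
        raise ValueError("series does not cover the 12 months before the interview")
    return float(series.values[end - 12 : end].sum())


def baseline_totals(series: MonthlySeries, interview_year: int, interview_month: int) -> np.ndarray:
    """Trailing-12-month totals for the same calendar window in every prior
    year, from the series start; the target year's own window is excluded."""
    if not 1 <= interview_month <= 12:
        raise ValueError("interview_month must be in 1..12")
    totals = []
    for year in range(series.start_year, interview_year):
        end = _window_end_index(series, year, interview_month)
        if end - 12 < 0 or end > series.values.size:
            continue
        totals.append(series.values[end - 12 : end].sum())
    if len(totals) < 2:
        raise ValueError("fewer than 2 baseline windows available before the target window")
    return np.asarray(totals, dtype=float)


def rainfall_percentile(target_total: float, baseline: np.ndarray) -> float:
    """Mid-rank empirical percentile of the target among baseline totals:
    ``(#{b < t} + 0.5 #{b == t}) / |b|``."""
    baseline = np.asarray(baseline, dtype=float)
    if baseline.size == 0:
        raise ValueError("baseline is empty")
    below = np.count_nonzero(baseline < target_total)
    ties = np.count_nonzero(baseline == target_total)
    return (below + 0.5 * ties) / baseline.size


def _check_percentile(percentile: float) -> None:
    if not 0.0 <= percentile <= 1.0:
        raise ValueError(f"percentile {percentile} outside [0, 1]")


def classify_drought(percentile: float) -> str:
    """Ordinal category from a rainfall percentile (lower-inclusive cuts)."""
    _check_percentile(percentile)
    if percentile < EXTREME_CUT:
        return "extreme"
    if percentile < SEVERE_CUT:
        return "severe"
    if percentile < MODERATE_CUT:
        return "moderate"
    return "none"


def binarize_drought(percentile: float) -> str:
    """Two-level recode: drought iff percentile < 0.30."""
    _check_percentile(percentile)
    return "drought" if percentile < MODERATE_CUT else "normal"


def compute_exposure(series: MonthlySeries, interview_year: int, interview_month: int) -> DroughtExposure:
    """Full exposure record for one location and interview date."""
    total = trailing_annual_rainfall(series, interview_year, interview_month)
    base = baseline_totals(series, interview_year, interview_month)
    pct = rainfall_percentile(total, base)
    return DroughtExposure(
        trailing_total=total,
        percentile=pct,
        category=classify_drought(pct),
        binary=binarize_drought(pct),
    )


def attach_exposure(records: pd.DataFrame, grid: RainfallGrid) -> pd.DataFrame:
    """Append ``drought_percentile``, ``drought_category`` and
    ``drought_binary`` columns computed per cluster location/date.

    Rows sharing (latitude, longitude, interview_year, interview_month)
    are looked up once.
    """
    out = records.copy()
    keys = ["latitude", "longitude", "interview_year", "interview_month"]
    pct = np.empty(len(out))
    cat = np.empty(len(out), dtype=object)
    for key_vals, idx in out.groupby(keys, sort=False).indices.items():
        lat, lon, year, month = key_vals
        series = extract_cluster_series(grid, float(lat), float(lon))
        exp = compute_exposure(series, int(year), int(month))
        pct[idx] = exp.percentile
        cat[idx] = exp.category
    out["drought_percentile"] = pct
    out["drought_category"] = cat
    out["drought_binary"] = np.where(pct < MODERATE_CUT, "drought", "normal")
    return out
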