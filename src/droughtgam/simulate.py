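"""Synthetic rainfall grids and clustered survey populations with known truth.

The generator produces the two inputs the analysis pipeline consumes:

* a monthly precipitation cube on a lat/lon grid, with interannual
  variability driven by a spatially smooth per-year multiplier field (so
  drought exposure is itself spatially structured), and
* a table of geolocated respondents whose binary outcomes follow a
  logistic model with covariates, survey fixed effects, a configurable
  true drought effect, and a latent spatially correlated risk field.

Because both the exposure and the latent risk share spatial scales, the
generator reproduces the confounding structure that makes naive
(non-spatial) hypothesis tests anti-conservative.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .geo import pairwise_km

OUTCOME_COLUMNS = ("controlling", "emotional", "physical", "sexual")

#: Default marginal frequencies for covariate sampling.  Binary covariates
#: map to a single probability; categorical covariates map level -> prob
#: (normalized at sampling time).
DEFAULT_COVARIATE_FREQS: dict = {
    "married": 0.841,
    "literate": 0.415,
    "rural": 0.691,
    "age_band": {"<20": 0.070, "20-29": 0.421, "30-39": 0.332, "40-49": 0.177},
    "births_band": {"0-2": 0.316, "3-4": 0.287, ">4": 0.330},
    "partner_education": {"none": 0.300, "primary": 0.334, "secondary": 0.294, "higher": 0.072},
    "partner_age_band": {"<20": 0.004, "20-29": 0.207, "30-39": 0.367, "40-49": 0.254, ">49": 0.168},
    "hh_size_band": {"1-3": 0.217, "4-5": 0.348, ">5": 0.434},
}

EMPLOYMENT_LEVELS = ("agriculture", "manual", "professional", "unemployed")
WATER_SOURCE_LEVELS = ("dug well", "piped", "purchased", "rain", "surface", "tube well", "other")


@dataclass
class RainfallGrid:
    """Monthly precipitation totals (mm) on a regular lat/lon grid.

    ``values`` is indexed ``(month_index, lat, lon)`` with month 0 being
    January of ``start_year``; the time axis length must be a multiple
    of 12.
    """

    lat_axis: np.ndarray
    lon_axis: np.ndarray
    start_year: int
    values: np.ndarray

    def __post_init__(self):
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lat_axis.ndim != 1 or self.lon_axis.ndim != 1:
            raise ValueError("lat_axis and lon_axis must be 1-D")
        if np.any(np.diff(self.lat_axis) <= 0) or np.any(np.diff(self.lon_axis) <= 0):
            raise ValueError("grid axes must be strictly ascending")
        if self.values.shape != (self.values.shape[0], self.lat_axis.size, self.lon_axis.size):
            raise ValueError("values must have shape (n_months, n_lat, n_lon)")
        if self.values.shape[0] % 12 != 0:
            raise ValueError("time axis length must be a multiple of 12")
        if np.any(self.values < 0):
            raise ValueError("precipitation values must be non-negative")

    @property
    def n_years(self) -> int:
        return self.values.shape[0] // 12

    @property
    def end_year(self) -> int:
        """Last complete calendar year covered by the grid."""
        return self.start_year + self.n_years - 1

    def half_cell(self) -> tuple[float, float]:
        """Half-cell padding (lat, lon) used for containment checks."""
        dlat = float(np.median(np.diff(self.lat_axis))) if self.lat_axis.size > 1 else 0.5
        dlon = float(np.median(np.diff(self.lon_axis))) if self.lon_axis.size > 1 else 0.5
        return dlat / 2.0, dlon / 2.0

    def contains(self, lat: float, lon: float) -> bool:
        plat, plon = self.half_cell()
        return (
            self.lat_axis[0] - plat <= lat <= self.lat_axis[-1] + plat
            and self.lon_axis[0] - plon <= lon <= self.lon_axis[-1] + plon
        )

    def to_dataset(self) -> xr.Dataset:
        time = np.arange(self.values.shape[0])
        ds = xr.Dataset(
            {"precip": (("time", "lat", "lon"), self.values)},
            coords={"time": time, "lat": self.lat_axis, "lon": self.lon_axis},
            attrs={"start_year": self.start_year},
        )
        ds["precip"].attrs["units"] = "mm/month"
        return ds

    def to_netcdf(self, path) -> None:
        # scipy engine writes classic NetCDF3 without the netCDF4 C library
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "RainfallGrid":
        return cls(
            lat_axis=ds["lat"].values,
            lon_axis=ds["lon"].values,
            start_year=int(ds.attrs["start_year"]),
            values=ds["precip"].values,
        )

    @classmethod
    def from_netcdf(cls, path) -> "RainfallGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


@dataclass
class GridConfig:
    """Configuration for :func:`generate_rainfall_grid`."""

    lat_min: float = 0.0
    lat_max: float = 10.0
    lon_min: float = 0.0
    lon_max: float = 10.0
    resolution_deg: float = 0.5
    n_years: int = 30
    start_year: int = 1981
    monthly_mean_mm: float = 80.0
    #: coefficient of variation of the within-year monthly gamma noise
    monthly_cv: float = 0.3
    #: coefficient of variation of the per-year rainfall multiplier
    annual_cv: float = 0.3
    #: spatial correlation length of the annual multiplier field
    annual_range_km: float = 300.0
    seed: int = 0


def _axis(lo: float, hi: float, res: float) -> np.ndarray:
    n = max(int(round((hi - lo) / res)), 1)
    return lo + res * (np.arange(n) + 0.5)


def generate_rainfall_grid(config: GridConfig) -> RainfallGrid:
    """Draw a synthetic monthly rainfall cube.

    Monthly totals are gamma-distributed around a per-cell, per-year
    multiplier; the multiplier itself is a spatially smooth lognormal
    field (mean 1) so that dry years cover contiguous regions.  With
    ``monthly_cv == annual_cv == 0`` every value equals
    ``monthly_mean_mm`` exactly.
    """
    if config.n_years < 2:
        raise ValueError("need at least 2 years of rainfall for a baseline distribution")
    if config.lat_max <= config.lat_min or config.lon_max <= config.lon_min:
        raise ValueError("degenerate grid extent")
    rng = np.random.default_rng(config.seed)
    lat_axis = _axis(config.lat_min, config.lat_max, config.resolution_deg)
    lon_axis = _axis(config.lon_min, config.lon_max, config.resolution_deg)
    n_lat, n_lon = lat_axis.size, lon_axis.size
    n_cells = n_lat * n_lon
    n_months = 12 * config.n_years

    cell_lat = np.repeat(lat_axis, n_lon)
    cell_lon = np.tile(lon_axis, n_lat)

    if config.annual_cv > 0:
        # lognormal multiplier with mean 1:  m = exp(f - s^2/2),  f ~ GP(0, s^2)
        sigma = float(np.sqrt(np.log1p(config.annual_cv**2)))
        chol = _field_cholesky(cell_lat, cell_lon, sigma, config.annual_range_km)
        eps = rng.standard_normal((n_cells, config.n_years))
        mult = np.exp(chol @ eps - sigma**2 / 2.0)  # (n_cells, n_years)
    else:
        mult = np.ones((n_cells, config.n_years))

    mean = config.monthly_mean_mm * np.repeat(mult, 12, axis=1)  # (n_cells, n_months)
    if config.monthly_cv > 0:
        shape = 1.0 / config.monthly_cv**2
        vals = rng.gamma(shape, mean / shape)
    else:
        vals = mean
    values = vals.T.reshape(n_months, n_lat, n_lon)
    return RainfallGrid(lat_axis=lat_axis, lon_axis=lon_axis, start_year=config.start_year, values=values)


COVARIANCE_KERNELS = ("exponential", "matern32", "gaussian")


def _kernel(d: np.ndarray, sd: float, range_km: float, kind: str) -> np.ndarray:
    if kind == "exponential":
        return sd**2 * np.exp(-d / range_km)
    if kind == "matern32":
        h = np.sqrt(3.0) * d / range_km
        return sd**2 * (1.0 + h) * np.exp(-h)
    if kind == "gaussian":
        return sd**2 * np.exp(-((d / range_km) ** 2))
    raise ValueError(f"unknown covariance kernel {kind!r}; choose from {COVARIANCE_KERNELS}")


def _field_cholesky(lat, lon, sd: float, range_km: float, kind: str = "exponential") -> np.ndarray:
    """Cholesky factor of the chosen stationary covariance kernel."""
    d = pairwise_km(lat, lon, lat, lon)
    cov = _kernel(d, sd, range_km, kind)
    jitter = 1e-10 * sd**2
    for _ in range(6):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(len(cov)))
        except np.linalg.LinAlgError:
            jitter *= 100.0
    raise np.linalg.LinAlgError("covariance factorization failed")


def sample_spatial_field(coords, sd: float, range_km: float, seed=None,
                         covariance: str = "exponential") -> np.ndarray:
    """One draw from a zero-mean Gaussian field at (lat, lon) coordinates.

    The default covariance is exponential, ``sd^2 * exp(-d / range_km)``;
    ``covariance`` may also be ``"matern32"`` or ``"gaussian"`` for
    progressively smoother sample paths.  ``seed`` may be an int or a
    ``numpy.random.Generator``.  ``sd == 0`` returns the zero vector;
    coincident coordinates receive identical values (correlation 1 at
    distance 0).
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    if range_km <= 0:
        raise ValueError("range_km must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    n = coords.shape[0]
    if sd == 0 or n == 0:
        return np.zeros(n)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # collapse duplicate coordinates so the factorization is well-posed and
    # coincident points get identical draws
    uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
    chol = _field_cholesky(uniq[:, 0], uniq[:, 1], sd, range_km, covariance)
    draw = chol @ rng.standard_normal(uniq.shape[0])
    return draw[inverse]


@dataclass
class SimulationConfig:
    """Ground-truth parameters for :func:`generate_population`.

    ``beta_covariates`` maps dummy-column names (e.g. ``"married"`` or
    ``"age_band[30-39]"``) to log-odds contributions; ``beta_drought``
    maps drought categories to the true effect of interest.
    """

    n_surveys: int = 1
    n_clusters_per_survey: int = 50
    n_women_per_cluster: int = 20
    beta0: float = -1.0
    beta_covariates: Mapping[str, float] = field(default_factory=dict)
    beta_drought: Mapping[str, float] = field(
        default_factory=lambda: {"moderate": 0.0, "severe": 0.0, "extreme": 0.0}
    )
    survey_effects: Sequence[float] | None = None
    spatial_sd: float = 0.0
    spatial_range_km: float = 300.0
    spatial_covariance: str = "exponential"
    seed: int = 0
    interview_year: int | None = None  # default: last grid year
    covariate_freqs: Mapping | None = None  # default: DEFAULT_COVARIATE_FREQS

    def __post_init__(self):
        if self.spatial_sd < 0:
            raise ValueError("spatial_sd must be non-negative")
        if self.spatial_range_km <= 0:
            raise ValueError("spatial_range_km must be positive")
        for name in ("n_surveys", "n_clusters_per_survey", "n_women_per_cluster"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _sample_categorical(rng, freqs: Mapping[str, float], n: int) -> np.ndarray:
    levels = list(freqs.keys())
    p = np.array([freqs[k] for k in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=n, p=p)


def generate_population(config: SimulationConfig, grid: RainfallGrid) -> pd.DataFrame:
    """Generate one respondent table (one row per woman).

    Clusters are placed uniformly over the grid's cell-center extent; all
    women in a cluster share coordinates, survey and interview date.
    Each of the four outcomes is an independent Bernoulli draw from
    ``logit = beta0 + X beta + beta_d x_d + delta_survey + field``, where
    the drought category ``x_d`` is computed from the grid by the drought
    module and ``field`` is the latent spatially correlated risk.  The
    returned frame carries ground-truth columns (``spatial_field``,
    ``true_logit``) alongside the observables.
    """
    from . import drought  # local import: drought depends on RainfallGrid

    rng = np.random.default_rng(config.seed)
    n_clusters = config.n_surveys * config.n_clusters_per_survey
    n_women = config.n_women_per_cluster
    n_total = n_clusters * n_women

    interview_year = config.interview_year if config.interview_year is not None else grid.end_year
    if interview_year < grid.start_year + 1:
        raise ValueError(
            f"interview year {interview_year} precedes grid start {grid.start_year} + 1; "
            "no trailing-12-month window available"
        )
    if interview_year > grid.end_year + 1:
        raise ValueError("interview year beyond grid coverage")

    cl_lat = rng.uniform(grid.lat_axis[0], grid.lat_axis[-1], n_clusters)
    cl_lon = rng.uniform(grid.lon_axis[0], grid.lon_axis[-1], n_clusters)
    cl_survey = np.repeat(np.arange(config.n_surveys), config.n_clusters_per_survey)
    survey_ids = np.array([f"s{j:03d}" for j in range(config.n_surveys)])
    # one interview month per survey, months with a full window exist for all
    cl_month = rng.integers(1, 13, size=config.n_surveys)[cl_survey]

    if config.survey_effects is None:
        delta = np.zeros(config.n_surveys)
    else:
        delta = np.asarray(config.survey_effects, dtype=float)
        if delta.shape != (config.n_surveys,):
            raise ValueError("survey_effects must have length n_surveys")

    field_vals = sample_spatial_field(
        np.column_stack([cl_lat, cl_lon]), config.spatial_sd, config.spatial_range_km,
        rng, covariance=config.spatial_covariance,
    )

    # drought exposure per cluster, via the drought module
    percentile = np.empty(n_clusters)
    category = np.empty(n_clusters, dtype=object)
    for c in range(n_clusters):
        series = drought.extract_cluster_series(grid, cl_lat[c], cl_lon[c])
        exp_c = drought.compute_exposure(series, interview_year, int(cl_month[c]))
        percentile[c] = exp_c.percentile
        category[c] = exp_c.category

    bd = np.array([config.beta_drought.get(cat, 0.0) if cat != "none" else 0.0 for cat in category])

    freqs = dict(DEFAULT_COVARIATE_FREQS)
    if config.covariate_freqs:
        freqs.update(config.covariate_freqs)

    cov_cols: dict[str, np.ndarray] = {}
    for name, spec in freqs.items():
        if isinstance(spec, Mapping):
            cov_cols[name] = _sample_categorical(rng, spec, n_total)
        else:
            cov_cols[name] = (rng.random(n_total) < float(spec)).astype(int)

    xb = np.zeros(n_total)
    for key, coef in config.beta_covariates.items():
        if "[" in key:
            base, level = key[:-1].split("[", 1)
            if base not in cov_cols:
                raise KeyError(f"unknown covariate in beta_covariates: {key}")
            xb += coef * (cov_cols[base] == level)
        else:
            if key not in cov_cols:
                raise KeyError(f"unknown covariate in beta_covariates: {key}")
            xb += coef * cov_cols[key].astype(float)

    cluster_idx = np.repeat(np.arange(n_clusters), n_women)
    logit = (
        config.beta0
        + xb
        + bd[cluster_idx]
        + delta[cl_survey][cluster_idx]
        + field_vals[cluster_idx]
    )
    p = 1.0 / (1.0 + np.exp(-logit))

    data = {
        "woman_id": np.arange(n_total),
        "cluster_id": cluster_idx,
        "survey_id": survey_ids[cl_survey][cluster_idx],
        "latitude": cl_lat[cluster_idx],
        "longitude": cl_lon[cluster_idx],
        "interview_year": np.full(n_total, interview_year, dtype=int),
        "interview_month": cl_month[cluster_idx].astype(int),
    }
    for out in OUTCOME_COLUMNS:
        data[out] = (rng.random(n_total) < p).astype(int)
    data.update(cov_cols)
    data["wealth_quintile"] = rng.integers(1, 6, size=n_total)
    data["employment"] = rng.choice(EMPLOYMENT_LEVELS, size=n_total)
    data["water_source"] = rng.choice(WATER_SOURCE_LEVELS, size=n_total)
    data["spatial_field"] = field_vals[cluster_idx]
    data["true_logit"] = logit
    data["true_percentile"] = percentile[cluster_idx]
    data["true_category"] = category[cluster_idx]
    return pd.DataFrame(data)


def config_to_dict(config) -> dict:
    """Serializable view of a dataclass config (for provenance logging)."""
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    return d
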