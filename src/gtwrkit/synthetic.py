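"""Seeded synthetic spatio-temporal panels with known ground truth.

The generator emulates the study design the package targets: 129 areal
units observed over 36 months (4,644 records) with an air-quality-index
covariate built from

* a static spatially autocorrelated surface (Gaussian random field with
  exponential covariance, realised by Cholesky factorisation of the
  covariance at the unit centroids and station sites jointly),
* a seasonal sinusoid with a 12-month period peaking mid-year (southern
  winter), and
* per-site random walks driven by spatially correlated innovations (one
  GRF draw per month, cumulatively summed), so every unit's AQI series
  carries a unit root — the temporal non-stationarity the downstream
  screening is supposed to detect — while each month's map stays
  spatially smooth.

Socio-economic covariates are static spatial fields (they barely move
month to month in the real data). The response is generated directly on
the log scale as

    y_it = Σ_k β_k(u_i, v_i, t) x_ikt + ε_it,   ε ~ N(0, noise_sd²),

from user-specified coefficient surfaces (constant, linear in the
coordinates, and/or seasonal in t), which are returned as ground truth so
coefficient-recovery error is measurable. Station series are *exact*
evaluations of the latent AQI field at the station sites, so
interpolation error is measurable too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .models import PanelDataset

__all__ = [
    "CoefficientSurface",
    "CovariateSpec",
    "SyntheticConfig",
    "GroundTruth",
    "StationSeries",
    "generate_panel",
    "generate_station_network",
    "generate_unit_root_series",
]


class ConfigurationError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class CoefficientSurface:
    """β_k(u, v, t) = base + gu·u/Lu + gv·v/Lv + amp·sin(2πt/12 + phase).

    ``gu``/``gv`` are the total change of the coefficient across the
    domain extent in each direction; ``amp`` is the seasonal amplitude.
    All three default to zero, giving a constant coefficient.
    """

    name: str
    base: float
    gu: float = 0.0
    gv: float = 0.0
    amp: float = 0.0
    phase: float = 0.0

    def evaluate(
        self, u: np.ndarray, v: np.ndarray, t: np.ndarray, extent: tuple[float, float]
    ) -> np.ndarray:
        return (
            self.base
            + self.gu * u / extent[0]
            + self.gv * v / extent[1]
            + self.amp * np.sin(2 * np.pi * t / 12.0 + self.phase)
        )

    @property
    def is_constant(self) -> bool:
        return self.gu == self.gv == self.amp == 0.0


@dataclass(frozen=True)
class CovariateSpec:
    """A static spatially autocorrelated covariate (mean + GRF·sd)."""

    name: str
    mean: float
    sd: float


def _default_surfaces() -> tuple[CoefficientSurface, ...]:
    # Magnitudes follow the scale of the published domestic-violence model:
    # positive AQI effect, stronger in winter (southern hemisphere, phase
    # shifted so the peak lands mid-year) and in the urban (east) end.
    return (
        CoefficientSurface("intercept", base=0.9),
        CoefficientSurface("aqi", base=0.015, gu=0.01, amp=0.005, phase=-math.pi / 2),
        CoefficientSurface("unemployment", base=0.033),
        CoefficientSurface("income", base=-0.0003),
    )


def _default_covariates() -> tuple[CovariateSpec, ...]:
    # Scales follow the study region's descriptive statistics: unemployment
    # ~6% and weekly income ~668 AUD.
    return (
        CovariateSpec("unemployment", mean=6.1, sd=2.0),
        CovariateSpec("income", mean=668.0, sd=150.0),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study region.

    Defaults mirror the target study: 129 units × 36 months, 87 stations,
    a monthly AQI averaging ~40 index points with seasonal swing and a
    random-walk drift, and log-scale responses with moderate noise.
    """

    n_units: int = 129
    n_months: int = 36
    n_stations: int = 87
    domain_extent: tuple[float, float] = (400_000.0, 300_000.0)  # metres
    spatial_range: float = 80_000.0  # GRF correlation range, metres
    aqi_mean: float = 40.0
    aqi_spatial_sd: float = 8.0
    seasonal_amplitude: float = 5.0
    seasonal_phase: float = -math.pi / 2  # peak mid-year: southern winter
    unit_root_sd: float = 4.0
    noise_sd: float = 0.15
    covariates: tuple[CovariateSpec, ...] = field(default_factory=_default_covariates)
    coefficient_surfaces: tuple[CoefficientSurface, ...] = field(
        default_factory=_default_surfaces
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1 or self.n_months < 1 or self.n_stations < 1:
            raise ConfigurationError("n_units, n_months, n_stations must be >= 1")
        if min(self.domain_extent) <= 0:
            raise ConfigurationError("domain_extent must have positive area")
        if self.unit_root_sd < 0 or self.noise_sd < 0 or self.aqi_spatial_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if self.spatial_range <= 0:
            raise ConfigurationError("spatial_range must be > 0")
        names = {s.name for s in self.coefficient_surfaces}
        needed = {"intercept", "aqi", *(c.name for c in self.covariates)}
        if names != needed:
            raise ConfigurationError(
                f"coefficient surfaces {sorted(names)} must match covariates "
                f"{sorted(needed)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "covariates" in raw:
            raw["covariates"] = tuple(CovariateSpec(**c) for c in raw["covariates"])
        if "coefficient_surfaces" in raw:
            raw["coefficient_surfaces"] = tuple(
                CoefficientSurface(**s) for s in raw["coefficient_surfaces"]
            )
        if "domain_extent" in raw:
            raw["domain_extent"] = tuple(raw["domain_extent"])
        return cls(**raw)


@dataclass(frozen=True)
class StationSeries:
    """One monitoring station: coordinates and a monthly value series."""

    station_id: str
    u: float
    v: float
    values: np.ndarray  # length n_months


@dataclass(frozen=True)
class GroundTruth:
    """The latent quantities behind a generated panel.

    ``beta_surface`` maps design names (intercept + covariates) to
    (n_units, n_months) coefficient arrays; ``station_values`` holds the
    exact latent AQI field at the station sites, (n_stations, n_months);
    ``unit_aqi`` is the same field at the unit centroids.
    """

    beta_surface: Mapping[str, np.ndarray]
    station_values: np.ndarray
    station_coords: np.ndarray  # (n_stations, 2)
    unit_aqi: np.ndarray  # (n_units, n_months)
    unit_coords: np.ndarray  # (n_units, 2)

    def beta_frame(self) -> pd.DataFrame:
        n_units, n_months = self.unit_aqi.shape
        rows = {
            "unit_idx": np.repeat(np.arange(n_units), n_months),
            "t": np.tile(np.arange(n_months), n_units),
        }
        for name, surface in self.beta_surface.items():
            rows[f"beta_{name}"] = surface.reshape(-1)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# field machinery


def _unit_layout(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid centroids: near-regular coverage, no coincident sites."""
    Lu, Lv = config.domain_extent
    ncol = int(np.ceil(np.sqrt(config.n_units * Lu / Lv)))
    nrow = int(np.ceil(config.n_units / ncol))
    iu, iv = np.meshgrid(np.arange(ncol), np.arange(nrow))
    cell = np.column_stack([iu.ravel(), iv.ravel()])[: config.n_units]
    du, dv = Lu / ncol, Lv / nrow
    centers = (cell + 0.5) * np.array([du, dv])
    jitter = rng.uniform(-0.3, 0.3, size=centers.shape) * np.array([du, dv])
    return centers + jitter


def _gaussian_field(
    sites: np.ndarray, spatial_range: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance GRF draw with exponential covariance exp(-d/range)."""
    diff = sites[:, None, :] - sites[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    cov = np.exp(-dist / spatial_range)
    cov[np.diag_indices_from(cov)] += 1e-10  # numerical jitter
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(len(sites))


def _latent_aqi(
    config: SyntheticConfig,
    unit_coords: np.ndarray,
    station_coords: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent AQI field at units and stations, shapes (n_sites, n_months)."""
    sites = np.vstack([unit_coords, station_coords])
    diff = sites[:, None, :] - sites[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    cov = np.exp(-dist / config.spatial_range)
    cov[np.diag_indices_from(cov)] += 1e-10
    chol = np.linalg.cholesky(cov)

    spatial = chol @ rng.standard_normal(len(sites))
    t = np.arange(config.n_months)
    seasonal = config.seasonal_amplitude * np.sin(
        2 * np.pi * t / 12.0 + config.seasonal_phase
    )
    # per-site random walks with spatially correlated monthly innovations:
    # each month's innovation map is itself a smooth GRF draw
    innovations = config.unit_root_sd * (
        chol @ rng.standard_normal((len(sites), config.n_months))
    )
    walk = np.cumsum(innovations, axis=1)
    field_all = (
        config.aqi_mean
        + config.aqi_spatial_sd * spatial[:, None]
        + seasonal[None, :]
        + walk
    )
    n_u = len(unit_coords)
    return field_all[:n_u], field_all[n_u:]


# ---------------------------------------------------------------------------
# public generators


def generate_panel(config: SyntheticConfig) -> tuple[PanelDataset, GroundTruth]:
    """Generate a (unit, month) panel plus its generating ground truth.

    The record count is exactly ``n_units × n_months``. With
    ``noise_sd=0`` and constant coefficient surfaces the response is
    exactly Xβ at every record, so OLS recovers β to machine precision.
    Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    unit_coords = _unit_layout(config, rng)
    station_coords = _station_layout(config, rng)
    unit_aqi, station_values = _latent_aqi(config, unit_coords, station_coords, rng)

    n_u, n_m = config.n_units, config.n_months
    covariate_values: dict[str, np.ndarray] = {"aqi": unit_aqi}
    for cov in config.covariates:
        static = cov.mean + cov.sd * _gaussian_field(
            unit_coords, config.spatial_range, rng
        )
        covariate_values[cov.name] = np.tile(static[:, None], (1, n_m))

    uu = np.repeat(unit_coords[:, 0], n_m)
    vv = np.repeat(unit_coords[:, 1], n_m)
    tt = np.tile(np.arange(n_m), n_u)

    beta_surface: dict[str, np.ndarray] = {}
    response = np.zeros(n_u * n_m)
    for surface in config.coefficient_surfaces:
        beta = surface.evaluate(uu, vv, tt, config.domain_extent)
        beta_surface[surface.name] = beta.reshape(n_u, n_m)
        x = (
            np.ones(n_u * n_m)
            if surface.name == "intercept"
            else covariate_values[surface.name].reshape(-1)
        )
        response += beta * x
    response += rng.normal(0.0, config.noise_sd, size=n_u * n_m)

    covariate_names = tuple(["aqi"] + [c.name for c in config.covariates])
    frame = pd.DataFrame(
        {
            "unit_id": np.repeat(
                [f"LGA{j:03d}" for j in range(n_u)], n_m
            ),
            "u": uu,
            "v": vv,
            "t": tt,
            "response": response,
            **{name: covariate_values[name].reshape(-1) for name in covariate_names},
        }
    )
    panel = PanelDataset(frame, covariate_names)
    truth = GroundTruth(
        beta_surface=beta_surface,
        station_values=station_values,
        station_coords=station_coords,
        unit_aqi=unit_aqi,
        unit_coords=unit_coords,
    )
    return panel, truth


def _station_layout(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    Lu, Lv = config.domain_extent
    return rng.uniform([0, 0], [Lu, Lv], size=(config.n_stations, 2))


def generate_station_network(config: SyntheticConfig) -> list[StationSeries]:
    """Monitoring-station series: exact draws of the latent AQI field.

    Uses the same seed path as :func:`generate_panel`, so the stations
    returned here observe exactly the field whose unit-centroid values sit
    in the panel — interpolation error against ``GroundTruth.unit_aqi`` is
    therefore a true error.
    """
    _, truth = generate_panel(config)
    return [
        StationSeries(
            station_id=f"ST{j:03d}",
            u=float(truth.station_coords[j, 0]),
            v=float(truth.station_coords[j, 1]),
            values=truth.station_values[j].copy(),
        )
        for j in range(config.n_stations)
    ]


def generate_unit_root_series(n: int, sd: float, seed: int) -> np.ndarray:
    """A pure random walk: cumulative sum of n iid N(0, sd²) innovations."""
    if n < 2:
        raise ValueError("need n >= 2")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    return np.cumsum(rng.normal(0.0, sd, size=n))


def stations_to_frame(stations: Sequence[StationSeries]) -> pd.DataFrame:
    """Long-format station table (station_id, u, v, t, value)."""
    rows = []
    for s in stations:
        for t, value in enumerate(s.values):
            rows.append(
                {"station_id": s.station_id, "u": s.u, "v": s.v, "t": t, "value": value}
            )
    return pd.DataFrame(rows)
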