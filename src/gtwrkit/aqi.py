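"""Air-quality index construction from pollutant concentrations.

The daily index at a station is the maximum, over the pollutants measured
that day, of the ratio of the period-averaged concentration to its NSW
regulatory standard concentration, scaled by 100:

    AQI = max_k ( p_k / ps_k ) * 100

An index of 100 therefore means the worst pollutant sits exactly at its
standard. The index is banded into six status categories ("Very good" up
to "Hazardous") and aggregated to station-month means for use as a panel
covariate.

Concentrations are assumed to be already averaged over each pollutant's
regulatory averaging period (8 h CO, 1 h NO2/O3/SO2, 4 h O3, 24 h
particulates) and expressed in the standard's units (ppm for gases,
µg/m³ for particulates).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "POLLUTANT_ORDER",
    "STATUS_BANDS",
    "PollutantStandard",
    "PollutantDay",
    "AqiValue",
    "default_standards",
    "compute_daily_aqi",
    "classify_status",
    "monthly_aqi",
    "read_concentration_csv",
    "daily_aqi_table",
]

#: Fixed pollutant order used for deterministic tie-breaking of the
#: dominant pollutant.
POLLUTANT_ORDER: tuple[str, ...] = (
    "CO",
    "NO2",
    "O3_1h",
    "O3_4h",
    "SO2",
    "PM10",
    "PM2.5",
)

#: Status bands as (upper_edge, label); values are banded with half-open
#: intervals so that non-integer indices classify consistently with the
#: integer band edges 0-33, 34-66, 67-99, 100-149, 150-200, 200+.
STATUS_BANDS: tuple[tuple[float, str], ...] = (
    (33.5, "Very good"),
    (66.5, "Good"),
    (99.5, "Fair"),
    (149.5, "Poor"),
    (200.5, "Very poor"),
    (float("inf"), "Hazardous"),
)


class MissingDataError(ValueError):
    """No usable pollutant concentration on a day."""


class ConfigurationError(ValueError):
    """Inconsistent standards/configuration input."""


@dataclass(frozen=True)
class PollutantStandard:
    """Regulatory standard concentration for one pollutant.

    Parameters
    ----------
    pollutant
        Name, one of :data:`POLLUTANT_ORDER`.
    averaging_period_hours
        Averaging period of the standard, in hours.
    standard_concentration
        The standard concentration ``ps`` (> 0) in the pollutant's units.
    """

    pollutant: str
    averaging_period_hours: float
    standard_concentration: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.standard_concentration <= 0:
            raise ConfigurationError(
                f"standard concentration for {self.pollutant} must be > 0"
            )


@dataclass(frozen=True)
class PollutantDay:
    """One station-day of period-averaged pollutant concentrations."""

    station_id: str
    date: _dt.date
    concentrations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.concentrations.items():
            if value < 0:
                raise ValueError(f"negative concentration for {name}: {value}")


@dataclass(frozen=True)
class AqiValue:
    """Daily AQI with its status band and the pollutant attaining the max."""

    value: float
    status: str
    dominant_pollutant: str


def default_standards() -> list[PollutantStandard]:
    """Load the NSW standard concentrations shipped with the package."""
    with resources.files("gtwrkit.data").joinpath("nsw_aqi_standards.csv").open() as fh:
        table = pd.read_csv(fh)
    return [
        PollutantStandard(
            pollutant=row.pollutant,
            averaging_period_hours=float(row.averaging_period_hours),
            standard_concentration=float(row.standard_concentration),
            units=row.units,
        )
        for row in table.itertuples()
    ]


def classify_status(value: float) -> str:
    """Map an AQI value to its NSW status band label."""
    if value < 0:
        raise ValueError(f"AQI value must be non-negative, got {value}")
    for edge, label in STATUS_BANDS:
        if value < edge:
            return label
    raise AssertionError("unreachable")  # pragma: no cover


def compute_daily_aqi(
    day: PollutantDay, standards: Sequence[PollutantStandard] | None = None
) -> AqiValue:
    """Daily AQI for one station-day: max over pollutants of (p/ps)*100.

    Pollutants absent from ``day.concentrations`` are skipped. Ties in the
    maximum ratio are broken by the fixed order of :data:`POLLUTANT_ORDER`,
    so the dominant pollutant is deterministic.
    """
    if standards is None:
        standards = default_standards()
    ps = {s.pollutant: s.standard_concentration for s in standards}

    present = [p for p in day.concentrations if day.concentrations[p] is not None]
    if not present:
        raise MissingDataError(
            f"no pollutant concentrations for station {day.station_id} on {day.date}"
        )
    missing_standard = [p for p in present if p not in ps]
    if missing_standard:
        raise ConfigurationError(
            f"no standard concentration for pollutant(s) {missing_standard}"
        )

    order = {name: i for i, name in enumerate(POLLUTANT_ORDER)}
    best_value = -np.inf
    best_pollutant = None
    for name in sorted(present, key=lambda p: order.get(p, len(order))):
        ratio = day.concentrations[name] / ps[name] * 100.0
        if ratio > best_value:
            best_value = ratio
            best_pollutant = name
    return AqiValue(
        value=float(best_value),
        status=classify_status(float(best_value)),
        dominant_pollutant=best_pollutant,
    )


def monthly_aqi(
    daily: Iterable[tuple[_dt.date, float]],
    months: Sequence[tuple[int, int]] | None = None,
) -> pd.Series:
    """Aggregate daily AQI values to monthly arithmetic means.

    Parameters
    ----------
    daily
        Iterable of (date, aqi_value) pairs for one station.
    months
        Optional explicit list of (year, month) pairs the output should
        cover; months with no observations come out as NaN. When omitted,
        the observed span of months is used.

    Returns
    -------
    pandas.Series indexed by monthly period, value = mean of daily values.
    """
    records = list(daily)
    if not records:
        return pd.Series(dtype=float)
    frame = pd.DataFrame(records, columns=["date", "aqi"])
    frame["period"] = pd.PeriodIndex(pd.to_datetime(frame["date"]), freq="M")
    means = frame.groupby("period")["aqi"].mean()
    if months is not None:
        index = pd.PeriodIndex(
            [pd.Period(year=y, month=m, freq="M") for y, m in months]
        )
    else:
        index = pd.period_range(means.index.min(), means.index.max(), freq="M")
    return means.reindex(index)


def read_concentration_csv(path) -> list[PollutantDay]:
    """Read station-day concentrations from long CSV.

    Expected columns: ``station_id,date,pollutant,value``.
    """
    table = pd.read_csv(path, parse_dates=["date"])
    days: list[PollutantDay] = []
    for (station, date), group in table.groupby(["station_id", "date"]):
        days.append(
            PollutantDay(
                station_id=str(station),
                date=date.date(),
                concentrations=dict(zip(group["pollutant"], group["value"])),
            )
        )
    return days


def daily_aqi_table(
    days: Iterable[PollutantDay],
    standards: Sequence[PollutantStandard] | None = None,
) -> pd.DataFrame:
    """Compute daily AQI for many station-days, dropping fully-missing days."""
    if standards is None:
        standards = default_standards()
    rows = []
    for day in days:
        if not day.concentrations:
            continue
        aqi = compute_daily_aqi(day, standards)
        rows.append(
            {
                "station_id": day.station_id,
                "date": day.date,
                "aqi": aqi.value,
                "status": aqi.status,
                "dominant_pollutant": aqi.dominant_pollutant,
            }
        )
    return pd.DataFrame(rows)
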