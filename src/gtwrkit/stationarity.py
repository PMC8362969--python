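"""Per-unit augmented Dickey–Fuller screening of panel covariates.

Each areal unit's monthly series for a covariate is tested for a unit
root with the ADF regression (constant, no trend)

    ΔX_t = c + γ X_{t−1} + Σ_j φ_j ΔX_{t−j} + ε_t,

lag order chosen by AIC. The null hypothesis is a unit root
(non-stationarity); p-values come from the MacKinnon response-surface
approximation. A regional summary reports the share of units that *fail
to reject* at level α — when a majority of units accept the null, the
variable is labelled non-stationary region-wide and a space–time model
(GTWR) is preferred over purely cross-sectional fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import adfuller

__all__ = ["AdfResult", "RegionalStationaritySummary", "adf_test", "regional_summary", "panel_adf_screen"]


class DegenerateSeriesError(ValueError):
    """Constant or too-short series: ADF regression undefined."""


@dataclass(frozen=True)
class AdfResult:
    """ADF statistic, MacKinnon p-value, selected lags and the α-verdict."""

    statistic: float
    p_value: float
    lags: int
    stationary: bool
    alpha: float = 0.05


@dataclass(frozen=True)
class RegionalStationaritySummary:
    """Distribution of per-unit ADF outcomes for one variable."""

    variable: str
    min_statistic: float
    median_statistic: float
    max_statistic: float
    accept_rate: float  # percent of units with p >= alpha
    verdict: str  # "stationary" | "nonstationary"


def adf_test(
    series: Sequence[float], max_lags: int = 4, alpha: float = 0.05
) -> AdfResult:
    """ADF unit-root test with constant, AIC lag selection over 0..max_lags.

    ``stationary`` is True when the unit-root null is rejected
    (p < alpha).
    """
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if len(x) < max_lags + 10:
        raise ValueError(
            f"series of length {len(x)} too short for max_lags={max_lags}"
        )
    if np.ptp(x) == 0.0:
        raise DegenerateSeriesError("constant series has no unit-root regression")
    stat, pvalue, usedlag, *_ = adfuller(
        x, maxlag=max_lags, regression="c", autolag="AIC"
    )
    return AdfResult(
        statistic=float(stat),
        p_value=float(pvalue),
        lags=int(usedlag),
        stationary=bool(pvalue < alpha),
        alpha=alpha,
    )


def regional_summary(
    results: Mapping[str, AdfResult],
    alpha: float = 0.05,
    variable: str = "",
    verdict_threshold: float = 50.0,
) -> RegionalStationaritySummary:
    """Summarise per-unit ADF results into a regional verdict.

    ``accept_rate`` is the percentage of units whose p-value is ≥ α (the
    unit-root null is accepted). The variable is declared non-stationary
    when the accept rate exceeds ``verdict_threshold`` percent.
    """
    if not results:
        raise ValueError("no per-unit results supplied")
    stats = np.array([r.statistic for r in results.values()])
    accepts = np.array([r.p_value >= alpha for r in results.values()])
    accept_rate = float(100.0 * accepts.mean())
    return RegionalStationaritySummary(
        variable=variable,
        min_statistic=float(stats.min()),
        median_statistic=float(np.median(stats)),
        max_statistic=float(stats.max()),
        accept_rate=accept_rate,
        verdict="nonstationary" if accept_rate > verdict_threshold else "stationary",
    )


def panel_adf_screen(
    panel_frame: pd.DataFrame,
    variables: Sequence[str],
    max_lags: int = 4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the ADF screen on each variable of a (unit, month) panel.

    Returns one row per variable: min/median/max ADF statistic over units,
    the accept rate (percent of units failing to reject the unit root) and
    the regional verdict. Constant per-unit series are skipped; the lag
    bound is clamped so short panels remain testable, and variables whose
    series are too short for any lag order are omitted entirely.
    """
    rows = []
    n_per_unit = int(panel_frame.groupby("unit_id").size().min())
    eff_lags = min(max_lags, max(n_per_unit - 10, 0))
    if n_per_unit < 10:
        return pd.DataFrame(
            columns=[
                "variable", "min_statistic", "median_statistic",
                "max_statistic", "accept_rate", "verdict",
            ]
        )
    for var in variables:
        per_unit: dict[str, AdfResult] = {}
        for unit, group in panel_frame.groupby("unit_id"):
            series = group.sort_values("t")[var].to_numpy()
            try:
                per_unit[str(unit)] = adf_test(series, max_lags=eff_lags, alpha=alpha)
            except DegenerateSeriesError:
                continue
        if not per_unit:
            continue
        summary = regional_summary(per_unit, alpha=alpha, variable=var)
        rows.append(
            {
                "variable": var,
                "min_statistic": summary.min_statistic,
                "median_statistic": summary.median_statistic,
                "max_statistic": summary.max_statistic,
                "accept_rate": summary.accept_rate,
                "verdict": summary.verdict,
            }
        )
    return pd.DataFrame(rows)
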