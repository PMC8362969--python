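# gtwrkit

Spatio-temporal panel regression for areal environmental-health analysis:
air-quality-index (AQI) construction, station-to-area geostatistical
interpolation, per-area unit-root screening, and geographically &
temporally weighted regression (GTWR) with kernel bandwidth and
space–time scale selection.

The intended setting is a region divided into areal units (e.g. local
government areas) observed monthly, where a sparse monitoring network
measures air quality and the analyst wants to relate an area-level
response (such as a log crime rate) to air quality and socio-economic
covariates — allowing the regression coefficients to vary over space
*and* time.

## The model

A global ordinary-least-squares fit assumes one coefficient vector for
the whole panel. GTWR instead estimates, at every record *i* with
coordinates (uᵢ, vᵢ) and month tᵢ,

    Yᵢ = β₀(uᵢ, vᵢ, tᵢ) + Σₖ βₖ(uᵢ, vᵢ, tᵢ) Xᵢₖ + εᵢ,

    β̂(uᵢ, vᵢ, tᵢ) = (Xᵀ Wᵢ X)⁻¹ Xᵀ Wᵢ Y,

where Wᵢ is diagonal with Gaussian kernel weights

    wᵢⱼ = exp(−d²ᵢⱼ / h²),   d²ᵢⱼ = (uᵢ−uⱼ)² + (vᵢ−vⱼ)² + τ (tᵢ−tⱼ)².

The spatial scale is normalised to 1; τ = μ/λ converts squared month
differences into squared metres, so τ = 0 recovers purely spatial GWR.
The bandwidth h and the ratio τ are chosen by leave-one-out
cross-validation, CV(h) = Σᵢ (yᵢ − ŷ₍≠ᵢ₎)², and fits are compared by R²,
the hat-matrix trace (effective parameters) and the corrected AIC.

Supporting stages:

- **aqi** — daily index = maxₖ (pₖ/psₖ)×100 against the NSW standard
  concentrations, banded Very good → Hazardous, averaged to months.
- **interpolation** — inverse-distance weighting and ordinary kriging
  (spherical semivariogram, k = 12 nearest stations) from stations to
  unit centroids, compared by leave-one-out MAPE.
- **stationarity** — per-unit augmented Dickey–Fuller tests (constant,
  AIC lag selection) with a regional accept-rate summary; a majority of
  units accepting the unit-root null argues for the space–time model.
- **diagnostics** — VIF collinearity screening, per-month Moran's I of
  OLS residuals (permutation test), and the spatial-nonstationarity
  comparison of local-coefficient interquartile ranges against twice the
  OLS standard errors.
- **synthetic** — seeded study-region generator (129 units × 36 months,
  87 stations by default) with known coefficient surfaces, so every
  stage can be validated against ground truth.

## Worked example

`examples/04_fit_models.py` generates a study-sized panel whose AQI
coefficient surface is β_aqi(u, v, t) = 0.5 + u/extent + 0.2·sin(2πt/12)
(stronger in the east, peaking seasonally), then fits OLS and GTWR:

```
selected bandwidth h = 30 km, tau = 1e+09
OLS   R2 = 0.769  AICc = 35767.3
GTWR  R2 = 0.999  AICc = 18763.4  trace(S) = 1905.0
beta_aqi recovery: corr = 0.939, RMSE GTWR = 0.117 vs OLS 0.337
```

The local model tracks the true coefficient surface (correlation 0.94
between β̂ and truth, one value per unit-month) with a third of the
global model's RMSE — the global fit can only report the surface's
average. τ = 10⁹ m²/month² means two records one month apart are
down-weighted like two records ~32 km apart.

The other examples cover daily/monthly AQI computation
(`01_daily_aqi.py`), IDW-vs-kriging selection by cross-validation MAPE
(`02_interpolate_stations.py`), the ADF screen (`03_unit_root_screen.py`)
and the end-to-end pipeline with CSV/JSON artifacts
(`05_full_pipeline.py`). The same stages are scriptable through a thin
CLI: `gtwrkit simulate|aqi|interpolate|adf|fit|diagnose|run`.

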