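# Methods

This note records the statistical models implemented in gtwrkit, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that affect results.

## Air-quality index

The daily index at a station is `max_k (p_k / ps_k) × 100` over the
pollutants measured that day, where `ps_k` is the NSW standard
concentration shipped in `gtwrkit/data/nsw_aqi_standards.csv` (CO 9.0
ppm/8 h; NO₂ 0.12 ppm/1 h; O₃ 0.10 ppm/1 h and 0.08 ppm/4 h; SO₂ 0.20
ppm/1 h; PM10 50 µg/m³/1 day; PM2.5 25 µg/m³/1 day). Inputs are assumed
already averaged over each pollutant's regulatory period and expressed in
the standard's units (the pphm reporting format used by some portals must
be converted upstream). Missing pollutants on a day are skipped — the max
runs over what was measured — and fully missing days are dropped before
monthly aggregation.

Status bands use half-open edges [0, 33.5), [33.5, 66.5), [66.5, 99.5),
[99.5, 149.5), [149.5, 200.5), [200.5, ∞) so that non-integer indices
classify consistently with the integer band labels 0–33 … 200+. Ties for
the dominant pollutant break by the fixed order CO, NO₂, O₃(1h), O₃(4h),
SO₂, PM10, PM2.5.

Monthly aggregation is the arithmetic mean of available daily values.
The max and median are defensible alternatives; the mean was chosen
because it is the convention for monthly exposure covariates and keeps
the monthly scale comparable with published monthly AQI summaries
(regional means around 40 index points).

## Interpolation

Stations rarely coincide with areal-unit centroids, so the AQI covariate
is interpolated per month, independently across months (no space–time
kriging).

- **IDW**: weights d⁻² over the k = 12 nearest stations. "12 nearby
  stations" is interpreted as a neighbour count, not a metric radius,
  because a count is what is specified. A query within 10⁻⁹ m of a
  station returns that station's value.
- **Ordinary kriging**: spherical semivariogram
  γ(h) = c₀ + c·(1.5 h/a − 0.5 (h/a)³) for h < a, fitted to the Matheron
  empirical variogram (15 equal-width bins up to half the maximum
  pairwise distance) by least squares weighted by √(pair count). The OK
  system over the k nearest stations enforces Σλ = 1 via a Lagrange
  multiplier; duplicate coordinates are averaged before a retry; the
  kriging variance is clamped at zero. With zero nugget the predictor is
  exact at station sites.
- **Selection**: leave-one-out MAPE per month plus the pooled mean over
  months (the per-month/pooled ambiguity is resolved by reporting both).
  Observations equal to zero are excluded from the MAPE with a logged
  count. On rough short-range fields IDW and kriging perform comparably;
  kriging's advantage appears on smooth, long-range fields, which is the
  regime the selection rule is meant to detect.

The module predicts at unit centroids only; raster surfaces are out of
scope since the downstream regression consumes one value per unit-month.

## Unit-root screening

Each unit's monthly series is tested with the ADF regression with
constant and no trend,

    ΔX_t = c + γ X_{t−1} + Σ_j φ_j ΔX_{t−j} + ε_t,

lag order selected by AIC over 0..4 (statsmodels `adfuller`, MacKinnon
p-values). Four lags is the most a 36-month series supports; for shorter
panels the bound is clamped to length − 10 and panels under 10 months are
not screened. The regional summary reports the percentage of units whose
p-value is ≥ α (the unit-root null is *accepted*); a variable is labelled
regionally non-stationary when that accept rate exceeds 50%. The
threshold generalises the narrative rule used with such screens (92%
accepting ⇒ non-stationary; 11% ⇒ stationary; 75% ⇒ non-stationary).

## Local regression models

- **OLS**: statsmodels behind the module surface; residuals are retained
  for Moran's I and the standard errors for the nonstationarity screen.
- **GWR/GTWR**: authored here. At each record the weighted normal
  equations are solved with the full panel reweighted by the Gaussian
  kernel of combined distance d² = Δu² + Δv² + τΔt². The kernel is fixed
  (not adaptive) and Gaussian; the spatial scale is normalised to λ = 1
  so only τ = μ/λ is free; time distance is in integer months. The hat
  diagonal is s_ii = wᵢᵢ xᵢᵀ(XᵀWᵢX)⁻¹xᵢ and trace(S) = Σ s_ii is the
  effective parameter count.
- **AICc**: n·ln(RSS/n) + n·ln 2π + n(n + tr S)/(n − 2 − tr S)
  (Hurvich–Simonoff form); with tr S = k+1 it coincides with the
  classical small-sample AICc, so OLS and local fits are comparable.
- **R²** is 1 − RSS/TSS with TSS about the *global* mean for every model,
  keeping comparisons like-for-like.
- **CV**: leave-one-out sum of squared errors with W_ii forced to zero
  (a sum, not a mean, matching the CV-score convention for bandwidth
  plots).
- **Selection**: golden-section search on h between the minimum
  nearest-neighbour spacing and the domain diameter, inside an outer τ
  grid (default {0} ∪ 10⁻²..10⁶ × spacing²). An explicit `h_grid`
  switches to grid search — the pipeline and the study-scale validation
  use coarse grids (4–6 h values × 4 τ values) as the desk-scale
  default, since the CV surface is smooth and shallow near its minimum.
  A boundary minimum (CV monotone over the range) returns the boundary
  with a warning. With spatially constant true coefficients the CV curve
  flattens: the search may return a large interior h whose CV is within
  a few percent of the flat-kernel limit rather than the boundary
  itself.
- **Degeneracy**: a local system with condition number above 10¹⁰ gets a
  ridge of 10⁻⁸·trace(XᵀWX) and a debug-level log. This occurs when tiny
  bandwidths leave too few effective neighbours, and during CV probing of
  deliberately small h.

Two GWR readings exist for multi-month panels and both are provided:
pooled GTWR with τ = 0 (time ignored), and independent per-month
cross-sectional fits (the pipeline's `gwr_cross_sectional` row, whose CV
is the sum of per-slice CVs).

## Diagnostics

- **VIF**: 1/(1 − R²ⱼ) from regressing covariate j on the rest plus an
  intercept; > 5 flags collinearity; perfectly collinear columns report
  ∞. Invariant to affine rescaling.
- **Moran's I**: I = (n/ΣW)·zᵀWz/zᵀz on row-standardised k = 8
  nearest-neighbour weights (contiguity is unavailable for synthetic
  point layouts; the weight matrix is an argument, so rook/queen weights
  can be supplied). The permutation p-value is one-sided toward
  clustering, since the diagnostic question is whether residuals are
  positively autocorrelated; "clustered" requires I > −1/(n−1) and
  p < 0.05. Residual I is computed per month and summarised as the share
  of significant months, because a pooled I over the panel would mix
  temporal and spatial structure.
- **Nonstationarity screen**: per covariate, the interquartile range of
  GTWR local coefficients and the smallest per-month GWR IQR are compared
  with twice the OLS standard error; the heterogeneity flag is driven by
  the GTWR column (both comparisons are reported). Quartiles use linear
  interpolation (type 7) — the flag can depend on this convention.

## Synthetic study regions

The generator emulates the target study design: 129 units × 36 months
(4,644 records), 87 stations, planar projected coordinates on a
400 × 300 km domain with units on a jittered grid.

The AQI field is

    aqi(s, t) = 40 + 8·G(s) + 5·sin(2πt/12 − π/2) + 4·Σ_{r≤t} G_r(s),

where G and each monthly innovation G_r are unit-variance Gaussian random
fields with exponential covariance (range 80 km), realised exactly by
Cholesky factorisation at the unit centroids and station sites jointly.
The sinusoid peaks mid-year (southern winter); the cumulative spatially
correlated innovations give every unit an integrated (unit-root) series
while keeping each month's map smooth, so interpolation error against the
latent field is measurable. The amplitude/innovation balance (5 vs 4) was
set so the ADF screen accepts the unit-root null for roughly 80% of units
at n = 36 — the qualitative regime the screening stage is designed for; a
stronger seasonal cycle relative to the walk would mask the unit root at
this series length. Station series are exact field evaluations (no
measurement noise).

Socio-economic covariates are static spatial fields (mean 6.1%, sd 2 for
unemployment; mean 668, sd 150 for weekly income), constant over months,
mirroring how slowly such variables move; they are generated
independently of the AQI field (the joint covariate distribution is
unspecified in the emulated design, so independence is the default).
Responses are continuous on the log scale, y = Σ βₖ(u,v,t)xₖ + ε with
ε ~ N(0, noise_sd²) and default noise_sd = 0.15 (≈ R² 0.5–0.8 for the
default surfaces, the range typical of such area-level models).
Coefficient surfaces are constant, linear in the coordinates and/or
sinusoidal in the month index.

What the generator does **not** emulate: realistic coastal/inland
geography and population density, count-valued responses with excess
zeros, covariate correlation, station dropout/missingness, and
measurement error in the stations. Tests passing on these panels
therefore demonstrate correctness of the estimators and calibration of
the tests under the assumed smooth-field data-generating process, not
robustness to real-data pathologies.

## Seasons and the pipeline

Months map to southern-hemisphere seasons (Summer = Dec–Feb, Autumn =
Mar–May, Winter = Jun–Aug, Spring = Sep–Nov); the season year is the
calendar year the month falls in. The pipeline runs simulate/ingest →
interpolate → ADF screen → OLS + per-month GWR + GTWR (with CV-selected
h, τ) → diagnostics → seasonal coefficient export, writing plain
CSV/JSON plus a manifest with the seed and a configuration hash;
identical config and seed reproduce identical bytes. A panel with a
single month degenerates gracefully: τ is inapplicable and is fixed at
zero. For real-data ingestion the pipeline consumes a pre-built panel
CSV; if crime counts are logged upstream, log10(count + 1) is the
documented convention for zero handling.

## Known limitations

- GTWR solves one local system per record; the O(n²k) per-fit cost is
  fine at 4,644 records but the implementation is not tiled for panels
  two orders of magnitude larger.
- Bandwidth search assumes a unimodal CV curve; the golden-section
  search can settle in a shallow local dip on noisy CV surfaces (the
  coarse-grid option is the robust alternative).
- At small panel sizes (tens of units) LOO CV can favour very small
  bandwidths and overfit; surface-recovery claims hold at study scale.
- The kriging neighbourhood reuses a single monthly variogram fit; no
  anisotropy, no co-kriging, no space–time covariance.
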