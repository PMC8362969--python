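"""Regression diagnostics: collinearity, residual spatial autocorrelation,
and the spatial-nonstationarity screen for local coefficients.

* **VIF** — variance inflation factor 1/(1−R²_j) of each covariate
  regressed on the others; values above 5 flag problematic collinearity.
* **Moran's I** — global spatial autocorrelation of (residual) values on a
  row-standardised k-nearest-neighbour weight graph, with a permutation
  p-value. Expected value under spatial randomness is −1/(n−1).
* **Nonstationarity table** — per covariate, the interquartile range of
  the local (GTWR) coefficients and the smallest per-month IQR of
  cross-sectional GWR coefficients, compared against twice the OLS
  standard error; a local coefficient spread exceeding 2×SE(OLS) marks
  the covariate's effect as spatially heterogeneous, justifying a local
  model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .models import LocalFitResult

__all__ = [
    "MoranResult",
    "vif",
    "knn_weights",
    "morans_i",
    "nonstationarity_table",
    "moran_by_month",
]

VIF_FLAG_THRESHOLD = 5.0


@dataclass(frozen=True)
class MoranResult:
    """Moran's I with its permutation p-value (one-sided, clustering)."""

    I: float
    expected_I: float
    p_value: float
    clustered: bool


def vif(design: pd.DataFrame | np.ndarray, names: Sequence[str] | None = None) -> pd.Series:
    """Variance inflation factors for a covariate matrix (no intercept column).

    Each covariate is regressed on all the others plus an intercept;
    VIF_j = 1/(1 − R²_j). A perfectly collinear column comes out as
    ``inf``. Values are invariant to affine rescaling of the covariates.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
    n, k = X.shape
    if k < 2:
        raise ValueError("VIF needs at least 2 covariates")
    if n <= k + 1:
        raise ValueError(f"n={n} too small for {k} covariates")
    out = {}
    for j in range(k):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        tss = float(((yj - yj.mean()) ** 2).sum())
        if tss == 0.0:
            out[names[j]] = np.inf
            continue
        r2 = 1.0 - float(resid @ resid) / tss
        out[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def knn_weights(coords: np.ndarray, k: int = 8) -> np.ndarray:
    """Row-standardised k-nearest-neighbour spatial weight matrix."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n <= k:
        raise ValueError(f"need more than k={k} sites, got {n}")
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    np.fill_diagonal(d, np.inf)
    W = np.zeros((n, n))
    order = np.argsort(d, axis=1, kind="stable")
    rows = np.repeat(np.arange(n), k)
    W[rows, order[:, :k].ravel()] = 1.0 / k
    return W


def morans_i(
    values: np.ndarray,
    weights: np.ndarray,
    n_perm: int = 999,
    seed: int | None = 0,
) -> MoranResult:
    """Global Moran's I with a permutation test for clustering.

    I = (n/ΣW) · zᵀWz / zᵀz with z the centred values. The p-value is the
    one-sided permutation probability of an I at least as large as
    observed (clustering alternative); ``clustered`` requires both
    I > E[I] = −1/(n−1) and p < 0.05.
    """
    z = np.asarray(values, dtype=float)
    W = np.asarray(weights, dtype=float)
    n = len(z)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(z) == 0.0:
        raise ValueError("Moran's I undefined for constant values")
    z = z - z.mean()
    s0 = W.sum()
    denom = float(z @ z)
    I_obs = float(n / s0 * (z @ W @ z) / denom)
    expected = -1.0 / (n - 1)

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        zp = rng.permutation(z)
        I_p = n / s0 * (zp @ W @ zp) / denom
        if I_p >= I_obs:
            count_ge += 1
    p = (count_ge + 1.0) / (n_perm + 1.0)
    return MoranResult(
        I=I_obs,
        expected_I=expected,
        p_value=float(p),
        clustered=bool(I_obs > expected and p < 0.05),
    )


def _iqr(x: np.ndarray) -> float:
    # type-7 (linear interpolation) quartiles
    q1, q3 = np.percentile(x, [25, 75])
    return float(q3 - q1)


def nonstationarity_table(
    gtwr_fit: LocalFitResult,
    gwr_slice_fits: Sequence[LocalFitResult],
    ols_fit: LocalFitResult,
) -> pd.DataFrame:
    """Spatial-nonstationarity screen of local coefficients.

    Per covariate: the IQR of the GTWR local coefficients, the minimum
    over months of the per-month GWR coefficient IQR, and twice the OLS
    standard error; ``heterogeneous`` flags IQR(GTWR) > 2×SE(OLS).
    Record order within each fit is irrelevant (quartiles are order
    statistics).
    """
    if ols_fit.standard_errors is None:
        raise ValueError("OLS fit must carry standard errors")
    names = gtwr_fit.coefficient_names
    for other in (*gwr_slice_fits, ols_fit):
        if other.coefficient_names != names:
            raise ValueError("covariate sets differ between fits")
    rows = []
    for j, name in enumerate(names):
        iqr_gtwr = _iqr(gtwr_fit.coefficients[:, j])
        iqr_gwr_lowest = min(
            _iqr(fit.coefficients[:, j]) for fit in gwr_slice_fits
        ) if gwr_slice_fits else np.nan
        twice_se = 2.0 * float(ols_fit.standard_errors[j])
        rows.append(
            {
                "variable": name,
                "iqr_gtwr": iqr_gtwr,
                "iqr_gwr_lowest": iqr_gwr_lowest,
                "twice_se_ols": twice_se,
                "heterogeneous": bool(iqr_gtwr > twice_se),
            }
        )
    return pd.DataFrame(rows)


def moran_by_month(
    panel_frame: pd.DataFrame,
    residuals: np.ndarray,
    k: int = 8,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Moran's I of residuals computed per month on unit centroids.

    A pooled I over the whole panel would mix temporal and spatial
    structure, so each month is tested separately; the caller can then
    summarise the share of significant months.
    """
    frame = panel_frame.copy()
    frame = frame.assign(_resid=np.asarray(residuals, dtype=float))
    rows = []
    for t, group in frame.groupby("t"):
        coords = group[["u", "v"]].to_numpy(dtype=float)
        W = knn_weights(coords, k=k)
        res = morans_i(group["_resid"].to_numpy(), W, n_perm=n_perm, seed=seed + int(t))
        rows.append(
            {
                "t": int(t),
                "I": res.I,
                "expected_I": res.expected_I,
                "p_value": res.p_value,
                "clustered": res.clustered,
            }
        )
    return pd.DataFrame(rows)
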