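"""Global and locally weighted regression on spatio-temporal panels.

Implements three nested estimators for a panel of areal units observed
monthly:

* **OLS** — one global coefficient vector.
* **GWR** — geographically weighted regression: at each location a weighted
  least-squares fit with Gaussian weights decaying in *spatial* distance,
  giving location-specific coefficients.
* **GTWR** — geographically *and* temporally weighted regression: the
  kernel distance combines space and time,

      d²_ij = (u_i-u_j)² + (v_i-v_j)² + τ (t_i-t_j)²,

  with the spatial scale normalised to 1 and τ = μ/λ the temporal-vs-
  spatial scale ratio. Each record gets its own coefficient vector

      β̂(u_i,v_i,t_i) = (Xᵀ W_i X)⁻¹ Xᵀ W_i y,

  where W_i is diagonal with Gaussian entries exp(-d²_ij / h²).

Bandwidth h (and τ for GTWR) are chosen by leave-one-out cross-validation,
minimising the sum of squared prediction errors CV(h) = Σ_i (y_i - ŷ_{≠i})².
Model fit is summarised by R² (about the global mean, so models are
comparable), the hat-matrix trace (effective number of parameters) and the
corrected AIC.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "PanelDataset",
    "KernelSpec",
    "LocalFitResult",
    "squared_st_distance",
    "kernel_weight",
    "aicc",
    "fit_ols",
    "fit_gtwr",
    "fit_gwr",
    "cv_score",
    "select_bandwidth",
]

_RIDGE_CONDITION_LIMIT = 1e10


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class PanelDataset:
    """A (unit, month) panel with coordinates, response and covariates.

    Parameters
    ----------
    frame
        One row per (unit, month) with columns ``unit_id``, ``u``, ``v``,
        ``t`` (integer month index), the response column and one column per
        covariate. Coordinates are planar projected lengths (metres).
    covariate_names
        Names of the covariate columns entering the design matrix; an
        intercept is always prepended.
    response
        Name of the response column (log-scale crime rate in the intended
        application).
    """

    frame: pd.DataFrame
    covariate_names: tuple[str, ...]
    response: str = "response"

    def __post_init__(self) -> None:
        required = {"unit_id", "u", "v", "t", self.response, *self.covariate_names}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"panel frame is missing columns {sorted(missing)}")
        if self.frame.duplicated(["unit_id", "t"]).any():
            raise ValueError("panel contains duplicate (unit_id, t) pairs")
        coord_var = self.frame.groupby("unit_id")[["u", "v"]].nunique()
        if (coord_var > 1).any().any():
            raise ValueError("coordinates must be constant within each unit")
        cols = ["u", "v", "t", self.response, *self.covariate_names]
        if self.frame[cols].isna().any().any():
            raise ValueError("panel contains missing values")
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of projected coordinates."""
        return self.frame[["u", "v"]].to_numpy(dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.frame["t"].to_numpy(dtype=float)

    @property
    def design(self) -> np.ndarray:
        """(n, k+1) design matrix with a leading intercept column."""
        X = self.frame[list(self.covariate_names)].to_numpy(dtype=float)
        return np.column_stack([np.ones(len(X)), X])

    @property
    def design_names(self) -> tuple[str, ...]:
        return ("intercept", *self.covariate_names)

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.response].to_numpy(dtype=float)

    def time_slice(self, t: int) -> "PanelDataset":
        """Cross-section of the panel at one month."""
        sliced = self.frame[self.frame["t"] == t].reset_index(drop=True)
        if sliced.empty:
            raise ValueError(f"no records at t={t}")
        return PanelDataset(sliced, self.covariate_names, self.response)

    def domain_diameter(self) -> float:
        xy = self.frame.groupby("unit_id")[["u", "v"]].first().to_numpy()
        span = xy.max(axis=0) - xy.min(axis=0)
        return float(np.hypot(*span))

    def nn_spacing(self) -> float:
        """Minimum nearest-neighbour spacing between unit centroids."""
        xy = self.frame.groupby("unit_id")[["u", "v"]].first().to_numpy()
        if len(xy) < 2:
            raise ValueError("need at least 2 units")
        d2 = _pairwise_sq(xy)
        np.fill_diagonal(d2, np.inf)
        return float(np.sqrt(d2.min(axis=1)).min())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path, covariate_names: Sequence[str], response: str = "response"
    ) -> "PanelDataset":
        return cls(pd.read_csv(path), tuple(covariate_names), response)


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian space-time kernel parameters.

    ``spatial_bandwidth`` h is in the units of the projected coordinates;
    ``tau`` = μ/λ (λ fixed at 1) converts squared month differences into
    squared spatial distance, so τ = 0 makes the weights purely spatial.
    """

    spatial_bandwidth: float
    tau: float = 0.0
    kernel: str = "gaussian"

    def __post_init__(self) -> None:
        if self.spatial_bandwidth <= 0:
            raise ValueError("spatial_bandwidth must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.kernel != "gaussian":
            raise ValueError(f"unsupported kernel {self.kernel!r}")


@dataclass
class LocalFitResult:
    """Per-record local coefficients and model-level fit diagnostics."""

    model: str
    coefficient_names: tuple[str, ...]
    coefficients: np.ndarray  # (n, k+1); identical rows for OLS
    fitted: np.ndarray
    residuals: np.ndarray
    hat: np.ndarray  # diagonal of the hat matrix S
    r2: float
    trace_s: float
    aicc: float
    spec: KernelSpec | None = None
    standard_errors: np.ndarray | None = None  # OLS only, (k+1,)
    cv: float | None = None
    frame_index: pd.DataFrame | None = None  # unit_id / t bookkeeping

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)

    def coefficients_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.coefficients, columns=list(self.coefficient_names))
        if self.frame_index is not None:
            out = pd.concat([self.frame_index.reset_index(drop=True), out], axis=1)
        out["fitted"] = self.fitted
        out["residual"] = self.residuals
        out["hat"] = self.hat
        return out


# ---------------------------------------------------------------------------
# kernel primitives


def squared_st_distance(
    a: tuple[float, float, float], b: tuple[float, float, float], tau: float
) -> float:
    """Squared space-time distance (u_a-u_b)² + (v_a-v_b)² + τ(t_a-t_b)²."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    du, dv, dt = a[0] - b[0], a[1] - b[1], a[2] - b[2]
    return du * du + dv * dv + tau * dt * dt


def kernel_weight(sq_dist: float, h: float) -> float:
    """Gaussian kernel weight exp(-d²/h²); 1 at zero distance."""
    if h <= 0:
        raise ValueError("bandwidth must be > 0")
    if np.any(np.asarray(sq_dist) < 0):
        raise ValueError("squared distance must be >= 0")
    return np.exp(-np.asarray(sq_dist) / (h * h))


def aicc(n: int, rss: float, trace_s: float) -> float:
    """Corrected AIC for a local-linear smoother with trace(S) parameters.

    ``n·ln(rss/n) + n·ln(2π) + n·(n + trace_S)/(n − 2 − trace_S)``. For OLS,
    trace_S = k+1 and this coincides with the classical small-sample AICc.
    """
    if n <= trace_s + 2:
        raise ValueError(
            f"effective parameters {trace_s:.2f} too large for n={n} (overfit)"
        )
    if rss <= 0:
        return -np.inf
    return float(
        n * math.log(rss / n)
        + n * math.log(2 * math.pi)
        + n * (n + trace_s) / (n - 2 - trace_s)
    )


def _pairwise_sq(xy: np.ndarray) -> np.ndarray:
    diff = xy[:, None, :] - xy[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


# ---------------------------------------------------------------------------
# global fit


def fit_ols(panel: PanelDataset) -> LocalFitResult:
    """Global ordinary least squares with one coefficient vector.

    Raises a ``ValueError`` naming collinear columns when the design is
    rank deficient.
    """
    X, y = panel.design, panel.y
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n={n} too small for {k} parameters")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        culprits = _collinear_columns(X, panel.design_names)
        raise ValueError(f"rank-deficient design; collinear columns: {culprits}")
    res = sm.OLS(y, X).fit()
    fitted = np.asarray(res.fittedvalues)
    resid = y - fitted
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss
    leverage = np.einsum("ij,ji->i", X, np.linalg.solve(X.T @ X, X.T))
    return LocalFitResult(
        model="ols",
        coefficient_names=panel.design_names,
        coefficients=np.tile(res.params, (n, 1)),
        fitted=fitted,
        residuals=resid,
        hat=leverage,
        r2=r2,
        trace_s=float(k),
        aicc=aicc(n, float(resid @ resid), float(k)),
        standard_errors=np.asarray(res.bse),
        frame_index=panel.frame[["unit_id", "t"]].copy(),
    )


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns representable (to numerical precision) by the other columns."""
    culprits = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        scale = max(float(np.abs(X[:, j]).max()), 1.0)
        if np.abs(resid).max() < 1e-8 * scale:
            culprits.append(names[j])
    return culprits


# ---------------------------------------------------------------------------
# local fits


def _local_solve(
    X: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the weighted normal equations at one regression point.

    Returns (beta, A) where A = XᵀWX. Falls back to a small ridge when the
    local system is numerically singular (condition number > 1e10).
    """
    Xw = X * w[:, None]
    A = Xw.T @ X
    b = Xw.T @ y
    if np.linalg.cond(A) > _RIDGE_CONDITION_LIMIT:
        lam = 1e-8 * np.trace(A)
        logger.debug("near-singular local system; applying ridge %.3e", lam)
        A = A + lam * np.eye(A.shape[0])
    return np.linalg.solve(A, b), A


def _weighted_fit(
    panel: PanelDataset,
    weight_rows: Callable[[int], np.ndarray],
    model: str,
    spec: KernelSpec | None,
) -> LocalFitResult:
    X, y = panel.design, panel.y
    n, k = X.shape
    coefs = np.empty((n, k))
    fitted = np.empty(n)
    hat = np.empty(n)
    for i in range(n):
        w = weight_rows(i)
        beta, A = _local_solve(X, y, w)
        coefs[i] = beta
        fitted[i] = X[i] @ beta
        # s_ii = w_i * x_iᵀ A⁻¹ x_i  (row i of the smoother matrix, entry i)
        hat[i] = w[i] * (X[i] @ np.linalg.solve(A, X[i]))
    resid = y - fitted
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float(resid @ resid)
    trace_s = float(hat.sum())
    return LocalFitResult(
        model=model,
        coefficient_names=panel.design_names,
        coefficients=coefs,
        fitted=fitted,
        residuals=resid,
        hat=hat,
        r2=1.0 - rss / tss,
        trace_s=trace_s,
        aicc=aicc(n, rss, trace_s),
        spec=spec,
        frame_index=panel.frame[["unit_id", "t"]].copy(),
    )


def fit_gtwr(panel: PanelDataset, spec: KernelSpec) -> LocalFitResult:
    """Geographically and temporally weighted regression.

    At every record i the full panel is reweighted by the Gaussian kernel
    of combined space-time distance and a local WLS problem is solved, so
    each (unit, month) gets its own coefficient vector.
    """
    coords, times = panel.coords, panel.times
    h2 = spec.spatial_bandwidth**2

    def weights(i: int) -> np.ndarray:
        du = coords[:, 0] - coords[i, 0]
        dv = coords[:, 1] - coords[i, 1]
        dt = times - times[i]
        d2 = du * du + dv * dv + spec.tau * dt * dt
        return np.exp(-d2 / h2)

    return _weighted_fit(panel, weights, "gtwr", spec)


def fit_gwr(panel: PanelDataset, h: float) -> LocalFitResult:
    """Cross-sectional GWR: purely spatial Gaussian weights.

    Intended for a single time slice; on a multi-month panel it simply
    ignores time, which is identical to GTWR with τ = 0.
    """
    result = fit_gtwr(panel, KernelSpec(spatial_bandwidth=h, tau=0.0))
    result.model = "gwr"
    return result


def cv_score(panel: PanelDataset, spec: KernelSpec, model: str = "gtwr") -> float:
    """Leave-one-out cross-validation score CV(h) = Σ_i (y_i − ŷ_{≠i})².

    The prediction at record i uses the local kernel weights with W_ii
    forced to zero, i.e. the record never explains itself.
    """
    if model not in ("gwr", "gtwr"):
        raise ValueError(f"unknown model {model!r}")
    tau = 0.0 if model == "gwr" else spec.tau
    coords, times = panel.coords, panel.times
    X, y = panel.design, panel.y
    h2 = spec.spatial_bandwidth**2
    total = 0.0
    for i in range(panel.n):
        du = coords[:, 0] - coords[i, 0]
        dv = coords[:, 1] - coords[i, 1]
        dt = times - times[i]
        w = np.exp(-(du * du + dv * dv + tau * dt * dt) / h2)
        w[i] = 0.0
        beta, _ = _local_solve(X, y, w)
        err = y[i] - X[i] @ beta
        total += err * err
    return float(total)


def _golden_section(
    f: Callable[[float], float], lo: float, hi: float, rtol: float = 1e-2
) -> tuple[float, float]:
    """Deterministic golden-section minimisation on [lo, hi].

    Returns (argmin, min). If the best point is at a search boundary a
    warning is emitted (CV monotone over the range).
    """
    invphi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > rtol * (hi - lo):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    candidates = [(fc, c), (fd, d), (f(lo), lo), (f(hi), hi)]
    best_f, best_x = min(candidates, key=lambda p: p[0])
    if best_x in (lo, hi):
        warnings.warn(
            "CV is monotone over the bandwidth search range; returning the "
            f"boundary value h={best_x:.4g}",
            stacklevel=3,
        )
    return best_x, best_f


def select_bandwidth(
    panel: PanelDataset,
    model: str = "gtwr",
    tau_grid: Sequence[float] | None = None,
    h_bounds: tuple[float, float] | None = None,
    h_grid: Sequence[float] | None = None,
    rtol: float = 1e-2,
) -> KernelSpec:
    """Choose the kernel bandwidth (and τ for GTWR) minimising the CV score.

    For each candidate τ (GTWR only; GWR fixes τ = 0) the spatial bandwidth
    is optimised by golden-section search between the minimum nearest-
    neighbour spacing and the domain diameter, unless an explicit ``h_grid``
    is given, in which case a grid search is used instead. Deterministic
    for a given panel.
    """
    if model not in ("gwr", "gtwr"):
        raise ValueError(f"unknown model {model!r}")
    if h_bounds is None:
        h_bounds = (panel.nn_spacing(), panel.domain_diameter())
    if model == "gwr":
        taus: Sequence[float] = [0.0]
    elif tau_grid is not None:
        taus = list(tau_grid)
    else:
        spacing_sq = panel.nn_spacing() ** 2
        taus = [0.0] + [10.0**e * spacing_sq for e in range(-2, 7)]

    best: tuple[float, float, float] | None = None  # (cv, h, tau)
    for tau in taus:

        def cv_of_h(h: float, _tau: float = tau) -> float:
            return cv_score(panel, KernelSpec(h, _tau), model=model)

        if h_grid is not None:
            scores = [(cv_of_h(h), h) for h in h_grid]
            cv_best, h_best = min(scores, key=lambda p: p[0])
        else:
            h_best, cv_best = _golden_section(cv_of_h, *h_bounds, rtol=rtol)
        if best is None or cv_best < best[0]:
            best = (cv_best, h_best, tau)
    assert best is not None
    return KernelSpec(spatial_bandwidth=best[1], tau=best[2])
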