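"""Station-to-centroid spatial interpolation: IDW and ordinary kriging.

Monitoring stations observe the air-quality field at scattered sites; the
regression needs one value per areal unit per month. Two interpolators are
provided and compared by leave-one-out cross-validation MAPE:

* **Inverse distance weighting** over the k nearest stations with weights
  d^(-power), exact at station sites.
* **Ordinary kriging** with a spherical semivariogram fitted to the
  empirical (Matheron) variogram by pair-count-weighted least squares.
  The kriging system enforces weights summing to one (unbiasedness) and
  is exact at station sites when the nugget is zero.

Interpolation is performed independently per month; the neighbourhood is
a k-nearest-station search (default k = 12).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborhoodSpec",
    "VariogramModel",
    "idw_predict",
    "empirical_variogram",
    "fit_spherical_variogram",
    "kriging_predict",
    "mape",
    "loo_mape",
    "interpolate_month",
]

_COINCIDENT = 1e-9


class DegenerateFieldWarning(UserWarning):
    """All station values identical: variogram is pure nugget zero."""


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Search neighbourhood: k nearest stations, IDW decay power."""

    k_neighbors: int = 12
    idw_power: float = 2.0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.idw_power <= 0:
            raise ValueError("idw_power must be > 0")


@dataclass(frozen=True)
class VariogramModel:
    """Spherical semivariogram γ(h).

    γ(h) = nugget + psill · (1.5 h/a − 0.5 (h/a)³) for 0 < h < a, reaching
    the sill nugget + psill at the range a and beyond. γ(0) is reported as
    the nugget (the model's limit from above).
    """

    nugget: float
    partial_sill: float
    range_: float
    model: str = "spherical"

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be >= 0")
        if self.range_ <= 0:
            raise ValueError("range must be > 0")

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        ratio = np.minimum(h / self.range_, 1.0)
        return self.nugget + self.partial_sill * (1.5 * ratio - 0.5 * ratio**3)


def _as_arrays(
    stations: Sequence[tuple[float, float]] | np.ndarray, values: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    coords = np.asarray(stations, dtype=float).reshape(-1, 2)
    vals = np.asarray(values, dtype=float)
    if len(coords) == 0:
        raise ValueError("need at least one station")
    if len(coords) != len(vals):
        raise ValueError("coordinates and values must align")
    return coords, vals


def _nearest(coords: np.ndarray, query: np.ndarray, k: int) -> np.ndarray:
    d = np.hypot(coords[:, 0] - query[0], coords[:, 1] - query[1])
    k = min(k, len(coords))
    idx = np.argpartition(d, k - 1)[:k]
    return idx[np.argsort(d[idx], kind="stable")]


def idw_predict(
    stations, values, query, spec: NeighborhoodSpec = NeighborhoodSpec()
) -> float:
    """Inverse-distance-weighted estimate at ``query``.

    Weighted mean with weights d^(−power) over the k nearest stations; a
    query within 1e-9 of a station returns that station's value exactly.
    """
    coords, vals = _as_arrays(stations, values)
    query = np.asarray(query, dtype=float)
    idx = _nearest(coords, query, spec.k_neighbors)
    d = np.hypot(coords[idx, 0] - query[0], coords[idx, 1] - query[1])
    if d[0] < _COINCIDENT:
        return float(vals[idx[0]])
    w = d ** (-spec.idw_power)
    return float(np.sum(w * vals[idx]) / np.sum(w))


def empirical_variogram(
    stations, values, n_bins: int = 15
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Matheron empirical semivariogram.

    Pairwise half mean squared differences binned into ``n_bins``
    equal-width distance bins up to half the maximum pairwise distance.
    Returns (bin centres, semivariances, pair counts) for non-empty bins.
    """
    coords, vals = _as_arrays(stations, values)
    n = len(coords)
    if n < 5:
        raise ValueError("need at least 5 stations for a variogram")
    iu, ju = np.triu_indices(n, k=1)
    d = np.hypot(coords[iu, 0] - coords[ju, 0], coords[iu, 1] - coords[ju, 1])
    sq = 0.5 * (vals[iu] - vals[ju]) ** 2
    cutoff = d.max() / 2.0
    keep = d <= cutoff
    d, sq = d[keep], sq[keep]
    edges = np.linspace(0.0, cutoff, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    centers, gammas, counts = [], [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        centers.append(d[mask].mean())
        gammas.append(sq[mask].mean())
        counts.append(int(mask.sum()))
    return np.asarray(centers), np.asarray(gammas), np.asarray(counts)


def fit_spherical_variogram(stations, values, n_bins: int = 15) -> VariogramModel:
    """Fit a spherical model to the empirical variogram.

    Least squares on (nugget, partial sill, range), weighted by the square
    root of each bin's pair count. A constant field (all values identical)
    degenerates to a zero pure-nugget model, returned with a warning.
    """
    coords, vals = _as_arrays(stations, values)
    if np.ptp(vals) == 0.0:
        warnings.warn(
            "all station values identical; returning a zero pure-nugget model",
            DegenerateFieldWarning,
            stacklevel=2,
        )
        max_d = cdist(coords, coords).max()
        return VariogramModel(nugget=0.0, partial_sill=0.0, range_=max(max_d, 1.0))
    centers, gammas, counts = empirical_variogram(coords, vals, n_bins=n_bins)
    if len(centers) < 3:
        raise ValueError("need >= 3 non-empty distance bins to fit a variogram")
    sample_var = float(np.var(vals))
    w = np.sqrt(counts)

    def resid(theta: np.ndarray) -> np.ndarray:
        model = VariogramModel(
            nugget=theta[0], partial_sill=theta[1], range_=theta[2]
        )
        return w * (model(centers) - gammas)

    x0 = np.array([0.0, sample_var, centers.max() / 2.0])
    bounds = (
        [0.0, 0.0, centers.min() / 10.0],
        [sample_var * 3.0 + 1e-12, sample_var * 10.0 + 1e-12, centers.max() * 10.0],
    )
    fit = least_squares(resid, x0=np.clip(x0, *bounds), bounds=bounds)
    nugget, psill, rng_ = fit.x
    return VariogramModel(nugget=float(nugget), partial_sill=float(psill), range_=float(rng_))


def _merge_duplicates(
    coords: np.ndarray, vals: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Average values at coincident station coordinates."""
    keep_coords: list[np.ndarray] = []
    keep_vals: list[list[float]] = []
    for xy, val in zip(coords, vals):
        for j, ref in enumerate(keep_coords):
            if np.hypot(*(xy - ref)) < _COINCIDENT:
                keep_vals[j].append(val)
                break
        else:
            keep_coords.append(xy)
            keep_vals.append([val])
    merged = np.array([np.mean(v) for v in keep_vals])
    return np.asarray(keep_coords), merged


def kriging_predict(
    stations,
    values,
    query,
    variogram: VariogramModel,
    spec: NeighborhoodSpec = NeighborhoodSpec(),
) -> tuple[float, float]:
    """Ordinary-kriging estimate and kriging variance at ``query``.

    Solves the OK system over the k nearest stations with a Lagrange
    multiplier enforcing Σλ = 1 (unbiasedness). Duplicate station
    coordinates are averaged and the solve retried; a still-singular
    system raises.
    """
    coords, vals = _as_arrays(stations, values)
    if len(coords) < 2:
        raise ValueError("ordinary kriging needs at least 2 stations")
    query = np.asarray(query, dtype=float)
    idx = _nearest(coords, query, spec.k_neighbors)
    sub_coords, sub_vals = coords[idx], vals[idx]

    for attempt in range(2):
        m = len(sub_coords)
        dmat = cdist(sub_coords, sub_coords)
        gamma = variogram(dmat)
        np.fill_diagonal(gamma, 0.0)
        A = np.zeros((m + 1, m + 1))
        A[:m, :m] = gamma
        A[:m, m] = 1.0
        A[m, :m] = 1.0
        d0 = np.hypot(sub_coords[:, 0] - query[0], sub_coords[:, 1] - query[1])
        g0 = np.where(d0 < _COINCIDENT, 0.0, variogram(d0))
        b = np.concatenate([g0, [1.0]])
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            sol = None
        if sol is not None and np.all(np.isfinite(sol)):
            lam, mu = sol[:m], sol[m]
            estimate = float(lam @ sub_vals)
            variance = float(max(lam @ g0 + mu, 0.0))
            return estimate, variance
        if attempt == 0:
            sub_coords, sub_vals = _merge_duplicates(sub_coords, sub_vals)
            if len(sub_coords) < 2:
                break
    raise np.linalg.LinAlgError("singular kriging system after duplicate merging")


def mape(observed, predicted) -> float:
    """Mean absolute percentage error, in percent.

    Observations equal to zero are excluded from the mean (their relative
    error is undefined); if every observation is zero the MAPE is
    undefined and a ``ValueError`` is raised.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must align")
    keep = obs != 0.0
    n_zero = int((~keep).sum())
    if n_zero:
        logger.info("mape: excluded %d zero-valued observations", n_zero)
    if not keep.any():
        raise ValueError("all observations are zero; MAPE undefined")
    return float(100.0 * np.mean(np.abs(obs[keep] - pred[keep]) / np.abs(obs[keep])))


def loo_mape(
    stations,
    values,
    method: str = "kriging",
    spec: NeighborhoodSpec = NeighborhoodSpec(),
    variogram: VariogramModel | None = None,
) -> float:
    """Leave-one-out cross-validation MAPE, in percent.

    Each station is predicted from all the others; MAPE is
    100 × mean(|obs − pred| / |obs|) over stations with non-zero observed
    values (zeros are excluded and logged).
    """
    coords, vals = _as_arrays(stations, values)
    if len(coords) < 3:
        raise ValueError("need at least 3 stations for cross-validation")
    if method not in ("idw", "kriging"):
        raise ValueError(f"unknown method {method!r}")
    if method == "kriging" and variogram is None:
        variogram = fit_spherical_variogram(coords, vals)
    preds = np.empty(len(coords))
    for i in range(len(coords)):
        rest = np.delete(np.arange(len(coords)), i)
        if method == "idw":
            preds[i] = idw_predict(coords[rest], vals[rest], coords[i], spec)
        else:
            preds[i], _ = kriging_predict(
                coords[rest], vals[rest], coords[i], variogram, spec
            )
    return mape(vals, preds)


def interpolate_month(
    station_coords: np.ndarray,
    station_values: np.ndarray,
    unit_coords: np.ndarray,
    spec: NeighborhoodSpec = NeighborhoodSpec(),
    variogram: VariogramModel | None = None,
) -> pd.DataFrame:
    """Predict one month's field at every unit centroid by IDW and kriging.

    Returns a frame with columns ``value_idw``, ``value_kriging`` and
    ``kriging_variance``, one row per unit.
    """
    if variogram is None:
        variogram = fit_spherical_variogram(station_coords, station_values)
    rows = []
    for xy in np.asarray(unit_coords, dtype=float):
        est_idw = idw_predict(station_coords, station_values, xy, spec)
        est_k, var_k = kriging_predict(
            station_coords, station_values, xy, variogram, spec
        )
        rows.append(
            {"value_idw": est_idw, "value_kriging": est_k, "kriging_variance": var_k}
        )
    return pd.DataFrame(rows)
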