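"""Hourly temperature surfaces from meteorological-station records.

Two-stage procedure: (1) a per-station, per-hour-of-day linear model
``T(h) = a·x + b`` regressing the hour-``h`` temperature on the day's mean
temperature, which turns daily summaries into 24 hourly values; (2) spatial
interpolation of each hour's station values onto a raster grid with
universal kriging — a variogram-modelled residual on top of a low-order
spatial drift.  With a zero nugget the kriging surface honours the station
observations exactly, and the drift constraints make it reproduce exactly
any field lying in the drift space (e.g. a plane under linear drift).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .raster import RasterGrid

__all__ = [
    "StationRecord",
    "VariogramSpec",
    "UniversalKriging",
    "HourlyTemperatureModel",
    "fit_hourly_model",
    "krige_hour",
    "monthly_mean_series",
    "read_stations_csv",
    "write_stations_csv",
]

_TEMP_BOUNDS_C = (-30.0, 50.0)


@dataclass
class StationRecord:
    """One meteorological station: location, altitude and a temperature series.

    ``series`` maps timestamps to air temperature in °C; timestamps must be
    unique and sorted.  Temperatures outside the physical range (−30…50 °C)
    are rejected unless ``allow_out_of_range`` is set.
    """

    station_id: str
    x: float
    y: float
    altitude: float
    series: pd.Series
    allow_out_of_range: bool = False

    def __post_init__(self) -> None:
        s = self.series
        if not isinstance(s.index, pd.DatetimeIndex):
            s = pd.Series(s.values, index=pd.DatetimeIndex(s.index))
        if s.index.has_duplicates:
            raise ValueError(f"station {self.station_id}: duplicate timestamps")
        if not s.index.is_monotonic_increasing:
            s = s.sort_index()
        if not self.allow_out_of_range:
            lo, hi = _TEMP_BOUNDS_C
            bad = s[(s < lo) | (s > hi)]
            if len(bad):
                raise ValueError(
                    f"station {self.station_id}: {len(bad)} temperatures outside "
                    f"[{lo}, {hi}] °C (set allow_out_of_range to keep them)")
        self.series = s

    def value_at(self, when) -> float:
        return float(self.series.loc[pd.Timestamp(when)])


@dataclass
class VariogramSpec:
    """Parametric semivariogram for kriging.

    ``range_`` is the practical range for the bounded models.  ``nugget``
    must be ≥ 0 and ``sill ≥ nugget``; for the ``linear`` model ``sill`` and
    ``range_`` only fix the slope ``(sill − nugget)/range_``.
    """

    model: str = "spherical"
    nugget: float = 0.0
    sill: float = 1.0
    range_: float = 1.0

    _MODELS = ("spherical", "exponential", "gaussian", "linear")

    def __post_init__(self) -> None:
        if self.model not in self._MODELS:
            raise ValueError(f"unknown variogram model {self.model!r}; "
                             f"choose from {self._MODELS}")
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")
        if self.sill < self.nugget:
            raise ValueError("sill must be >= nugget")
        if self.range_ <= 0:
            raise ValueError("range must be > 0")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        """Semivariance γ(h); γ(0) = 0 (exact-interpolation convention)."""
        h = np.asarray(h, dtype=float)
        c = self.sill - self.nugget
        a = self.range_
        if self.model == "spherical":
            hr = np.minimum(h / a, 1.0)
            g = c * (1.5 * hr - 0.5 * hr ** 3)
        elif self.model == "exponential":
            g = c * (1.0 - np.exp(-3.0 * h / a))
        elif self.model == "gaussian":
            g = c * (1.0 - np.exp(-3.0 * (h / a) ** 2))
        else:  # linear
            g = (c / a) * h
        return np.where(h > 0, self.nugget + g, 0.0)


def empirical_variogram(coords: np.ndarray, values: np.ndarray,
                        n_lags: int = 8) -> pd.DataFrame:
    """Binned empirical semivariogram: lag centre, semivariance, pair count."""
    d = pdist(coords)
    gamma = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    edges = np.linspace(0, d.max() * (1 + 1e-9), n_lags + 1)
    idx = np.digitize(d, edges) - 1
    rows = []
    for k in range(n_lags):
        sel = idx == k
        if sel.any():
            rows.append((d[sel].mean(), gamma[sel].mean(), int(sel.sum())))
    return pd.DataFrame(rows, columns=["lag", "semivariance", "n_pairs"])


def fit_variogram(coords: np.ndarray, values: np.ndarray,
                  model: str = "spherical", n_lags: int = 8,
                  nugget: float | None = None) -> VariogramSpec:
    """Weighted-least-squares fit of a variogram model to the empirical cloud.

    Weights are pair counts.  Pass ``nugget=0`` to force exact interpolation.
    """
    emp = empirical_variogram(coords, values, n_lags=n_lags)
    lags = emp["lag"].to_numpy()
    gam = emp["semivariance"].to_numpy()
    w = np.sqrt(emp["n_pairs"].to_numpy(float))
    sill0 = max(gam.max(), 1e-12)
    a0 = max(lags.max() * 0.5, 1e-9)
    fixed_nugget = nugget is not None

    def residuals(theta):
        if fixed_nugget:
            sill, rng = theta
            ng = nugget
        else:
            ng, sill, rng = theta
        spec = VariogramSpec(model=model, nugget=ng, sill=max(sill, ng), range_=rng)
        return w * (spec(lags) - gam)

    if fixed_nugget:
        x0, lb, ub = [sill0, a0], [1e-12, 1e-9], [np.inf, np.inf]
    else:
        x0, lb, ub = [0.0, sill0, a0], [0.0, 1e-12, 1e-9], [np.inf, np.inf, np.inf]
    sol = least_squares(residuals, x0, bounds=(lb, ub))
    if fixed_nugget:
        sill, rng = sol.x
        ng = nugget
    else:
        ng, sill, rng = sol.x
    return VariogramSpec(model=model, nugget=float(ng),
                         sill=float(max(sill, ng)), range_=float(rng))


def _drift_matrix(coords: np.ndarray, drift: str) -> np.ndarray:
    if drift == "constant":
        return np.ones((len(coords), 1))
    if drift == "linear":
        return np.column_stack([np.ones(len(coords)), coords[:, 0], coords[:, 1]])
    raise ValueError(f"unknown drift {drift!r}; choose 'constant' or 'linear'")


class UniversalKriging(BaseEstimator, RegressorMixin):
    """Universal (drift) kriging interpolator, scikit-learn style.

    Parameters
    ----------
    variogram : VariogramSpec or None
        Semivariogram of the residual process.  If None, a model of kind
        ``variogram_model`` is fitted by weighted least squares to the
        empirical variogram of the drift-detrended values.
    variogram_model : str
        Model family used when fitting (``spherical`` by default).
    drift : {"constant", "linear"}
        Spatial trend functions; ``linear`` means 1, x, y.  The constant
        term enforces that kriging weights sum to 1.
    nugget : float or None
        Nugget forced during the fit; ``0.0`` (default) makes the predictor
        an exact interpolator at the stations.

    Attributes
    ----------
    X_ : (n, 2) station coordinates seen in fit.
    y_ : station values.
    variogram_ : the VariogramSpec actually used.
    condition_number_ : condition number of the kriging system.
    """

    def __init__(self, variogram: VariogramSpec | None = None,
                 variogram_model: str = "spherical",
                 drift: str = "linear",
                 nugget: float | None = 0.0,
                 n_lags: int = 8):
        self.variogram = variogram
        self.variogram_model = variogram_model
        self.drift = drift
        self.nugget = nugget
        self.n_lags = n_lags

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(f"X must be (n, 2) coordinates, got {X.shape}")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if len(X) < 4:
            raise ValueError("kriging needs at least 4 stations")
        if not np.all(np.isfinite(y)):
            raise ValueError("station values must be finite")
        d = squareform(pdist(X))
        if np.any(d[np.triu_indices_from(d, k=1)] == 0):
            raise ValueError("duplicate station coordinates")

        F = _drift_matrix(X, self.drift)
        if self.variogram is not None:
            vario = self.variogram
        else:
            # detrend so the variogram describes the residual process
            beta, *_ = np.linalg.lstsq(F, y, rcond=None)
            resid = y - F @ beta
            if np.allclose(resid, 0, atol=1e-10 * max(1.0, np.abs(y).max())):
                # residual process is degenerate (field lies in the drift
                # space); any valid variogram gives the exact answer there,
                # so pick a well-conditioned linear one
                vario = VariogramSpec(model="linear", nugget=0.0, sill=1.0,
                                      range_=float(max(d.max(), 1.0)))
            else:
                vario = fit_variogram(X, resid, model=self.variogram_model,
                                      n_lags=self.n_lags, nugget=self.nugget)

        n, p = len(X), F.shape[1]
        A = np.zeros((n + p, n + p))
        A[:n, :n] = vario(d)
        A[:n, n:] = F
        A[n:, :n] = F.T
        self.condition_number_ = float(np.linalg.cond(A))
        if not np.isfinite(self.condition_number_) or self.condition_number_ > 1e14:
            raise np.linalg.LinAlgError(
                f"singular kriging system (condition number "
                f"{self.condition_number_:.3g}); check station geometry/variogram")
        self.X_, self.y_, self.variogram_, self._A, self._F = X, y, vario, A, F
        return self

    def _solve(self, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Kriging weights λ and Lagrange multipliers μ for each target point."""
        n, p = len(self.X_), self._F.shape[1]
        gamma0 = self.variogram_(cdist(self.X_, X_new))
        f0 = _drift_matrix(X_new, self.drift).T
        b = np.vstack([gamma0, f0])
        sol = np.linalg.solve(self._A, b)
        return sol[:n], sol[n:]

    def predict(self, X, return_std: bool = False):
        check_is_fitted(self, "variogram_")
        X = np.asarray(X, dtype=float)
        lam, mu = self._solve(X)
        pred = lam.T @ self.y_
        if not return_std:
            return pred
        gamma0 = self.variogram_(cdist(self.X_, X))
        f0 = _drift_matrix(X, self.drift).T
        var = np.einsum("ij,ij->j", lam, gamma0) + np.einsum("ij,ij->j", mu, f0)
        return pred, np.sqrt(np.maximum(var, 0.0))

    def weights(self, X) -> np.ndarray:
        """Kriging weights per prediction point, shape (n_stations, n_points)."""
        check_is_fitted(self, "variogram_")
        lam, _ = self._solve(np.asarray(X, dtype=float))
        return lam

    def predict_grid(self, like: RasterGrid) -> RasterGrid:
        """Predict at the cell centers of ``like`` and return a new grid."""
        gx, gy = like.cell_centers()
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        z = self.predict(pts).reshape(like.shape)
        return like.with_values(z, nodata=like.nodata)


class HourlyTemperatureModel(BaseEstimator):
    """Per-station, per-hour linear models T(hour) = a · T_daily + b.

    The regressor ``T_daily`` is the day's mean temperature, computed as the
    mean of the daily minimum and maximum.  One ordinary-least-squares fit
    per station per hour-of-day; hour slots with fewer than 3 observations
    are filled from the nearest populated hour and flagged.

    Attributes
    ----------
    coef_ : dict station_id -> (24, 2) array of (a, b).
    r2_ : dict station_id -> (24,) array of in-sample R².
    filled_hours_ : dict station_id -> sorted list of hour slots that were
        filled from a neighbouring hour.
    """

    def __init__(self, min_obs_per_hour: int = 3):
        self.min_obs_per_hour = min_obs_per_hour

    def fit(self, stations: Sequence[StationRecord], y=None,
            daily_summaries: Mapping[str, pd.Series] | None = None):
        """Fit per-hour lines; ``daily_summaries`` optionally supplies the
        per-day regressor (indexed by date) instead of the min/max mean
        derived from the series itself."""
        self.coef_, self.r2_, self.filled_hours_ = {}, {}, {}
        for st in stations:
            df = pd.DataFrame({"temp": st.series})
            df["date"] = df.index.date
            df["hour"] = df.index.hour
            daily = df.groupby("date")["temp"].agg(["min", "max"])
            if len(daily) < 10:
                raise ValueError(f"station {st.station_id}: needs >=10 days of "
                                 f"data, got {len(daily)}")
            if daily_summaries is not None and st.station_id in daily_summaries:
                daily_mean = daily_summaries[st.station_id]
            else:
                daily_mean = (daily["min"] + daily["max"]) / 2.0
            df["daily_mean"] = df["date"].map(daily_mean)
            df = df.dropna(subset=["daily_mean"])

            coef = np.full((24, 2), np.nan)
            r2 = np.full(24, np.nan)
            for h, g in df.groupby("hour"):
                if len(g) < self.min_obs_per_hour:
                    continue
                coef[h], r2[h] = _ols_line(g["daily_mean"].to_numpy(),
                                           g["temp"].to_numpy())
            missing = np.nonzero(np.isnan(coef[:, 0]))[0]
            have = np.nonzero(~np.isnan(coef[:, 0]))[0]
            if have.size == 0:
                raise ValueError(f"station {st.station_id}: no hour slot has "
                                 f">={self.min_obs_per_hour} observations")
            for h in missing:  # fill from circularly nearest populated hour
                delta = np.minimum((have - h) % 24, (h - have) % 24)
                src = have[np.argmin(delta)]
                coef[h], r2[h] = coef[src], r2[src]
            self.coef_[st.station_id] = coef
            self.r2_[st.station_id] = r2
            self.filled_hours_[st.station_id] = sorted(int(h) for h in missing)
        return self

    def predict(self, station_id: str, daily_mean: float,
                hours: Sequence[int] | None = None) -> np.ndarray:
        check_is_fitted(self, "coef_")
        coef = self.coef_[station_id]
        hrs = np.arange(24) if hours is None else np.asarray(hours, int)
        return coef[hrs, 0] * daily_mean + coef[hrs, 1]


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[tuple[float, float], float]:
    """Slope/intercept by OLS; a degenerate (constant) regressor gives a=0."""
    if np.ptp(x) < 1e-12:
        b = float(np.mean(y))
        ss_res = float(np.sum((y - b) ** 2))
        ss_tot = float(np.sum((y - np.mean(y)) ** 2))
        return (0.0, b), (1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0)
    a, b = np.polyfit(x, y, 1)
    yhat = a * x + b
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return (float(a), float(b)), r2


def fit_hourly_model(stations: Sequence[StationRecord],
                     min_obs_per_hour: int = 3) -> HourlyTemperatureModel:
    """Fit the per-station hourly regression model (thin estimator wrapper)."""
    return HourlyTemperatureModel(min_obs_per_hour=min_obs_per_hour).fit(stations)


def krige_hour(stations: Sequence[StationRecord], values: Sequence[float],
               like: RasterGrid, variogram: VariogramSpec | None = None,
               drift: str = "linear", nugget: float | None = 0.0) -> RasterGrid:
    """Interpolate one hour's station values onto the grid of ``like``."""
    coords = np.array([[s.x, s.y] for s in stations], dtype=float)
    uk = UniversalKriging(variogram=variogram, drift=drift, nugget=nugget)
    uk.fit(coords, np.asarray(values, dtype=float))
    return uk.predict_grid(like)


def monthly_mean_series(surfaces: Mapping[int, Sequence[RasterGrid]],
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Spatio-temporal means of hourly temperature surfaces.

    ``surfaces`` maps month number -> 24 hourly grids (one representative
    diurnal cycle per month).  Returns a per-month table (mean °C and a
    completeness flag: 24 hourly layers present) and the per-hour
    climatology averaged over complete months.  Cells are uniform, so the
    plain mean is area-weighted.
    """
    rows = []
    hourly_acc = np.zeros(24)
    n_complete = 0
    for month in sorted(surfaces):
        grids = list(surfaces[month])
        complete = len(grids) == 24
        means = [float(g.values[g.mask()].mean()) for g in grids]
        rows.append({"month": month, "mean_c": float(np.mean(means)),
                     "complete": complete})
        if complete:
            hourly_acc += np.array(means)
            n_complete += 1
    monthly = pd.DataFrame(rows).set_index("month")
    climatology = pd.Series(hourly_acc / max(n_complete, 1),
                            index=pd.RangeIndex(24, name="hour"), name="mean_c")
    return monthly, climatology


def write_stations_csv(stations: Sequence[StationRecord], path) -> None:
    """CSV with columns station_id, x, y, altitude_m, timestamp, temp_c."""
    frames = [pd.DataFrame({
        "station_id": s.station_id, "x": s.x, "y": s.y, "altitude_m": s.altitude,
        "timestamp": s.series.index.strftime("%Y-%m-%dT%H:%M:%S"),
        "temp_c": s.series.values,
    }) for s in stations]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_stations_csv(path) -> list[StationRecord]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for sid, g in df.groupby("station_id", sort=False):
        out.append(StationRecord(
            station_id=str(sid), x=float(g["x"].iloc[0]), y=float(g["y"].iloc[0]),
            altitude=float(g["altitude_m"].iloc[0]),
            series=pd.Series(g["temp_c"].values,
                             index=pd.DatetimeIndex(g["timestamp"])),
        ))
    return out
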