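"""Per-cell breeding-phenology estimation from snow and NDVI series.

Two estimators:

* :func:`fit_snowmelt` — maximum-likelihood fit of an asymmetric Gaussian
  snow-free probability curve to daily binary snow status (Bernoulli
  likelihood); the snowmelt date is where the fitted curve first reaches
  one third.
* :func:`fit_greenup` — distance-weighted penalized cubic smoothing spline
  through weekly NDVI of a focal cell and its neighbours; green-up is the
  first day on the rising limb exceeding the seasonal start by 15% of the
  start-to-maximum amplitude, interpolated only on snow-free days.

Regional aggregation (median/95% quantile band, pooled-cell OLS year trend)
and the snowmelt/green-up cross-correlation round out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import minimize

from .config import DEFAULTS

__all__ = [
    "SnowmeltFit",
    "GreenupFit",
    "RegionalSummary",
    "fit_snowmelt",
    "fit_greenup",
    "regional_summary",
    "snow_ndvi_correlation",
    "haversine_km",
]

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in kilometres (vectorised)."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlmb = np.deg2rad(np.asarray(lon2, float) - np.asarray(lon1, float))
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


# ---------------------------------------------------------------------------
# snowmelt: asymmetric Gaussian with Bernoulli error
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnowmeltFit:
    p_max: float
    mu: float
    sigma_left: float
    sigma_right: float
    loglik: float
    snowmelt_doy: Optional[float]
    converged: bool


def _asym_gauss(t: np.ndarray, p_max: float, mu: float, sl: float, sr: float) -> np.ndarray:
    sigma = np.where(t < mu, sl, sr)
    return p_max * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _nll(params: np.ndarray, t: np.ndarray, y: np.ndarray) -> float:
    s = _asym_gauss(t, *params)
    s = np.clip(s, 1e-9, 1.0 - 1e-9)
    return -float(np.sum(y * np.log(s) + (1.0 - y) * np.log(1.0 - s)))


def _crossing(p_max: float, mu: float, sigma_left: float, threshold: float, first_doy: float) -> Optional[float]:
    """Smallest series day where the fitted curve reaches ``threshold``."""
    if p_max < threshold:
        return None
    if p_max == threshold:
        return float(mu)
    t = mu - sigma_left * np.sqrt(2.0 * np.log(p_max / threshold))
    return float(max(t, first_doy))


def fit_snowmelt(
    series: pd.DataFrame,
    threshold: float = DEFAULTS["snow_free_threshold"],
    n_starts: int = 4,
) -> SnowmeltFit:
    """Fit the asymmetric-Gaussian snow-free curve to a daily binary series.

    ``series`` needs columns ``doy`` and ``value`` (1 = snow-free).  The
    Bernoulli log-likelihood is maximised by bounded quasi-Newton from a
    small grid of starts (the likelihood can be multimodal on short
    seasons).  ``snowmelt_doy`` is None when the fitted peak never reaches
    the threshold.
    """
    t = series["doy"].to_numpy(float)
    y = series["value"].to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("snow series values must be binary")
    if len(t) < 8:
        raise ValueError("snow series too short to fit")

    free_days = t[y == 1]
    mu_guess = float(np.median(free_days)) if len(free_days) else float(np.median(t))
    p_guess = min(max(float(y.mean()) * 1.5, 0.05), 1.0)
    starts = [
        (p_guess, mu_guess, 20.0, 40.0),
        (p_guess, mu_guess, 60.0, 60.0),
        (1.0, mu_guess + 30.0, 30.0, 60.0),
        (1.0, float(np.median(t)), 45.0, 90.0),
    ][:n_starts]
    bounds = [
        (1e-4, 1.0),
        (t.min() - 60.0, t.max() + 60.0),
        (0.5, 250.0),
        (0.5, 250.0),
    ]

    best = None
    for x0 in starts:
        res = minimize(
            _nll, np.asarray(x0, float), args=(t, y), method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    p_max, mu, sl, sr = (float(v) for v in best.x)
    cross = _crossing(p_max, mu, sl, threshold, float(t.min()))
    return SnowmeltFit(
        p_max=p_max,
        mu=mu,
        sigma_left=sl,
        sigma_right=sr,
        loglik=-float(best.fun),
        snowmelt_doy=cross,
        converged=bool(best.success),
    )


# ---------------------------------------------------------------------------
# NDVI green-up: distance-weighted penalized smoothing spline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GreenupFit:
    max_doy: float
    max_value: float
    start_doy: float
    start_value: float
    amplitude: float
    greenup_doy: Optional[float]
    n_points: int
    n_cells: int


def fit_greenup(
    ndvi: pd.DataFrame,
    focal_cell: str,
    snow_free_doys: Sequence[float],
    focal_lat: Optional[float] = None,
    focal_lon: Optional[float] = None,
    radius_km: float = DEFAULTS["neighbor_radius_km"],
    sd_km: float = DEFAULTS["neighbor_sd_km"],
    amplitude_frac: float = DEFAULTS["greenup_amplitude_frac"],
    min_amplitude: float = DEFAULTS["greenup_min_amplitude"],
) -> GreenupFit:
    """Estimate the green-up (start-of-season) date for one cell-year.

    ``ndvi`` holds weekly observations for the focal cell and any neighbours
    (columns ``cell_id, lat, lon, doy, value``).  Neighbours within
    ``radius_km`` contribute with Gaussian distance weights (SD ``sd_km``);
    with no neighbours the fit reduces to an unweighted spline of the focal
    cell.  The spline penalty is chosen by generalized cross-validation.
    Daily interpolation is restricted to ``snow_free_doys``; green-up is the
    first such day on the rising limb where the curve exceeds the seasonal
    start by ``amplitude_frac`` of the start-to-maximum amplitude.
    """
    snow_free = np.unique(np.asarray(list(snow_free_doys), float))
    if len(snow_free) == 0:
        raise ValueError("no snow-free days in the neighbourhood")
    focal = ndvi[ndvi["cell_id"] == focal_cell]
    if not focal.empty:
        flat, flon = float(focal["lat"].iloc[0]), float(focal["lon"].iloc[0])
    elif focal_lat is not None and focal_lon is not None:
        # focal cell has no observations: the fit is carried by neighbours
        flat, flon = float(focal_lat), float(focal_lon)
    else:
        raise ValueError(
            f"focal cell {focal_cell!r} has no observations and no coordinates were given"
        )

    dist = haversine_km(flat, flon, ndvi["lat"].to_numpy(), ndvi["lon"].to_numpy())
    keep = dist <= radius_km
    sub = ndvi[keep]
    w = np.exp(-0.5 * (dist[keep] / sd_km) ** 2)
    if len(sub) < 4:
        raise ValueError("need at least 4 NDVI observations to fit a spline")

    # weighted aggregation of duplicate days (spline needs increasing x)
    agg = (
        pd.DataFrame({"doy": sub["doy"].to_numpy(float), "wv": w * sub["value"].to_numpy(float), "w": w})
        .groupby("doy")
        .sum()
    )
    x = agg.index.to_numpy()
    yw = (agg["wv"] / agg["w"]).to_numpy()
    ww = agg["w"].to_numpy()
    if len(x) < 4:
        raise ValueError("need at least 4 distinct observation days")
    spline = make_smoothing_spline(x, yw, w=ww, lam=None)

    days = snow_free[(snow_free >= x.min()) & (snow_free <= x.max())]
    if len(days) == 0:
        raise ValueError("no snow-free days inside the observed NDVI span")
    fitted = spline(days)
    imax = int(np.argmax(fitted))
    max_doy, max_val = float(days[imax]), float(fitted[imax])
    rising = fitted[: imax + 1]
    istart = int(np.argmin(rising))
    start_doy, start_val = float(days[istart]), float(rising[istart])
    amplitude = max_val - start_val
    greenup: Optional[float] = None
    if amplitude >= min_amplitude:
        above = np.flatnonzero(rising[istart:] >= start_val + amplitude_frac * amplitude)
        greenup = float(days[istart + above[0]])
    return GreenupFit(
        max_doy=max_doy,
        max_value=max_val,
        start_doy=start_doy,
        start_value=start_val,
        amplitude=float(amplitude),
        greenup_doy=greenup,
        n_points=int(len(sub)),
        n_cells=int(sub["cell_id"].nunique()),
    )


# ---------------------------------------------------------------------------
# regional summaries and trends
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionalSummary:
    region: str
    table: pd.DataFrame  # year, median_doy, q2_5, q97_5, n_cells
    slope: float
    se: float
    p: float
    n: int


def regional_summary(
    dates: pd.DataFrame,
    date_col: str,
    split_lat: float = DEFAULTS["region_split_lat"],
    regions: Sequence[str] = ("All", "North", "South"),
) -> dict[str, RegionalSummary]:
    """Median/95%-quantile summaries and pooled-cell OLS trends per region.

    ``dates`` needs columns ``cell_id, lat, year`` and ``date_col``.  The
    trend slope is OLS of cell-level dates on year pooling all cells of the
    region (matching the very small standard errors that pooled cell counts
    produce).
    """
    sub = dates.dropna(subset=[date_col])
    out: dict[str, RegionalSummary] = {}
    for region in regions:
        if region == "All":
            d = sub
        elif region == "North":
            d = sub[sub["lat"] > split_lat]
        else:
            d = sub[sub["lat"] < split_lat]
        if d["year"].nunique() < 2:
            warnings.warn(f"region {region}: fewer than two years with data; skipped")
            continue
        rows = []
        for year, g in d.groupby("year"):
            v = g[date_col].to_numpy(float)
            rows.append(
                {
                    "year": int(year),
                    "median_doy": float(np.median(v)),
                    "q2_5": float(np.quantile(v, 0.025)),
                    "q97_5": float(np.quantile(v, 0.975)),
                    "n_cells": int(len(v)),
                }
            )
        x = sm.add_constant(d["year"].to_numpy(float))
        res = sm.OLS(d[date_col].to_numpy(float), x).fit()
        out[region] = RegionalSummary(
            region=region,
            table=pd.DataFrame(rows).sort_values("year").reset_index(drop=True),
            slope=float(res.params[1]),
            se=float(res.bse[1]),
            p=float(res.pvalues[1]),
            n=int(res.nobs),
        )
    return out


@dataclass(frozen=True)
class CorrelationResult:
    r2: float
    t: float
    df: int
    p: float
    slope: float
    n: int


def snow_ndvi_correlation(paired: pd.DataFrame) -> CorrelationResult:
    """OLS of green-up on snowmelt dates over paired cell-years."""
    sub = paired.dropna(subset=["snowmelt_doy", "greenup_doy"])
    if len(sub) < 3:
        raise ValueError("need at least three complete cell-year pairs")
    xs = sub["snowmelt_doy"].to_numpy(float)
    if np.ptp(xs) == 0:
        raise ValueError("snowmelt dates are constant; correlation undefined")
    x = sm.add_constant(xs)
    res = sm.OLS(sub["greenup_doy"].to_numpy(float), x).fit()
    return CorrelationResult(
        r2=float(res.rsquared),
        t=float(res.tvalues[1]),
        df=int(res.df_resid),
        p=float(res.pvalues[1]),
        slope=float(res.params[1]),
        n=int(res.nobs),
    )
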