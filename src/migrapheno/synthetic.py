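"""Synthetic data generators with known ground truth.

Three families of artefacts are produced:

* departure panels — individual-by-year departure dates generated from a
  within/between-individual slope decomposition model,
* geolocator traces — light + wet/dry conductivity series for one full
  northward migration (two long over-water flights, a stopover, and optional
  post-arrival incubation shading),
* phenology grids — per-cell daily snow-free indicators and weekly NDVI
  values with latitude- and year-dependent seasonal timing.

Every generator is deterministic under its seed and returns the generating
truth alongside the data so downstream estimators can be tested by parameter
recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from . import _solar

__all__ = [
    "PanelSpec",
    "TraceSpec",
    "GridSpec",
    "generate_departure_panel",
    "generate_trace",
    "generate_light_trace",
    "generate_phenology_grid",
    "generate_timing_panel",
]


# ---------------------------------------------------------------------------
# departure panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelSpec:
    """Generating parameters for an individual-by-year departure panel.

    The data-generating model is

        date_ij = mean_date_year0 + beta_between * (mean_year_i - year0)
                  + beta_within * (year_ij - mean_year_i) + u_i + e_ij

    where ``mean_year_i`` is individual *i*'s mean observed year,
    ``u_i ~ N(0, sd_individual_intercept^2)`` and
    ``e_ij ~ N(0, sd_residual^2)``.
    """

    n_individuals: int
    years: tuple[int, int]
    beta_within: float
    beta_between: float
    sd_individual_intercept: float
    sd_residual: float
    mean_date_year0: float = 76.0
    presence_prob: float = 0.9
    career_years: tuple[int, int] = (3, 13)
    direct_obs_prob: float = 0.86
    round_to_day: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.years[1] <= self.years[0]:
            raise ValueError("need at least two distinct years")
        if self.sd_individual_intercept < 0 or self.sd_residual < 0:
            raise ValueError("sd terms must be >= 0")
        if not (0 < self.presence_prob <= 1):
            raise ValueError("presence_prob must be in (0, 1]")


def generate_departure_panel(
    spec: PanelSpec,
    min_years: Optional[int] = None,
    return_survival_knob: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Generate a departure panel; returns ``(panel, truth)``.

    Parameters
    ----------
    spec
        Generating parameters.
    min_years
        If given, only individuals observed in at least this many years are
        emitted.
    return_survival_knob
        Log-odds change in next-year presence per day of departure date
        (0 = presence independent of date).  Used to create detectable
        composition change for power tests of the return-rate model.
    """
    rng = np.random.default_rng(spec.seed)
    years = np.arange(spec.years[0], spec.years[1] + 1)
    n, ny = spec.n_individuals, len(years)

    u = rng.normal(0.0, spec.sd_individual_intercept, size=n)
    base_date = spec.mean_date_year0 + u  # per-individual intercept at year0

    # staggered careers: each bird enters the marked population in some year
    # and is observable for a bounded span, spreading individual mean-years
    entry = rng.integers(0, ny, size=n)
    span = rng.integers(spec.career_years[0], min(spec.career_years[1], ny) + 1, size=n)
    idx = np.arange(ny)
    in_career = (idx >= entry[:, None]) & (idx <= np.minimum(entry + span - 1, ny - 1)[:, None])

    if return_survival_knob == 0.0:
        present = in_career & (rng.random((n, ny)) < spec.presence_prob)
    else:
        # sequential presence whose odds depend on the bird's typical date
        present = np.zeros((n, ny), dtype=bool)
        logit0 = np.log(spec.presence_prob / (1 - spec.presence_prob))
        p = expit(logit0 + return_survival_knob * (base_date - spec.mean_date_year0))
        for j in range(ny):
            present[:, j] = in_career[:, j] & (rng.random(n) < p)

    rows = []
    for i in range(n):
        obs_years = years[present[i]]
        if len(obs_years) == 0:
            continue
        mean_year = obs_years.mean()
        dates = (
            spec.mean_date_year0
            + spec.beta_between * (mean_year - years[0])
            + spec.beta_within * (obs_years - mean_year)
            + u[i]
            + rng.normal(0.0, spec.sd_residual, size=len(obs_years))
        )
        direct = rng.random(len(obs_years)) < spec.direct_obs_prob
        for y, d, o in zip(obs_years, dates, direct):
            rows.append((f"B{i:04d}", int(y), d, int(o)))

    panel = pd.DataFrame(rows, columns=["id", "year", "depart_doy", "observed"])
    if spec.round_to_day:
        panel["depart_doy"] = np.rint(panel["depart_doy"]).astype(int)
    if min_years is not None:
        counts = panel.groupby("id")["year"].transform("size")
        panel = panel[counts >= min_years].reset_index(drop=True)

    truth = {
        "beta_within": spec.beta_within,
        "beta_between": spec.beta_between,
        "sd_individual_intercept": spec.sd_individual_intercept,
        "sd_residual": spec.sd_residual,
        "mean_date_year0": spec.mean_date_year0,
    }
    return panel, truth


# ---------------------------------------------------------------------------
# geolocator trace
# ---------------------------------------------------------------------------

NZ_SITE = (-40.47, 175.22)
STOPOVER_SITE = (37.0, 122.0)

# light model: linear ramp of solar elevation between these two angles
DARK_ELEV_DEG = -6.0
BRIGHT_ELEV_DEG = 4.0
LIGHT_MAX = 10.0

TIDE_PERIOD_H = 12.42
TIDE_WET_H = 5.0
FLIGHT_WET_BUFFER_H = 3.0  # forced-wet margin on land around each flight


@dataclass(frozen=True)
class TraceSpec:
    """Generating parameters for one bird-year light/conductivity trace."""

    sampling_interval: int = 10  # minutes
    year: int = 2013
    flight1_start: float = 79.5  # fractional day-of-year
    flight1_duration: float = 7.5  # days
    stopover_duration: float = 38.0
    flight2_duration: float = 7.0
    incubation_start_offset: float = 12.0  # days after Alaska arrival
    incubation_bout_hours: float = 6.0
    incubation_days: int = 0
    site_lat: float = 62.0
    site_lon: float = -162.0
    noise_wet_prob: float = 0.0
    light_noise_sd: float = 0.0
    trace_start_doy: int = 60
    trace_end_doy: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if 1440 % self.sampling_interval != 0:
            raise ValueError("sampling_interval must divide 24 h")
        if self.flight1_duration <= 3 or self.flight2_duration <= 3:
            raise ValueError("flight durations must exceed 3 d")
        if self.stopover_duration <= 0:
            raise ValueError("events overlap: stopover_duration must be > 0")
        if self.incubation_days > 0 and self.incubation_start_offset <= 0:
            raise ValueError("events overlap: incubation must start after arrival")
        if not (0 < self.incubation_bout_hours < 24):
            raise ValueError("incubation_bout_hours must lie in (0, 24)")


def _event_times(spec: TraceSpec) -> dict:
    nzdep = spec.flight1_start
    ysarr = nzdep + spec.flight1_duration
    ysdep = ysarr + spec.stopover_duration
    akarr = ysdep + spec.flight2_duration
    return {"nzdep": nzdep, "ysarr": ysarr, "ysdep": ysdep, "akarr": akarr}


def _solar_noon_frac(lon: float) -> float:
    """Approximate fraction of the UTC day at which local solar noon falls."""
    return ((12.0 - lon / 15.0) / 24.0) % 1.0


def _incubation_bouts(spec: TraceSpec, akarr: float) -> list[tuple[float, float]]:
    if spec.incubation_days <= 0:
        return []
    noon = _solar_noon_frac(spec.site_lon)
    half = spec.incubation_bout_hours / 48.0  # half bout in days
    target = akarr + spec.incubation_start_offset
    day = int(np.floor(target)) - 1
    while day + noon - half < target:
        day += 1
    return [
        (day + k + noon - half, day + k + noon + half)
        for k in range(spec.incubation_days)
    ]


def generate_trace(spec: TraceSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a full-migration light + wet/dry trace.

    Returns ``(trace, truth)`` where ``trace`` has columns ``timestamp``
    (UTC), ``light`` and ``wet`` and ``truth`` carries the exact event times
    (fractional day-of-year): ``nzdep``, ``ysarr``, ``ysdep``, ``akarr``,
    ``incst`` (whole doy, or None) and the shading bout intervals.
    """
    rng = np.random.default_rng(spec.seed)
    ev = _event_times(spec)
    bouts = _incubation_bouts(spec, ev["akarr"])

    end_doy = spec.trace_end_doy
    if end_doy is None:
        tail = bouts[-1][1] if bouts else ev["akarr"]
        end_doy = int(np.ceil(tail)) + 10
    if spec.trace_start_doy >= ev["nzdep"]:
        raise ValueError("trace must start before the first flight")

    step_days = spec.sampling_interval / 1440.0
    n_steps = int(round((end_doy - spec.trace_start_doy) / step_days))
    doy = spec.trace_start_doy + step_days * np.arange(n_steps)  # fractional doy
    ts = pd.Timestamp(f"{spec.year}-01-01", tz="UTC") + pd.to_timedelta(
        np.round((doy - 1.0) * 86400.0), unit="s"
    )

    # piecewise location: NZ -> (flight1) -> stopover -> (flight2) -> site
    lat = np.full_like(doy, NZ_SITE[0])
    lon_u = np.full_like(doy, NZ_SITE[1])  # unwrapped longitude
    site_lon_u = spec.site_lon + 360.0 if spec.site_lon < 0 else spec.site_lon

    def _leg(t0, t1, p0, p1):
        m = (doy >= t0) & (doy < t1)
        f = (doy[m] - t0) / (t1 - t0)
        lat[m] = p0[0] + f * (p1[0] - p0[0])
        lon_u[m] = p0[1] + f * (p1[1] - p0[1])

    _leg(ev["nzdep"], ev["ysarr"], NZ_SITE, STOPOVER_SITE)
    m = (doy >= ev["ysarr"]) & (doy < ev["ysdep"])
    lat[m], lon_u[m] = STOPOVER_SITE
    _leg(ev["ysdep"], ev["akarr"], STOPOVER_SITE, (spec.site_lat, site_lon_u))
    m = doy >= ev["akarr"]
    lat[m], lon_u[m] = spec.site_lat, site_lon_u
    lon = (lon_u + 180.0) % 360.0 - 180.0

    utc_hour = (doy % 1.0) * 24.0
    elev = _solar.solar_elevation_deg(lat, lon, np.floor(doy), utc_hour)
    frac = np.clip((elev - DARK_ELEV_DEG) / (BRIGHT_ELEV_DEG - DARK_ELEV_DEG), 0.0, 1.0)
    light = LIGHT_MAX * frac
    if spec.light_noise_sd > 0:
        light = np.clip(light + rng.normal(0.0, spec.light_noise_sd, light.shape), 0.0, None)

    for b0, b1 in bouts:
        light[(doy >= b0) & (doy < b1)] = 0.0

    # conductivity: tidal wetting on land, dry in flight (minus spurious wets)
    hours = (doy - doy[0]) * 24.0
    wet = ((hours % TIDE_PERIOD_H) < TIDE_WET_H).astype(np.int8)
    in_flight = ((doy >= ev["nzdep"]) & (doy < ev["ysarr"])) | (
        (doy >= ev["ysdep"]) & (doy < ev["akarr"])
    )
    wet[in_flight] = 0
    if spec.noise_wet_prob > 0:
        spurious = rng.random(in_flight.sum()) < spec.noise_wet_prob
        wet[np.flatnonzero(in_flight)[spurious]] = 1
    buf = FLIGHT_WET_BUFFER_H / 24.0
    for t0, t1 in ((ev["nzdep"], ev["ysarr"]), (ev["ysdep"], ev["akarr"])):
        edge = ((doy >= t0 - buf) & (doy < t0)) | ((doy >= t1) & (doy < t1 + buf))
        wet[edge & ~in_flight] = 1

    trace = pd.DataFrame({"timestamp": ts, "light": light, "wet": wet})
    truth = dict(ev)
    truth["incst"] = int(np.floor(bouts[0][0])) if bouts else None
    truth["bouts"] = bouts
    truth["site_lat"] = spec.site_lat
    truth["site_lon"] = spec.site_lon
    return trace, truth


def generate_light_trace(
    lat: float,
    lon: float,
    year: int,
    start_doy: int,
    end_doy: int,
    sampling_interval: int = 10,
    light_noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Stationary light/wet trace at a fixed site (wet at tidal cadence)."""
    rng = np.random.default_rng(seed)
    step = sampling_interval / 1440.0
    n_steps = int(round((end_doy - start_doy) / step))
    doy = start_doy + step * np.arange(n_steps)
    ts = pd.Timestamp(f"{year}-01-01", tz="UTC") + pd.to_timedelta(
        np.round((doy - 1.0) * 86400.0), unit="s"
    )
    elev = _solar.solar_elevation_deg(lat, lon, np.floor(doy), (doy % 1.0) * 24.0)
    light = LIGHT_MAX * np.clip((elev - DARK_ELEV_DEG) / (BRIGHT_ELEV_DEG - DARK_ELEV_DEG), 0, 1)
    if light_noise_sd > 0:
        light = np.clip(light + rng.normal(0.0, light_noise_sd, light.shape), 0.0, None)
    wet = (((doy - doy[0]) * 24.0 % TIDE_PERIOD_H) < TIDE_WET_H).astype(np.int8)
    return pd.DataFrame({"timestamp": ts, "light": light, "wet": wet})


# ---------------------------------------------------------------------------
# phenology grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Generating parameters for a snow/NDVI grid.

    Snow-free probability follows an asymmetric Gaussian
    ``s(t) = p_max * exp(-0.5 ((t - mu)/sigma)^2)`` with ``sigma_left`` for
    ``t < mu`` and ``sigma_right`` after; daily observations are Bernoulli
    draws.  NDVI follows a rise-and-fall logistic product sampled weekly with
    Gaussian noise.  Peak timing is linear in latitude and year; the northern
    (``lat >= north_split``) year slope may be overridden to create regional
    trend contrasts.
    """

    n_cells: int
    lat_range: tuple[float, float]
    years: tuple[int, int]
    lon_range: tuple[float, float] = (-165.0, -150.0)
    snow_p_max: float = 1.0
    snow_mu0: float = 160.0
    snow_mu_lat_slope: float = 3.0  # days per degree latitude
    snow_mu_year_slope: float = 0.0
    snow_mu_year_slope_north: Optional[float] = None
    snow_sigma_left: float = 30.0
    snow_sigma_right: float = 60.0
    ndvi_base: float = 0.10
    ndvi_amplitude: float = 0.60
    ndvi_mid0: float = 170.0
    ndvi_mid_lat_slope: float = 3.0
    ndvi_mid_year_slope: float = 0.0
    ndvi_mid_year_slope_north: Optional[float] = None
    ndvi_rate: float = 0.15
    ndvi_fall_rate: float = 0.08
    ndvi_fall_offset: float = 80.0
    ndvi_noise_sd: float = 0.02
    lat_ref: float = 62.0
    north_split: float = 64.0
    greenup_frac: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.snow_p_max <= 1):
            raise ValueError("snow_p_max must be in (0, 1]")
        if self.ndvi_amplitude < 0:
            raise ValueError("ndvi_amplitude must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def _asym_gauss(t: np.ndarray, p_max: float, mu: float, sl: float, sr: float) -> np.ndarray:
    sigma = np.where(t < mu, sl, sr)
    return p_max * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _snowmelt_crossing(p_max: float, mu: float, sigma_left: float, threshold: float, first_doy: float) -> float:
    """Analytic first crossing of the asymmetric Gaussian at ``threshold``."""
    if p_max < threshold:
        return float("nan")
    if p_max == threshold:
        return float(mu)
    t = mu - sigma_left * np.sqrt(2.0 * np.log(p_max / threshold))
    return float(max(t, first_doy))


def _ndvi_curve(t: np.ndarray, spec: GridSpec, mid: float) -> np.ndarray:
    rise = expit(spec.ndvi_rate * (t - mid))
    fall = expit(-spec.ndvi_fall_rate * (t - (mid + spec.ndvi_fall_offset)))
    return spec.ndvi_base + spec.ndvi_amplitude * rise * fall


def _greenup_truth(spec: GridSpec, mid: float) -> float:
    """Forward-model 15%-of-amplitude crossing on the noise-free daily curve."""
    t = np.arange(1.0, 366.0)
    v = _ndvi_curve(t, spec, mid)
    imax = int(np.argmax(v))
    if imax == 0:
        return float("nan")
    start = v[: imax + 1].min()
    amp = v[imax] - start
    if amp <= 0:
        return float("nan")
    above = np.flatnonzero(v[: imax + 1] >= start + spec.greenup_frac * amp)
    return float(t[above[0]])


def generate_phenology_grid(spec: GridSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate grid observations and truth; returns ``(grid, truth)``.

    ``grid`` is long-format with columns ``cell_id, lat, lon, year, doy,
    value, channel`` (channel in {snow, ndvi}); ``truth`` has one row per
    cell-year with the generating snowmelt (1/3-crossing) and green-up
    (15%-of-amplitude) dates.
    """
    rng = np.random.default_rng(spec.seed)
    years = np.arange(spec.years[0], spec.years[1] + 1)
    lats = rng.uniform(*spec.lat_range, size=spec.n_cells)
    lons = rng.uniform(*spec.lon_range, size=spec.n_cells)

    snow_doys = np.arange(1, 366, dtype=float)
    ndvi_doys = np.arange(3, 366, 7, dtype=float)

    frames, truth_rows = [], []
    for c in range(spec.n_cells):
        lat, lon = lats[c], lons[c]
        north = lat >= spec.north_split
        s_yr = (
            spec.snow_mu_year_slope_north
            if (north and spec.snow_mu_year_slope_north is not None)
            else spec.snow_mu_year_slope
        )
        n_yr = (
            spec.ndvi_mid_year_slope_north
            if (north and spec.ndvi_mid_year_slope_north is not None)
            else spec.ndvi_mid_year_slope
        )
        for year in years:
            dy = year - years[0]
            mu = spec.snow_mu0 + spec.snow_mu_lat_slope * (lat - spec.lat_ref) + s_yr * dy
            mid = spec.ndvi_mid0 + spec.ndvi_mid_lat_slope * (lat - spec.lat_ref) + n_yr * dy

            p = _asym_gauss(snow_doys, spec.snow_p_max, mu, spec.snow_sigma_left, spec.snow_sigma_right)
            snow = (rng.random(len(snow_doys)) < p).astype(np.int8)
            ndvi = _ndvi_curve(ndvi_doys, spec, mid)
            if spec.ndvi_noise_sd > 0:
                ndvi = ndvi + rng.normal(0.0, spec.ndvi_noise_sd, ndvi.shape)

            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": f"C{c:04d}",
                        "lat": lat,
                        "lon": lon,
                        "year": year,
                        "doy": np.concatenate([snow_doys, ndvi_doys]),
                        "value": np.concatenate([snow.astype(float), ndvi]),
                        "channel": ["snow"] * len(snow_doys) + ["ndvi"] * len(ndvi_doys),
                    }
                )
            )
            truth_rows.append(
                {
                    "cell_id": f"C{c:04d}",
                    "lat": lat,
                    "lon": lon,
                    "year": year,
                    "snowmelt_doy": _snowmelt_crossing(
                        spec.snow_p_max, mu, spec.snow_sigma_left, 1.0 / 3.0, snow_doys[0]
                    ),
                    "greenup_doy": _greenup_truth(spec, mid),
                }
            )

    grid = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return grid, truth


# ---------------------------------------------------------------------------
# timing table (for trend-model tests)
# ---------------------------------------------------------------------------

DEFAULT_TIMING_PARAMS: dict[str, dict] = {
    "NZdep": {"intercept": 79.0, "slope": -0.85, "region_effect": 4.0},
    "YSarr": {"intercept": 87.0, "slope": -0.89, "region_effect": 4.0},
    "YSdep": {"intercept": 127.0, "slope": -0.33, "region_effect": 5.0},
    "AKarr": {"intercept": 134.0, "slope": -0.21, "region_effect": 5.0},
    "YSdur": {"intercept": 40.0, "slope": 0.69, "region_effect": 1.0},
    "IncSt": {"intercept": 155.0, "slope": 0.07, "region_effect": 6.0},
}


def generate_timing_panel(
    n_individuals: int = 36,
    years: tuple[int, ...] = (2008, 2009, 2013, 2014),
    params: Optional[dict[str, dict]] = None,
    sd_individual: float = 3.0,
    sd_residual: float = 3.0,
    prob_north: float = 0.45,
    tracks_per_individual: tuple[int, int] = (1, 3),
    year_center: int = 2008,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a per-track migration-timing table for trend-model tests.

    Each parameter follows ``intercept + slope*(year - year_center) +
    region_effect*north + u_i + e`` with shared individual effects ``u_i``.
    """
    if params is None:
        params = DEFAULT_TIMING_PARAMS
    rng = np.random.default_rng(seed)
    years = np.asarray(years)
    rows = []
    for i in range(n_individuals):
        north = rng.random() < prob_north
        n_tracks = rng.integers(tracks_per_individual[0], tracks_per_individual[1] + 1)
        obs_years = rng.choice(years, size=min(n_tracks, len(years)), replace=False)
        u = rng.normal(0.0, sd_individual)
        for year in sorted(obs_years):
            row = {
                "id": f"T{i:03d}",
                "year": int(year),
                "region": "North" if north else "South",
            }
            for name, p in params.items():
                row[name] = (
                    p["intercept"]
                    + p["slope"] * (year - year_center)
                    + p["region_effect"] * north
                    + u
                    + rng.normal(0.0, sd_residual)
                )
            rows.append(row)
    return pd.DataFrame(rows)


def panel_spec_fields() -> list[str]:
    return [f.name for f in dataclasses.fields(PanelSpec)]
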