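"""Annotate geolocator light/conductivity traces with migration timing.

A trace is a DataFrame with columns ``timestamp`` (UTC, fixed sampling
interval), ``light`` (arbitrary nonnegative units) and ``wet`` (0/1
conductivity).  The module derives:

* flight events — maximal dry runs in the conductivity channel,
* the migration timing parameters NZdep, YSarr, YSdep, AKarr, YSdur,
* incubation start (IncSt) from daytime shading bouts,
* breeding locations by the light-threshold geolocation method, and
* per-parameter linear mixed-model year trends across tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import _solar
from .config import DEFAULTS

__all__ = [
    "FlightEvent",
    "MigrationTiming",
    "IncubationResult",
    "BreedingLocation",
    "TimingTrendFit",
    "detect_flights",
    "derive_timing",
    "detect_incubation",
    "extract_twilights",
    "calibrate_sun_angle",
    "daily_positions",
    "estimate_breeding_location",
    "assign_region",
    "timing_trend_models",
    "TIMING_PARAMETERS",
]

TIMING_PARAMETERS = ("NZdep", "YSarr", "YSdep", "AKarr", "YSdur", "IncSt")


def _trace_arrays(trace: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Return (fractional doy, light, wet, interval_days); validates cadence."""
    ts = trace["timestamp"]
    if not pd.api.types.is_datetime64_any_dtype(ts):
        ts = pd.to_datetime(ts, utc=True, format="ISO8601")
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("timestamps must be strictly increasing")
    year_start = pd.Timestamp(year=ts.iloc[0].year, month=1, day=1, tz="UTC")
    doy = (ts - year_start).dt.total_seconds().to_numpy() / 86400.0 + 1.0
    steps = np.diff(doy)
    if len(steps) and (steps.max() - steps.min()) > 1e-9:
        raise ValueError("sampling interval must be constant")
    interval = float(steps[0]) if len(steps) else np.nan
    return doy, trace["light"].to_numpy(float), trace["wet"].to_numpy(int), interval


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first_index, last_index) inclusive."""
    if not mask.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return [(int(a), int(b - 1)) for a, b in zip(idx[::2], idx[1::2])]


# ---------------------------------------------------------------------------
# conductivity flight detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlightEvent:
    start: pd.Timestamp
    end: pd.Timestamp
    duration_days: float
    dry_fraction: float


def detect_flights(
    trace: pd.DataFrame,
    min_duration_days: float = DEFAULTS["flight_min_duration_days"],
    purity: float = DEFAULTS["flight_purity"],
    bridge_hours: float = DEFAULTS["flight_bridge_hours"],
) -> list[FlightEvent]:
    """Find extended dry periods diagnostic of non-stop over-water flight.

    Wet runs shorter than ``bridge_hours`` that are flanked by dry readings
    are bridged over (they still count against the run's dry fraction);
    maximal dry runs at least ``min_duration_days`` long with a dry fraction
    of at least ``purity`` are returned in time order.
    """
    if trace.empty:
        return []
    doy, _, wet, interval = _trace_arrays(trace)
    ts = trace["timestamp"]
    if not pd.api.types.is_datetime64_any_dtype(ts):
        ts = pd.to_datetime(ts, utc=True, format="ISO8601")
    ts = ts.reset_index(drop=True)
    dry_raw = wet == 0
    effective = dry_raw.copy()
    bridge_days = bridge_hours / 24.0
    for a, b in _runs(~dry_raw):
        if a == 0 or b == len(dry_raw) - 1:
            continue  # boundary wet runs are not bridged
        if (b - a + 1) * interval <= bridge_days:
            effective[a : b + 1] = True

    events = []
    for a, b in _runs(effective):
        duration = (b - a + 1) * interval
        if duration + 1e-9 < min_duration_days:
            continue
        frac = float(dry_raw[a : b + 1].mean())
        if frac < purity:
            continue
        events.append(
            FlightEvent(
                start=ts.iloc[a],
                end=ts.iloc[b] + pd.Timedelta(days=interval),
                duration_days=float(duration),
                dry_fraction=frac,
            )
        )
    return events


# ---------------------------------------------------------------------------
# migration timing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MigrationTiming:
    """Six derived timing parameters (day-of-year, 1 = 1 Jan)."""

    nzdep: Optional[int] = None
    ysarr: Optional[int] = None
    ysdep: Optional[int] = None
    akarr: Optional[int] = None
    ysdur: Optional[int] = None
    incst: Optional[int] = None

    def validate(self) -> None:
        seq = [v for v in (self.nzdep, self.ysarr, self.ysdep, self.akarr) if v is not None]
        if any(b < a for a, b in zip(seq, seq[1:])):
            raise ValueError(f"timing parameters out of order: {self}")
        if self.ysdur is not None and self.ysdur < 0:
            raise ValueError("negative stopover duration")
        if self.incst is not None and self.akarr is not None and self.incst < self.akarr:
            raise ValueError("incubation before Alaska arrival")


def _event_doy(ts: pd.Timestamp) -> int:
    year_start = pd.Timestamp(year=ts.year, month=1, day=1, tz="UTC")
    return int(np.floor((ts - year_start).total_seconds() / 86400.0)) + 1


def derive_timing(
    flights: Sequence[FlightEvent],
    season: tuple[float, float] = (45.0, 180.0),
) -> MigrationTiming:
    """Map the two long northward flights onto the four timing dates.

    The first qualifying flight gives NZdep (start) and YSarr (end), the
    second gives YSdep and AKarr; YSdur is their difference in whole days.
    With fewer than two flights a partial timing is returned; with more than
    two, the two longest are used (chronological order kept) with a warning.
    """
    season_flights = [
        f for f in flights if season[0] <= _event_doy(f.start) + 0.0 <= season[1]
    ]
    if len(season_flights) > 2:
        warnings.warn(
            f"{len(season_flights)} qualifying flights; selecting the two longest"
        )
        season_flights = sorted(
            sorted(season_flights, key=lambda f: f.duration_days, reverse=True)[:2],
            key=lambda f: f.start,
        )
    if not season_flights:
        return MigrationTiming()
    first = season_flights[0]
    timing = {
        "nzdep": _event_doy(first.start),
        "ysarr": _event_doy(first.end),
    }
    if len(season_flights) > 1:
        second = season_flights[1]
        timing["ysdep"] = _event_doy(second.start)
        timing["akarr"] = _event_doy(second.end)
        timing["ysdur"] = timing["ysdep"] - timing["ysarr"]
    result = MigrationTiming(**timing)
    result.validate()
    return result


# ---------------------------------------------------------------------------
# incubation detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IncubationResult:
    status: str  # "detected" | "absent" | "undetermined"
    incst: Optional[int] = None


def _solar_midnight_frac(lon: float) -> float:
    """Fraction of the UTC day at which local solar midnight falls."""
    return ((12.0 - lon / 15.0) / 24.0 + 0.5) % 1.0


def detect_incubation(
    trace: pd.DataFrame,
    akarr: int,
    lon: Optional[float] = None,
    bout_range: tuple[float, float] = DEFAULTS["bout_range_hours"],
    min_consecutive_days: int = DEFAULTS["incubation_min_consecutive_days"],
    search_window: tuple[float, float] = DEFAULTS["incubation_search_window_days"],
    light_threshold: float = DEFAULTS["light_threshold"],
) -> IncubationResult:
    """Find the start of incubation from daytime shading bouts.

    A shading event is a contiguous sub-threshold light run that does not
    span local solar midnight (runs containing midnight are the night).  A
    day qualifies when it contains an event whose duration lies within
    ``bout_range`` hours; IncSt is the first day of the first run of at
    least ``min_consecutive_days`` qualifying days starting within
    ``search_window`` days after Alaska arrival.  Under 24-h daylight there
    is no night run and every sub-threshold run is a candidate event.
    """
    doy, light, _, interval = _trace_arrays(trace)
    post = doy >= akarr
    if not post.any():
        return IncubationResult("undetermined")
    doy_p, light_p = doy[post], light[post]

    if lon is not None:
        midnight = _solar_midnight_frac(lon)
    else:
        # fall back to the clock time of minimum mean light after arrival
        frac = doy_p % 1.0
        bins = np.linspace(0, 1, 25)
        which = np.digitize(frac, bins) - 1
        means = [light_p[which == b].mean() if (which == b).any() else np.inf for b in range(24)]
        midnight = (int(np.argmin(means)) + 0.5) / 24.0

    tol_h = interval * 24.0  # one sampling interval of slack on bout bounds
    qualifying_days: dict[int, float] = {}  # day index -> first event start doy
    for a, b in _runs(light_p < light_threshold):
        start, stop = doy_p[a], doy_p[b] + interval
        if np.floor(start - midnight) != np.floor(stop - midnight):
            continue  # spans local midnight: night, not shading
        dur_h = (b - a + 1) * interval * 24.0
        if not (bout_range[0] - tol_h <= dur_h <= bout_range[1] + tol_h):
            continue
        day = int(np.floor(start - midnight))
        qualifying_days.setdefault(day, float(start))

    days = sorted(qualifying_days)
    i = 0
    while i < len(days):
        j = i
        while j + 1 < len(days) and days[j + 1] == days[j] + 1:
            j += 1
        if j - i + 1 >= min_consecutive_days:
            incst = int(np.floor(qualifying_days[days[i]]))
            if search_window[0] <= incst - akarr <= search_window[1]:
                return IncubationResult("detected", incst)
        i = j + 1

    if doy[-1] < akarr + search_window[1] + min_consecutive_days:
        return IncubationResult("undetermined")
    return IncubationResult("absent")


# ---------------------------------------------------------------------------
# threshold geolocation
# ---------------------------------------------------------------------------

def extract_twilights(
    trace: pd.DataFrame,
    light_threshold: float = DEFAULTS["light_threshold"],
    min_night_hours: float = DEFAULTS["min_night_hours"],
) -> pd.DataFrame:
    """Sunset/sunrise instants from threshold crossings of the light channel.

    Returns one row per detected night with fractional-doy columns
    ``sunset`` (down-crossing) and ``sunrise`` (up-crossing); crossing times
    are linearly interpolated between samples.  Runs touching the trace
    boundary are discarded.
    """
    doy, light, _, interval = _trace_arrays(trace)
    rows = []
    for a, b in _runs(light < light_threshold):
        if a == 0 or b == len(light) - 1:
            continue
        if (b - a + 1) * interval * 24.0 < min_night_hours:
            continue
        la0, la1 = light[a - 1], light[a]
        sunset = doy[a - 1] + (la0 - light_threshold) / (la0 - la1) * interval
        lb0, lb1 = light[b], light[b + 1]
        sunrise = doy[b] + (light_threshold - lb0) / (lb1 - lb0) * interval
        rows.append((sunset, sunrise))
    return pd.DataFrame(rows, columns=["sunset", "sunrise"])


def calibrate_sun_angle(
    trace: pd.DataFrame,
    lat: float,
    lon: float,
    window: tuple[float, float],
    light_threshold: float = DEFAULTS["light_threshold"],
) -> float:
    """Reference sun elevation angle from a period at a known location.

    Computes the solar elevation at every twilight crossing inside
    ``window`` (fractional doy bounds) at the known site and returns the
    median — the angle at which the logger's light crosses the threshold.
    """
    tw = extract_twilights(trace, light_threshold)
    times = np.concatenate([tw["sunset"].to_numpy(), tw["sunrise"].to_numpy()])
    times = times[(times >= window[0]) & (times <= window[1])]
    if len(times) == 0:
        raise ValueError("no twilights in the calibration window")
    elevs = _solar.solar_elevation_deg(lat, lon, np.floor(times), (times % 1.0) * 24.0)
    return float(np.median(elevs))


def daily_positions(
    twilights: pd.DataFrame,
    sun_angle_deg: float,
    min_abs_declination_deg: float = DEFAULTS["min_abs_declination_deg"],
) -> pd.DataFrame:
    """Daily position estimates from paired twilights.

    For each day bounded by consecutive nights: longitude from the UTC
    midpoint of sunrise and the following sunset (solar noon), latitude by
    inverting the day-length relation at the calibrated sun angle.
    Latitude is nan when the inversion is uninformative and flagged
    ``low_confidence`` when the solar declination is near zero (equinox).
    """
    rows = []
    for i in range(len(twilights) - 1):
        sunrise = float(twilights["sunrise"].iloc[i])
        sunset = float(twilights["sunset"].iloc[i + 1])
        if not (0.0 < sunset - sunrise < 1.5):
            continue
        noon = 0.5 * (sunrise + sunset)
        day_hours = (sunset - sunrise) * 24.0
        noon_hour = (noon % 1.0) * 24.0
        lon = float(_solar.longitude_from_solar_noon(noon_hour, np.floor(noon)))
        decl = float(_solar.declination_rad(_solar.fractional_year(np.floor(noon), noon_hour)))
        low_conf = abs(np.rad2deg(decl)) < min_abs_declination_deg
        if day_hours >= 23.9 or day_hours <= 0.1:
            lat = float("nan")
        else:
            lat = _solar.latitude_from_day_length(day_hours, decl, sun_angle_deg)
        rows.append(
            {
                "doy": float(np.floor(noon)),
                "lat": lat,
                "lon": lon,
                "day_hours": day_hours,
                "low_confidence": bool(low_conf),
            }
        )
    return pd.DataFrame(rows, columns=["doy", "lat", "lon", "day_hours", "low_confidence"])


@dataclass(frozen=True)
class BreedingLocation:
    lat: float
    lon: float
    lat_extent: tuple[float, float]
    lon_extent: tuple[float, float]
    region: Optional[str]
    n_days: int
    method: str = "threshold"
    lat_estimable: bool = True


def estimate_breeding_location(
    positions: pd.DataFrame,
    window: Optional[tuple[float, float]] = None,
    split_lat: float = DEFAULTS["region_split_lat"],
) -> BreedingLocation:
    """Median position over a stationary window, with 95% extents."""
    sub = positions
    if window is not None:
        sub = positions[(positions["doy"] >= window[0]) & (positions["doy"] <= window[1])]
    if sub.empty:
        raise ValueError("no position estimates in the requested window")
    lats = sub["lat"].dropna().to_numpy()
    lons = sub["lon"].dropna().to_numpy()
    lat_ok = len(lats) > 0
    lat = float(np.median(lats)) if lat_ok else float("nan")
    lon = float(np.median(lons)) if len(lons) else float("nan")
    lat_ext = tuple(np.quantile(lats, [0.025, 0.975])) if lat_ok else (np.nan, np.nan)
    lon_ext = tuple(np.quantile(lons, [0.025, 0.975])) if len(lons) else (np.nan, np.nan)
    region = assign_region(lat, split_lat=split_lat) if lat_ok else None
    return BreedingLocation(
        lat=lat,
        lon=lon,
        lat_extent=(float(lat_ext[0]), float(lat_ext[1])),
        lon_extent=(float(lon_ext[0]), float(lon_ext[1])),
        region=region,
        n_days=int(len(sub)),
        lat_estimable=lat_ok,
    )


def assign_region(
    lat: float,
    split_lat: float = DEFAULTS["region_split_lat"],
    east_longitude_evidence: bool = False,
    assumed_north_lat: float = 70.2,
) -> str:
    """North/South assignment at the split latitude (strict comparison).

    A missing latitude with east-of-range longitude evidence may be
    overridden to North (assumed Arctic breeding latitude).  A latitude
    exactly on the split is flagged as ``"Boundary"``.
    """
    if not np.isfinite(lat):
        if east_longitude_evidence:
            return assign_region(assumed_north_lat, split_lat=split_lat)
        raise ValueError("latitude unavailable and no longitude evidence for override")
    if lat > split_lat:
        return "North"
    if lat < split_lat:
        return "South"
    return "Boundary"


# ---------------------------------------------------------------------------
# timing trend models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimingTrendFit:
    parameter: str
    slope: float
    se: float
    p: float
    region_effect: float
    region_se: float
    interaction_p: float
    interaction_dropped: bool
    n_tracks: int
    n_individuals: int


def _mixedlm(y, exog, groups):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=groups)
        try:
            return model.fit(reml=True)
        except Exception:
            return model.fit(reml=True, method="lbfgs")


def timing_trend_models(
    timings: pd.DataFrame,
    parameters: Sequence[str] = TIMING_PARAMETERS,
    year_center: int = DEFAULTS["year_center"],
    interaction_alpha: float = DEFAULTS["interaction_alpha"],
    min_values: int = 5,
) -> dict[str, TimingTrendFit]:
    """Per-parameter mixed-model year trends across tracks.

    Each parameter is modelled with fixed effects year (centered), region
    and their interaction, plus a random intercept per individual.  When the
    interaction is non-significant at ``interaction_alpha`` it is dropped
    and the reduced model reported.
    """
    required = {"id", "year", "region"}
    if required - set(timings.columns):
        raise ValueError("timings must have id, year, region columns")
    out: dict[str, TimingTrendFit] = {}
    for param in parameters:
        if param not in timings.columns:
            continue
        sub = timings.dropna(subset=[param])
        if len(sub) < min_values:
            warnings.warn(f"{param}: only {len(sub)} values; skipped")
            continue
        y = sub[param].to_numpy(float)
        year_c = sub["year"].to_numpy(float) - year_center
        north = (sub["region"] == "North").to_numpy(float)
        groups = sub["id"].to_numpy()

        full = np.column_stack([np.ones(len(sub)), year_c, north, year_c * north])
        res_full = _mixedlm(y, full, groups)
        inter_p = float(res_full.pvalues[3])
        if inter_p >= interaction_alpha or not np.isfinite(inter_p):
            reduced = full[:, :3]
            res = _mixedlm(y, reduced, groups)
            dropped = True
        else:
            res = res_full
            dropped = False
        out[param] = TimingTrendFit(
            parameter=param,
            slope=float(res.params[1]),
            se=float(res.bse[1]),
            p=float(res.pvalues[1]),
            region_effect=float(res.params[2]),
            region_se=float(res.bse[2]),
            interaction_p=inter_p,
            interaction_dropped=dropped,
            n_tracks=int(len(sub)),
            n_individuals=int(sub["id"].nunique()),
        )
    return out
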