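"""NOAA solar-position geometry shared by the trace generator and geolocation.

All functions are vectorised over numpy arrays.  Angles in degrees unless a
``_rad`` suffix says otherwise; times are UTC.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "fractional_year",
    "equation_of_time_min",
    "declination_rad",
    "solar_elevation_deg",
    "day_length_hours",
    "latitude_from_day_length",
    "longitude_from_solar_noon",
]


def fractional_year(doy, utc_hour):
    """Fractional year angle (radians) from day-of-year and UTC hour."""
    return 2.0 * np.pi / 365.0 * (np.asarray(doy, float) - 1.0 + (np.asarray(utc_hour, float) - 12.0) / 24.0)


def equation_of_time_min(gamma):
    """Equation of time in minutes (apparent minus mean solar time)."""
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )


def declination_rad(gamma):
    """Solar declination in radians."""
    return (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )


def solar_elevation_deg(lat_deg, lon_deg, doy, utc_hour):
    """Solar elevation above the horizon (degrees), no refraction."""
    gamma = fractional_year(doy, utc_hour)
    decl = declination_rad(gamma)
    eqt = equation_of_time_min(gamma)
    tst = np.asarray(utc_hour, float) * 60.0 + eqt + 4.0 * np.asarray(lon_deg, float)
    ha_rad = np.deg2rad(tst / 4.0 - 180.0)
    lat = np.deg2rad(np.asarray(lat_deg, float))
    sin_el = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(ha_rad)
    return np.rad2deg(np.arcsin(np.clip(sin_el, -1.0, 1.0)))


def day_length_hours(lat_deg, decl_rad, elev_deg):
    """Time the sun spends above elevation ``elev_deg`` (hours in [0, 24]).

    Clipped closed form: 0 for polar night, 24 for polar day.
    """
    lat = np.deg2rad(np.asarray(lat_deg, float))
    h0 = np.deg2rad(elev_deg)
    cos_ha = (np.sin(h0) - np.sin(lat) * np.sin(decl_rad)) / (np.cos(lat) * np.cos(decl_rad))
    cos_ha = np.clip(cos_ha, -1.0, 1.0)
    return 2.0 * np.rad2deg(np.arccos(cos_ha)) / 15.0


def latitude_from_day_length(day_hours, decl_rad, elev_deg, lat_bounds=(-85.0, 85.0)):
    """Invert the day-length relation for latitude.

    Returns nan when the relation carries no information at this declination
    (e.g. near the equinox, when day length is ~12 h at every latitude) or
    when the observed day length is outside the attainable range.
    """
    lo, hi = lat_bounds

    def f(lat):
        return day_length_hours(lat, decl_rad, elev_deg) - day_hours

    flo, fhi = f(lo), f(hi)
    if not np.isfinite(flo) or not np.isfinite(fhi) or flo * fhi > 0:
        return float("nan")
    if flo == 0.0 and fhi == 0.0:  # flat relation: inestimable
        return float("nan")
    return float(brentq(f, lo, hi, xtol=1e-8))


def longitude_from_solar_noon(noon_utc_hour, doy):
    """Longitude (degrees) from the UTC instant of local solar noon."""
    gamma = fractional_year(doy, noon_utc_hour)
    eqt = equation_of_time_min(gamma)
    lon = (720.0 - np.asarray(noon_utc_hour, float) * 60.0 - eqt) / 4.0
    return (lon + 180.0) % 360.0 - 180.0
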