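"""Central registry of every tunable threshold used by the pipeline.

All numeric defaults live in :data:`DEFAULTS`; analysis functions pull their
keyword defaults from here so that a run configuration file can override any
of them in one place.  Day-of-year convention throughout: 1 = 1 January.
"""

from __future__ import annotations

from types import MappingProxyType

DEFAULTS = MappingProxyType(
    {
        # departure-panel analyses
        "min_years": 3,
        "depart_window": (32, 120),  # plausible departure doys (early Feb-late Apr)
        "n_posterior_draws": 1000,
        # conductivity flight detection
        "flight_min_duration_days": 3.0,
        "flight_purity": 0.95,
        "flight_bridge_hours": 2.0,
        # incubation detection
        "bout_range_hours": (4.0, 13.0),
        "incubation_min_consecutive_days": 3,
        "incubation_search_window_days": (6, 25),
        # light-threshold geolocation
        "light_threshold": 2.0,
        "min_night_hours": 0.5,
        "min_abs_declination_deg": 5.0,  # below this, latitude is low-confidence
        # regional split and trend models
        "region_split_lat": 64.0,
        "year_center": 2008,
        "interaction_alpha": 0.05,
        # phenology
        "snow_free_threshold": 1.0 / 3.0,
        "greenup_amplitude_frac": 0.15,
        "neighbor_radius_km": 15.0,
        "neighbor_sd_km": 4.0,
        "greenup_min_amplitude": 0.01,
    }
)
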