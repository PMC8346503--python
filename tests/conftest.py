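import numpy as np
import pandas as pd
import pytest

from migrapheno import synthetic as syn


def frac_doy(ts: pd.Timestamp, year: int) -> float:
    """Fractional day-of-year (1 = 1 Jan 00:00 UTC) of a timestamp."""
    return (ts - pd.Timestamp(f"{year}-01-01", tz="UTC")).total_seconds() / 86400.0 + 1.0


@pytest.fixture
def hand_panel() -> pd.DataFrame:
    """Six-row panel with distinct years for closed-form OLS checks."""
    return pd.DataFrame(
        {
            "id": ["a", "a", "a", "b", "b", "b"],
            "year": [2010, 2011, 2012, 2010, 2011, 2012],
            "depart_doy": [80.0, 78.0, 77.0, 90.0, 89.0, 86.0],
        }
    )


@pytest.fixture
def recovery_panel() -> tuple[pd.DataFrame, dict]:
    spec = syn.PanelSpec(
        n_individuals=124,
        years=(2008, 2020),
        beta_within=-0.43,
        beta_between=-0.46,
        sd_individual_intercept=8.0,
        sd_residual=3.0,
        seed=0,
    )
    return syn.generate_departure_panel(spec, min_years=3)


@pytest.fixture
def noise_free_panel() -> pd.DataFrame:
    spec = syn.PanelSpec(
        n_individuals=30,
        years=(2008, 2020),
        beta_within=-0.5,
        beta_between=-0.5,
        sd_individual_intercept=0.0,
        sd_residual=0.0,
        round_to_day=False,
        seed=3,
    )
    panel, _ = syn.generate_departure_panel(spec, min_years=3)
    return panel
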