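"""Statistics on the directly observed departure panel.

A panel is a tidy DataFrame with columns ``id``, ``year``, ``depart_doy``
and (optionally) ``observed``; one row per bird-year.

Operations
----------
population_trend
    Pooled OLS of departure date on year over every row.
decompose_trend
    Within-subject centering in a random-intercept linear mixed model,
    separating within- from between-individual year slopes.
repeatability
    One-way ANOVA intraclass correlation with the Lessells-Boag effective
    group size.
simulate_individual_slopes
    Per-individual OLS with draws from the joint noninformative posterior of
    the linear-model parameters.
return_rate_glm
    Logistic regression of next-year return on departure date.
subgroup_decomposition
    decompose_trend applied separately per breeding region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .config import DEFAULTS

__all__ = [
    "PopulationTrend",
    "TrendDecomposition",
    "RepeatabilityResult",
    "IndividualSlopeSim",
    "SlopeSimSummary",
    "ReturnRateFit",
    "population_trend",
    "decompose_trend",
    "repeatability",
    "simulate_individual_slopes",
    "return_rate_glm",
    "subgroup_decomposition",
    "validate_panel",
]


class InestimableError(ValueError):
    """A model term cannot be estimated from the data provided."""


def validate_panel(panel: pd.DataFrame, window: tuple[float, float] = DEFAULTS["depart_window"]) -> None:
    """Validate panel structure; warns on dates outside the plausible window."""
    required = {"id", "year", "depart_doy"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel missing columns: {sorted(missing)}")
    if panel.duplicated(["id", "year"]).any():
        raise ValueError("panel has duplicate id-year rows")
    out = ~panel["depart_doy"].between(*window)
    if out.any():
        warnings.warn(
            f"{int(out.sum())} departure dates outside plausible window {window}",
            stacklevel=2,
        )


# ---------------------------------------------------------------------------
# population-level trend
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationTrend:
    slope: float
    se: float
    r2: float
    f: float
    df_model: int
    df_resid: int
    p: float
    n: int


def population_trend(panel: pd.DataFrame) -> PopulationTrend:
    """OLS of departure day-of-year on calendar year over all rows."""
    if panel["year"].nunique() < 2:
        raise ValueError("population trend needs at least two distinct years")
    x = sm.add_constant(panel["year"].to_numpy(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sm.OLS(panel["depart_doy"].to_numpy(float), x).fit()
        r2, f, p = float(res.rsquared), float(res.fvalue), float(res.f_pvalue)
    if not np.isfinite(r2):  # constant response
        r2, f, p = 0.0, 0.0, 1.0
    return PopulationTrend(
        slope=float(res.params[1]),
        se=float(res.bse[1]),
        r2=r2,
        f=f,
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        p=p,
        n=int(res.nobs),
    )


# ---------------------------------------------------------------------------
# within-subject centering decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendDecomposition:
    beta_within: float
    se_within: float
    beta_between: float
    se_between: float
    p_difference: float
    n_individuals: int
    n_observations: int
    var_individual: float
    var_residual: float


def _filter_min_years(panel: pd.DataFrame, min_years: int) -> pd.DataFrame:
    counts = panel.groupby("id")["year"].transform("size")
    return panel.loc[counts >= min_years].copy()


def decompose_trend(panel: pd.DataFrame, min_years: int = DEFAULTS["min_years"]) -> TrendDecomposition:
    """Separate within- and between-individual year slopes.

    Fits ``depart_doy ~ mean_year_i + (year - mean_year_i)`` with a random
    intercept per individual (REML).  ``p_difference`` is the Wald p-value of
    the ``mean_year`` coefficient in the equivalent ``(year, mean_year)``
    parameterization, which tests ``beta_between - beta_within = 0``.
    """
    sub = _filter_min_years(panel, min_years)
    if sub["id"].nunique() < 2:
        raise ValueError("need at least two individuals after min-years filtering")
    mean_year = sub.groupby("id")["year"].transform("mean")
    dev = sub["year"] - mean_year
    if float(np.var(mean_year)) < 1e-12:
        raise InestimableError(
            "between-individual covariate is constant (identical year sets)"
        )

    y = sub["depart_doy"].to_numpy(float)
    center = mean_year.mean()
    exog = np.column_stack(
        [np.ones(len(sub)), mean_year.to_numpy(float) - center, dev.to_numpy(float)]
    )
    groups = sub["id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MixedLM(y, exog, groups=groups).fit(reml=True)

    # reparameterization: depart ~ year + mean_year; mean_year coefficient
    # equals beta_between - beta_within
    exog2 = np.column_stack(
        [
            np.ones(len(sub)),
            sub["year"].to_numpy(float) - center,
            mean_year.to_numpy(float) - center,
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res2 = sm.MixedLM(y, exog2, groups=groups).fit(reml=True)

    return TrendDecomposition(
        beta_within=float(res.params[2]),
        se_within=float(res.bse[2]),
        beta_between=float(res.params[1]),
        se_between=float(res.bse[1]),
        p_difference=float(res2.pvalues[2]),
        n_individuals=int(sub["id"].nunique()),
        n_observations=int(len(sub)),
        var_individual=float(np.asarray(res.cov_re)[0, 0]),
        var_residual=float(res.scale),
    )


def subgroup_decomposition(
    panel: pd.DataFrame,
    region_map: pd.Series | dict,
    min_years: int = DEFAULTS["min_years"],
) -> dict[str, TrendDecomposition]:
    """Run :func:`decompose_trend` separately per mapped region."""
    region_map = pd.Series(region_map)
    if region_map.empty:
        raise ValueError("region map is empty")
    out: dict[str, TrendDecomposition] = {}
    for region, ids in region_map.groupby(region_map).groups.items():
        sub = panel[panel["id"].isin(ids)]
        if sub["id"].nunique() < 2:
            raise ValueError(f"region {region!r} has fewer than two individuals")
        out[str(region)] = decompose_trend(sub, min_years=min_years)
    return out


# ---------------------------------------------------------------------------
# repeatability (one-way ANOVA ICC)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatabilityResult:
    r: float
    se: float
    f: float
    df_among: int
    df_within: int
    p: float
    n0: float
    n_individuals: int
    n_observations: int


def repeatability(panel: pd.DataFrame, min_years: int = DEFAULTS["min_years"]) -> RepeatabilityResult:
    """ANOVA-based intraclass correlation of departure date across individuals.

    Uses ``r = (MS_A - MS_W) / (MS_A + (n0 - 1) MS_W)`` with the
    Lessells-Boag effective group size ``n0 = (N - sum(n_i^2)/N) / (k - 1)``
    and the Fisher large-sample standard error.
    """
    sub = _filter_min_years(panel, min_years)
    sizes = sub.groupby("id")["depart_doy"].size()
    singletons = sizes[sizes < 2].index
    if len(singletons):
        warnings.warn(f"excluding {len(singletons)} individuals with a single observation")
        sub = sub[~sub["id"].isin(singletons)]
        sizes = sub.groupby("id")["depart_doy"].size()
    k = len(sizes)
    if k < 2:
        raise ValueError("repeatability needs at least two individuals")

    y = sub["depart_doy"].to_numpy(float)
    n_total = len(y)
    grand = y.mean()
    group_means = sub.groupby("id")["depart_doy"].mean()
    ni = sizes.to_numpy(float)
    ss_among = float((ni * (group_means.to_numpy() - grand) ** 2).sum())
    ss_within = float(((y - group_means.reindex(sub["id"]).to_numpy()) ** 2).sum())
    df_a, df_w = k - 1, n_total - k
    ms_a, ms_w = ss_among / df_a, ss_within / df_w
    n0 = (n_total - float((ni**2).sum()) / n_total) / df_a
    if ms_w == 0.0:
        r = 1.0
        f = np.inf
        p = 0.0
    else:
        f = ms_a / ms_w
        r = (ms_a - ms_w) / (ms_a + (n0 - 1.0) * ms_w)
        p = float(stats.f.sf(f, df_a, df_w))
    se = float(
        np.sqrt(
            2.0 * (1.0 - r) ** 2 * (1.0 + (n0 - 1.0) * r) ** 2 / (n0 * (n0 - 1.0) * df_a)
        )
    )
    return RepeatabilityResult(
        r=float(r),
        se=se,
        f=float(f),
        df_among=df_a,
        df_within=df_w,
        p=p,
        n0=float(n0),
        n_individuals=k,
        n_observations=n_total,
    )


# ---------------------------------------------------------------------------
# per-individual posterior slope simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndividualSlopeSim:
    id: str
    point_slope: float
    draws: np.ndarray
    prob_negative: float
    q2_5: float
    q97_5: float
    degenerate: bool


@dataclass(frozen=True)
class SlopeSimSummary:
    n_individuals: int
    n_advancing: int
    pct_advancing: float
    q2_5: float
    q97_5: float
    mean_prob_negative: float


def simulate_individual_slopes(
    panel: pd.DataFrame,
    n_draws: int = DEFAULTS["n_posterior_draws"],
    seed: Optional[int] = None,
    min_years: int = DEFAULTS["min_years"],
) -> tuple[list[IndividualSlopeSim], SlopeSimSummary]:
    """Per-individual OLS slopes with joint-posterior simulation draws.

    For each individual with >= ``min_years`` observations, fits OLS of
    departure date on year, then draws ``sigma^2`` from its scaled
    inverse-chi-square marginal on the residual df and the coefficients from
    the conditional normal — the standard noninformative joint posterior of
    ordinary linear-model parameters.  Individuals with zero residual
    variance get a degenerate posterior at the point estimate and are
    flagged.
    """
    rng = np.random.default_rng(seed)
    sub = _filter_min_years(panel, min_years)
    results: list[IndividualSlopeSim] = []
    for ind, g in sub.groupby("id", sort=True):
        x = np.column_stack([np.ones(len(g)), g["year"].to_numpy(float)])
        y = g["depart_doy"].to_numpy(float)
        beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        df = len(g) - 2
        sse = float(resid @ resid)
        xtx_inv = np.linalg.inv(x.T @ x)
        if df <= 0 or sse <= 1e-12:
            draws = np.full(n_draws, beta[1])
            degenerate = True
        else:
            sigma2 = sse / rng.chisquare(df, size=n_draws)
            z = rng.standard_normal((n_draws, 2))
            chol = np.linalg.cholesky(xtx_inv)
            draws = beta[1] + np.sqrt(sigma2) * (z @ chol.T)[:, 1]
            degenerate = False
        results.append(
            IndividualSlopeSim(
                id=str(ind),
                point_slope=float(beta[1]),
                draws=draws,
                prob_negative=float(np.mean(draws < 0)),
                q2_5=float(np.quantile(draws, 0.025)),
                q97_5=float(np.quantile(draws, 0.975)),
                degenerate=degenerate,
            )
        )
    if not results:
        raise ValueError("no individuals pass the min-years filter")
    points = np.array([r.point_slope for r in results])
    all_draws = np.concatenate([r.draws for r in results])
    n_adv = int((points < 0).sum())
    summary = SlopeSimSummary(
        n_individuals=len(results),
        n_advancing=n_adv,
        pct_advancing=100.0 * n_adv / len(results),
        q2_5=float(np.quantile(all_draws, 0.025)),
        q97_5=float(np.quantile(all_draws, 0.975)),
        mean_prob_negative=float(np.mean([r.prob_negative for r in results])),
    )
    return results, summary


# ---------------------------------------------------------------------------
# next-year return GLM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReturnRateFit:
    slope: float
    se: float
    z: float
    df_resid: int
    p: float
    n: int


def return_rate_glm(panel: pd.DataFrame) -> ReturnRateFit:
    """Logistic regression of next-year return on departure date.

    The response is constructed from the panel itself: a bird-year counts as
    "returned" when the same individual appears in the following calendar
    year.  The final panel year is excluded (return unobservable).
    """
    last_year = int(panel["year"].max())
    seen = set(zip(panel["id"], panel["year"]))
    sub = panel[panel["year"] < last_year].copy()
    if sub.empty:
        raise ValueError("panel spans a single year; return is unobservable")
    sub["returned"] = [
        int((i, y + 1) in seen) for i, y in zip(sub["id"], sub["year"])
    ]
    if sub["returned"].nunique() < 2:
        raise InestimableError("complete separation: all bird-years returned or none did")
    x = sm.add_constant(sub["depart_doy"].to_numpy(float))
    res = sm.GLM(sub["returned"].to_numpy(float), x, family=sm.families.Binomial()).fit()
    return ReturnRateFit(
        slope=float(res.params[1]),
        se=float(res.bse[1]),
        z=float(res.tvalues[1]),
        df_resid=int(res.df_resid),
        p=float(res.pvalues[1]),
        n=int(res.nobs),
    )
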