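import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from migrapheno import departures as dep
from migrapheno import synthetic as syn


def brute_force_icc(groups: list[list[float]]):
    """Two-loop one-way ANOVA ICC with Lessells-Boag effective group size."""
    all_vals = [v for g in groups for v in g]
    n_total, k = len(all_vals), len(groups)
    grand = sum(all_vals) / n_total
    ss_a = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_w = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    ms_a = ss_a / (k - 1)
    ms_w = ss_w / (n_total - k)
    n0 = (n_total - sum(len(g) ** 2 for g in groups) / n_total) / (k - 1)
    if ms_w == 0:
        return 1.0, float("inf"), n0
    r = (ms_a - ms_w) / (ms_a + (n0 - 1) * ms_w)
    return r, ms_a / ms_w, n0


def _panel_from_groups(groups: list[list[float]]) -> pd.DataFrame:
    rows = []
    for i, g in enumerate(groups):
        for j, v in enumerate(g):
            rows.append((f"i{i}", 2000 + j, float(v)))
    return pd.DataFrame(rows, columns=["id", "year", "depart_doy"])


class TestPopulationTrend:
    def test_constant_dates(self):
        panel = pd.DataFrame(
            {"id": list("abcd"), "year": [2010, 2011, 2012, 2013], "depart_doy": [100.0] * 4}
        )
        res = dep.population_trend(panel)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.r2 == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_slope(self, noise_free_panel):
        res = dep.population_trend(noise_free_panel)
        assert res.slope == pytest.approx(-0.5, abs=1e-9)

    def test_hand_ols_oracle(self, hand_panel):
        # closed-form OLS via normal equations
        x = hand_panel["year"].to_numpy(float)
        y = hand_panel["depart_doy"].to_numpy(float)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        res = dep.population_trend(hand_panel)
        assert res.slope == pytest.approx(slope, abs=1e-8)
        assert res.n == 6

    def test_single_year_errors(self):
        panel = pd.DataFrame({"id": ["a", "b"], "year": [2010, 2010], "depart_doy": [90.0, 95.0]})
        with pytest.raises(ValueError):
            dep.population_trend(panel)


class TestDecomposeTrend:
    def test_noise_free_equal_slopes(self):
        spec = syn.PanelSpec(
            n_individuals=40, years=(2008, 2020), beta_within=-0.5, beta_between=-0.5,
            sd_individual_intercept=0.0, sd_residual=0.01, round_to_day=False, seed=2,
        )
        panel, _ = syn.generate_departure_panel(spec, min_years=3)
        d = dep.decompose_trend(panel)
        assert d.beta_within == pytest.approx(-0.5, abs=1e-2)
        assert d.beta_between == pytest.approx(-0.5, abs=1e-2)
        assert d.p_difference > 0.2

    def test_parameter_recovery(self, recovery_panel):
        panel, truth = recovery_panel
        d = dep.decompose_trend(panel)
        assert abs(d.beta_within - truth["beta_within"]) < 2 * d.se_within
        assert abs(d.beta_between - truth["beta_between"]) < 2 * d.se_between
        assert d.n_individuals == panel["id"].nunique()

    def test_min_years_filter_row_count(self, recovery_panel):
        panel, _ = recovery_panel
        extra = pd.DataFrame(
            {"id": ["solo1", "solo2"], "year": [2010, 2011], "depart_doy": [90.0, 91.0]}
        )
        aug = pd.concat([panel, extra], ignore_index=True)
        d = dep.decompose_trend(aug, min_years=3)
        assert d.n_observations == len(panel)

    def test_identical_year_sets_inestimable(self):
        years = [2010, 2011, 2012]
        panel = pd.DataFrame(
            [(f"i{i}", y, 90.0 + i + 0.1 * y) for i in range(5) for y in years],
            columns=["id", "year", "depart_doy"],
        )
        with pytest.raises(dep.InestimableError):
            dep.decompose_trend(panel, min_years=3)

    def test_pooled_slope_consistency_when_slopes_equal(self, noise_free_panel):
        # with beta_within == beta_between the pooled OLS slope and both
        # decomposition slopes must agree
        pop = dep.population_trend(noise_free_panel)
        d = dep.decompose_trend(noise_free_panel)
        assert pop.slope == pytest.approx(-0.5, abs=1e-6)
        assert d.beta_within == pytest.approx(pop.slope, abs=1e-4)
        assert d.beta_between == pytest.approx(pop.slope, abs=1e-4)


class TestRepeatability:
    def test_perfectly_repeatable(self):
        groups = [[80.0] * 4, [90.0] * 4, [100.0] * 4]
        res = dep.repeatability(_panel_from_groups(groups), min_years=2)
        assert res.r == 1.0
        assert res.p == 0.0

    def test_hand_panel_oracle(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 6.0, 8.0], [2.0, 2.0, 5.0]]
        r, f, n0 = brute_force_icc(groups)
        res = dep.repeatability(_panel_from_groups(groups), min_years=2)
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.f == pytest.approx(f, abs=1e-12)
        assert res.n0 == pytest.approx(n0, abs=1e-12)
        assert res.df_among == 2

    def test_zero_repeatability_limit(self):
        # identical group means, all variance within
        groups = [[1.0, 5.0], [2.0, 4.0], [3.0, 3.0]]
        res = dep.repeatability(_panel_from_groups(groups), min_years=2)
        assert res.r < 0

    def test_singletons_excluded_with_warning(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]
        panel = pd.concat(
            [
                _panel_from_groups(groups),
                pd.DataFrame({"id": ["solo"], "year": [2000], "depart_doy": [9.0]}),
            ],
            ignore_index=True,
        )
        with pytest.warns(UserWarning):
            res = dep.repeatability(panel, min_years=1)
        assert res.n_individuals == 2

    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=6),
            min_size=2,
            max_size=8,
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force(self, int_groups):
        groups = [[float(v) for v in g] for g in int_groups]
        panel = _panel_from_groups(groups)
        if all(len(set(g)) == 1 for g in groups) and len({g[0] for g in groups}) == 1:
            return  # fully degenerate: zero variance everywhere
        total_ss = panel["depart_doy"].var()
        if total_ss == 0:
            return
        r, f, _ = brute_force_icc(groups)
        res = dep.repeatability(panel, min_years=2)
        assert res.r == pytest.approx(r, abs=1e-10)


class TestIndividualSlopes:
    def test_exact_linear_decline_is_degenerate(self):
        panel = pd.DataFrame(
            {"id": "a", "year": [2010, 2011, 2012, 2013], "depart_doy": [90.0, 89.0, 88.0, 87.0]}
        )
        sims, summary = dep.simulate_individual_slopes(panel, seed=0)
        assert sims[0].degenerate
        assert sims[0].prob_negative == 1.0
        assert summary.pct_advancing == 100.0

    def test_draw_mean_converges_to_ols_slope(self):
        rng = np.random.default_rng(5)
        years = np.arange(2008, 2016)
        panel = pd.DataFrame(
            {"id": "a", "year": years, "depart_doy": 90 - 0.4 * (years - 2008) + rng.normal(0, 2, len(years))}
        )
        sims, _ = dep.simulate_individual_slopes(panel, n_draws=100_000, seed=1)
        s = sims[0]
        mc_se = s.draws.std() / np.sqrt(len(s.draws))
        assert abs(s.draws.mean() - s.point_slope) < 3 * mc_se

    def test_coverage_under_null(self):
        spec = syn.PanelSpec(
            n_individuals=200, years=(2008, 2020), beta_within=0.0, beta_between=0.0,
            sd_individual_intercept=5.0, sd_residual=3.0, seed=21,
        )
        panel, _ = syn.generate_departure_panel(spec, min_years=4)
        sims, _ = dep.simulate_individual_slopes(panel, n_draws=400, seed=2)
        cover = np.mean([s.q2_5 <= 0.0 <= s.q97_5 for s in sims])
        assert 0.88 <= cover <= 0.995

    def test_reported_quantiles_ordered(self, recovery_panel):
        panel, _ = recovery_panel
        sims, summary = dep.simulate_individual_slopes(panel, n_draws=300, seed=3)
        assert summary.q2_5 < summary.q97_5
        for s in sims[:10]:
            assert s.q2_5 <= s.q97_5
            assert 0.0 <= s.prob_negative <= 1.0


class TestReturnRate:
    def test_null_simulation(self):
        zs = []
        for seed in range(25):
            spec = syn.PanelSpec(
                n_individuals=120, years=(2008, 2020), beta_within=0.0, beta_between=0.0,
                sd_individual_intercept=6.0, sd_residual=3.0, seed=seed,
            )
            panel, _ = syn.generate_departure_panel(spec)
            zs.append(dep.return_rate_glm(panel).z)
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.6
        assert np.mean(np.abs(zs) > 1.96) <= 0.2

    def test_power_with_survival_knob(self):
        spec = syn.PanelSpec(
            n_individuals=400, years=(2008, 2020), beta_within=0.0, beta_between=0.0,
            sd_individual_intercept=8.0, sd_residual=3.0, presence_prob=0.7, seed=8,
        )
        panel, _ = syn.generate_departure_panel(spec, return_survival_knob=-0.08)
        res = dep.return_rate_glm(panel)
        assert res.slope < 0
        assert res.z < -2

    def test_separation_flagged(self):
        panel = pd.DataFrame(
            {
                "id": ["a", "a", "a", "b", "b", "b"],
                "year": [2010, 2011, 2012, 2010, 2011, 2012],
                "depart_doy": [90.0, 91.0, 92.0, 85.0, 86.0, 87.0],
            }
        )
        with pytest.raises(dep.InestimableError):
            dep.return_rate_glm(panel)


class TestSubgroupDecomposition:
    def test_recovery_with_identical_slopes(self):
        spec = syn.PanelSpec(
            n_individuals=80, years=(2008, 2020), beta_within=-0.5, beta_between=-0.5,
            sd_individual_intercept=6.0, sd_residual=3.0, seed=13,
        )
        panel, _ = syn.generate_departure_panel(spec, min_years=3)
        ids = sorted(panel["id"].unique())
        rmap = pd.Series({i: ("North" if n % 2 else "South") for n, i in enumerate(ids)})
        out = dep.subgroup_decomposition(panel, rmap)
        assert set(out) == {"North", "South"}
        diff = out["North"].beta_within - out["South"].beta_within
        se = np.hypot(out["North"].se_within, out["South"].se_within)
        assert abs(diff) < 2 * se

    def test_empty_map_errors(self, recovery_panel):
        panel, _ = recovery_panel
        with pytest.raises(ValueError):
            dep.subgroup_decomposition(panel, {})

    def test_tiny_region_errors(self, recovery_panel):
        panel, _ = recovery_panel
        ids = sorted(panel["id"].unique())
        rmap = {ids[0]: "North", ids[1]: "South", ids[2]: "South"}
        with pytest.raises(ValueError):
            dep.subgroup_decomposition(panel, rmap)


def test_validate_panel_warns_outside_window():
    panel = pd.DataFrame({"id": ["a"], "year": [2010], "depart_doy": [300.0]})
    with pytest.warns(UserWarning):
        dep.validate_panel(panel)


def test_validate_panel_duplicate_rows():
    panel = pd.DataFrame({"id": ["a", "a"], "year": [2010, 2010], "depart_doy": [90.0, 91.0]})
    with pytest.raises(ValueError):
        dep.validate_panel(panel)
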