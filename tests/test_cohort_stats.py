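import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from pretermbiome.cohort_stats import (
    bd2_group_test,
    beta_binomial_compare,
    cox_time_varying,
    fit_gestational_trend,
    grid_frame,
    interaction_grid,
    km_curve,
    make_intervals,
    pool_cells,
    proportion_pct,
    quantile_bins,
    quartile_modulation,
    rcs_basis,
)
from pretermbiome.core_data import TaxaTable
from conftest import make_meta


# ---------------------------------------------------------------------------
# gestational-age trends
# ---------------------------------------------------------------------------

class TestGestationalTrend:
    def test_linear_truth_selects_three_knots_and_recovers_slope(self):
        rng = np.random.default_rng(0)
        ga = rng.uniform(16, 28, 500)
        y = 1.0 + 0.05 * ga + rng.normal(0, 0.1, 500)
        fit = fit_gestational_trend(y, ga)
        assert fit.n_knots == 3
        slope = (fit.predict([27.0]) - fit.predict([17.0]))[0] / 10.0
        assert slope == pytest.approx(0.05, rel=0.10)

    def test_constant_truth_is_flat(self):
        rng = np.random.default_rng(1)
        ga = rng.uniform(16, 28, 300)
        y = np.full(300, 2.0) + rng.normal(0, 0.01, 300)
        fit = fit_gestational_trend(y, ga)
        assert fit.r2 < 0.05

    def test_curved_truth_fits_within_noise(self):
        rng = np.random.default_rng(2)
        sigma = 0.2
        ga = rng.uniform(16, 28, 1000)
        truth = 0.002 * (ga - 22.0) ** 3
        y = truth + rng.normal(0, sigma, 1000)
        fit = fit_gestational_trend(y, ga)
        assert fit.n_knots >= 3
        rmse = np.sqrt(np.mean((fit.predict(ga) - truth) ** 2))
        assert rmse < sigma

    def test_rcs_basis_is_linear_in_tails(self):
        knots = np.array([18.0, 22.0, 26.0])
        x = np.array([10.0, 12.0, 14.0])
        basis = rcs_basis(x, knots)
        # below the first knot every column is linear in x
        d1 = basis[1] - basis[0]
        d2 = basis[2] - basis[1]
        np.testing.assert_allclose(d1, d2, atol=1e-9)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        curves, _ = km_curve([38, 39, 40], [0, 0, 0], ["a", "a", "a"])
        assert (curves["a"]["survival"] == 1.0).all()

    def test_product_limit_hand_value(self):
        curves, _ = km_curve([35, 36, 37, 38], [1, 1, 1, 1], ["a"] * 4)
        sf = curves["a"]
        # S(36.5): two of four delivered -> 0.5
        s = sf[sf["time"] <= 36.5]["survival"].iloc[-1]
        assert s == pytest.approx(0.5)

    def test_matches_hand_product_limit_with_censoring(self):
        time = np.array([34, 35, 35, 36, 38, 39.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        curves, _ = km_curve(time, event, ["g"] * 6)
        sf = curves["g"].set_index("time")["survival"]
        # hand product-limit (events precede censoring at tied times):
        # t=34: n=6,d=1 -> 5/6; t=35: n=5,d=1 -> 2/3; t=36: n=3,d=1 -> 4/9;
        # t=39: n=1,d=1 -> 0
        assert sf.loc[34.0] == pytest.approx(5 / 6)
        assert sf.loc[35.0] == pytest.approx(5 / 6 * 4 / 5)
        assert sf.loc[36.0] == pytest.approx(5 / 6 * 4 / 5 * 2 / 3)
        assert sf.loc[39.0] == pytest.approx(0.0)

    def test_identical_groups_identical_curves(self):
        t = [35, 36, 37, 38]
        e = [1, 1, 1, 1]
        curves, _ = km_curve(t + t, e + e, ["a"] * 4 + ["b"] * 4)
        pd.testing.assert_frame_equal(curves["a"], curves["b"])

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            km_curve([0.0, 38.0], [1, 1], ["a", "a"])


# ---------------------------------------------------------------------------
# Cox partial likelihood oracle
# ---------------------------------------------------------------------------

def efron_negloglik(beta, df):
    """Brute-force Efron partial log-likelihood on counting-process rows."""
    beta = float(beta)
    ll = 0.0
    event_times = sorted(df.loc[df["event"] == 1, "stop"].unique())
    for t in event_times:
        at_risk = df[(df["start"] < t) & (t <= df["stop"])]
        dead = at_risk[(at_risk["stop"] == t) & (at_risk["event"] == 1)]
        m = len(dead)
        r_all = np.exp(beta * at_risk["covariate"].to_numpy())
        r_dead = np.exp(beta * dead["covariate"].to_numpy())
        ll += beta * dead["covariate"].sum()
        for j in range(m):
            ll -= np.log(r_all.sum() - j / m * r_dead.sum())
    return -ll


class TestCoxTimeVarying:
    def _fixed_df(self):
        # 6 subjects, fixed covariate, distinct delivery times
        return pd.DataFrame(
            {
                "subject_id": [f"p{i}" for i in range(6)],
                "start": [16.0] * 6,
                "stop": [33.0, 35.0, 36.0, 38.0, 39.0, 40.0],
                "event": [1] * 6,
                "covariate": [1.0, 1.0, 0.0, 1.0, 0.0, 0.0],
            }
        )

    def test_constant_covariate_hr_exactly_one(self):
        df = self._fixed_df()
        df["covariate"] = 1.0
        res = cox_time_varying(df)
        assert res.hazard_ratio == 1.0

    def test_fixed_covariate_matches_brute_force_oracle(self):
        df = self._fixed_df()
        res = cox_time_varying(df)
        oracle = optimize.minimize_scalar(
            efron_negloglik, args=(df,), bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        ).x
        assert res.coef == pytest.approx(oracle, abs=1e-6)
        assert res.ci_lo <= res.hazard_ratio <= res.ci_hi

    def test_time_varying_covariate_matches_oracle(self):
        # exposure switches on mid-pregnancy for two subjects
        df = pd.DataFrame(
            {
                "subject_id": ["a", "a", "b", "b", "c", "d", "e", "f"],
                "start": [16, 22, 16, 22, 16, 16, 16, 16.0],
                "stop": [22, 34, 22, 36, 37, 38, 39, 40.0],
                "event": [0, 1, 0, 1, 1, 1, 1, 1],
                "covariate": [0, 1, 0, 1, 0, 0, 1, 0.0],
            }
        )
        res = cox_time_varying(df)
        oracle = optimize.minimize_scalar(
            efron_negloglik, args=(df,), bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        ).x
        assert res.coef == pytest.approx(oracle, abs=1e-6)

    def test_no_events_raises(self):
        df = self._fixed_df()
        df["event"] = 0
        with pytest.raises(ValueError):
            cox_time_varying(df)


class TestMakeIntervals:
    def _table(self, ra_by_visit, ga_delivery=39.0, outcome="term"):
        ids = [f"sV{v}" for v in range(1, len(ra_by_visit) + 1)]
        ra = pd.DataFrame(
            {"tax": ra_by_visit, "other": [1 - r for r in ra_by_visit]}, index=ids
        )
        meta = make_meta(
            ids,
            subject_id=["subj"] * len(ids),
            visit=list(range(1, len(ids) + 1)),
            ga_sample=[18.0, 22.0, 26.0][: len(ids)],
            ga_delivery=[ga_delivery] * len(ids),
            outcome=[outcome] * len(ids),
        )
        return TaxaTable(ra, meta, check_row_sums=False)

    def test_always_below_collapses_to_single_interval(self):
        t = self._table([1e-4, 1e-4, 1e-4])
        iv = make_intervals(t, "tax", threshold=-2.0)
        assert len(iv) == 1
        row = iv.iloc[0]
        assert (row["start"], row["stop"], row["event"], row["covariate"]) == (
            18.0, 39.0, 1, 0.0,
        )

    def test_crossing_at_visit_two_gives_two_rows(self):
        t = self._table([1e-4, 0.05, 0.05])
        iv = make_intervals(t, "tax", threshold=-2.0)
        assert len(iv) == 2
        assert iv["covariate"].tolist() == [0.0, 1.0]
        assert iv["event"].tolist() == [0, 1]
        assert iv.iloc[0]["stop"] == iv.iloc[1]["start"] == 22.0

    def test_delivery_before_visit_two_single_interval(self):
        t = self._table([0.05], ga_delivery=21.0, outcome="sPTB")
        iv = make_intervals(t, "tax", threshold=-2.0)
        assert len(iv) == 1
        assert iv.iloc[0]["covariate"] == 1.0
        assert iv.iloc[0]["stop"] == 21.0


# ---------------------------------------------------------------------------
# beta-defensin-2 and proportions
# ---------------------------------------------------------------------------

class TestBd2Test:
    def test_identical_groups_zero_difference(self):
        v = np.array([100.0, 200.0, 300.0, 100.0, 200.0, 300.0])
        g = np.array(["a"] * 3 + ["b"] * 3)
        diff, p = bd2_group_test(v, g)
        assert diff == 0.0

    def test_power_against_unit_shift(self):
        rng = np.random.default_rng(3)
        a = 10 ** rng.normal(0, 1, 50)
        b = 10 ** rng.normal(1, 1, 50)
        _, p = bd2_group_test(
            np.concatenate([a, b]), np.array(["a"] * 50 + ["b"] * 50)
        )
        assert p < 0.05

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(4)
        rejections = 0
        runs = 1000
        for _ in range(runs):
            v = 10 ** rng.normal(0, 1, 60)
            g = np.array(["a"] * 30 + ["b"] * 30)
            _, p = bd2_group_test(v, g)
            rejections += p < 0.05
        assert rejections / runs == pytest.approx(0.05, abs=0.02)


class TestBetaBinomial:
    def test_symmetry_gives_half(self):
        c = beta_binomial_compare(5, 20, 5, 20)
        assert c.posterior_prob_diff == pytest.approx(0.5, abs=1e-9)

    def test_matches_monte_carlo_oracle(self):
        c = beta_binomial_compare(9, 10, 1, 10)
        rng = np.random.default_rng(5)
        n_mc = 1_000_000
        p1 = rng.beta(10, 2, n_mc)
        p2 = rng.beta(2, 10, n_mc)
        mc = (p1 > p2).mean()
        assert c.posterior_prob_diff == pytest.approx(mc, abs=0.002)

    def test_extreme_separation(self):
        c = beta_binomial_compare(0, 10, 10, 10)
        assert c.posterior_prob_diff < 0.001

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            beta_binomial_compare(11, 10, 0, 10)


class TestQuartileModulation:
    def test_null_bd2_is_calibrated(self):
        rng = np.random.default_rng(6)
        n_sig = 0
        runs = 100
        for _ in range(runs):
            bd2 = 10 ** rng.normal(3, 0.5, 200)
            y = (rng.random(200) < 0.2).astype(int)
            _, comp = quartile_modulation(bd2, y)
            n_sig += comp.p_value_analog < 0.05
        assert n_sig / runs <= 0.10

    def test_protective_effect_direction(self):
        rng = np.random.default_rng(7)
        bd2 = 10 ** rng.normal(3, 0.5, 2000)
        risk = np.where(bd2 < np.quantile(bd2, 0.25), 0.4, 0.1)
        y = (rng.random(2000) < risk).astype(int)
        tab, comp = quartile_modulation(bd2, y)
        assert tab.loc[0, "proportion"] > tab.loc[3, "proportion"]
        assert comp.posterior_prob_diff > 0.95

    def test_degenerate_ties_fall_in_lowest_bin(self):
        bins = quantile_bins(np.full(20, 7.0), 4)
        assert (bins == 0).all()


class TestInteractionGrid:
    def test_baseline_proportion_from_study_design(self):
        assert proportion_pct(102, 521) == 19.58
        assert proportion_pct(43, 107, 1) == 40.2

    def test_cell_equal_to_baseline_is_even_odds(self):
        c = beta_binomial_compare(102, 521, 102, 521)
        assert c.posterior_prob_diff == pytest.approx(0.5, abs=1e-9)

    def test_tertiles_partition_exactly(self):
        rng = np.random.default_rng(8)
        n = 400
        bd2 = 10 ** rng.normal(3, 0.5, n)
        lac = rng.random(n)
        y = (rng.random(n) < 0.2).astype(int)
        cells = interaction_grid(bd2, lac, y)
        assert sum(c.n_total for c in cells) == n
        gf = grid_frame(cells)
        assert len(gf) == 9
        assert gf["n_sptb"].sum() == y.sum()

    def test_null_grid_is_calibrated(self):
        rng = np.random.default_rng(9)
        runs, any_sig = 60, 0
        for _ in range(runs):
            n = 500
            bd2 = 10 ** rng.normal(3, 0.5, n)
            lac = rng.random(n)
            y = (rng.random(n) < 0.1958).astype(int)
            cells = interaction_grid(bd2, lac, y)
            # baseline taken from the same draw keeps the null exact
            any_sig += any(
                c.p_value_analog_is_small if hasattr(c, "p_value_analog_is_small")
                else (c.n_total > 0 and c.p_vs_baseline < 0.05)
                for c in cells
            )
        assert any_sig / runs <= 0.35  # 9 dependent comparisons per run

    def test_pooling_high_bd2_cells(self):
        rng = np.random.default_rng(10)
        n = 300
        bd2 = 10 ** rng.normal(3, 0.5, n)
        lac = rng.random(n)
        y = (rng.random(n) < 0.2).astype(int)
        cells = interaction_grid(bd2, lac, y)
        pooled = pool_cells(cells, bd2_tertiles={3})
        third = [c for c in cells if c.bd2_tertile == 3]
        assert pooled.n1 == sum(c.n_total for c in third)
        assert pooled.x1 == sum(c.n_sptb for c in third)
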