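import numpy as np
import pytest
from scipy.special import expit

from pretermbiome.error_model import ErrorModel
from pretermbiome.risk_spline import (
    SplineConfig,
    _sample_pg,
    association_significance,
    fit_absolute_abundance_risk,
    fit_adaptive_spline,
    fit_with_measurement_error,
    signed_effect_size,
    threshold_from_curve,
)

FAST = dict(chains=2, warmup=400, draws=400)


class TestPolyaGamma:
    def test_mean_matches_analytic(self):
        # E[PG(b, c)] = b/(2c) tanh(c/2); b/4 at c=0
        rng = np.random.default_rng(0)
        for b, c in [(1.0, 0.5), (10.0, 2.0), (50.0, 0.0), (5.0, 4.0)]:
            draws = _sample_pg(np.full(40_000, b), np.full(40_000, c), rng)
            expected = b / 4 if c == 0 else b / (2 * c) * np.tanh(c / 2)
            assert draws.mean() == pytest.approx(expected, rel=0.01)


class TestAdaptiveSpline:
    def test_degenerate_outcomes_give_flat_fit(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-4, -1, 100)
        fit = fit_adaptive_spline(x, np.zeros(100), SplineConfig(seed=1))
        assert fit.degenerate
        assert np.all(fit.f == 0.0)
        assert signed_effect_size(fit.x_grid, fit.f) == 0.0

    def test_smooth_logistic_truth_recovered(self):
        # truth: risk 0.119 at x=-4 rising to 0.832 at x=-1, |gEff| = 0.713
        rng = np.random.default_rng(2)
        n = 800
        x = rng.uniform(-4, -1, n)
        y = (rng.random(n) < expit(-2 + 1.2 * (x + 4))).astype(float)
        fit = fit_adaptive_spline(x, y, SplineConfig(seed=2, **FAST))
        truth = expit(-2 + 1.2 * (fit.x_grid + 4))
        coverage = np.mean((fit.band_lo <= truth) & (truth <= fit.band_hi))
        assert coverage >= 0.90
        g = signed_effect_size(fit.x_grid, fit.f)
        assert g == pytest.approx(0.713, abs=0.08)

    def test_step_truth_recovered_away_from_jump(self):
        rng = np.random.default_rng(3)
        n = 2000
        x0 = -2.5
        x = rng.uniform(-4, -1, n)
        truth_fn = lambda v: np.where(v >= x0, 0.55, 0.15)
        y = (rng.random(n) < truth_fn(x)).astype(float)
        fit = fit_adaptive_spline(x, y, SplineConfig(seed=3, **FAST))
        away = np.abs(fit.x_grid - x0) > 0.3
        err = np.max(np.abs(fit.f[away] - truth_fn(fit.x_grid[away])))
        assert err < 0.1

    def test_monotone_truth_yields_mostly_monotone_estimate(self):
        rng = np.random.default_rng(4)
        n = 1500
        x = rng.uniform(-4, -1, n)
        y = (rng.random(n) < expit(-2 + 1.2 * (x + 4))).astype(float)
        fit = fit_adaptive_spline(x, y, SplineConfig(seed=4, **FAST))
        viol = np.mean(np.diff(fit.f) < 0)
        assert viol <= 0.10

    def test_baseline_consistency(self):
        rng = np.random.default_rng(5)
        n = 1000
        x = rng.uniform(-4, -1, n)
        y = (rng.random(n) < expit(-2 + 1.2 * (x + 4))).astype(float)
        fit = fit_adaptive_spline(x, y, SplineConfig(seed=5, **FAST))
        _, idx = np.unique(x, return_inverse=True)
        weights = np.bincount(
            np.searchsorted(fit.x_grid, x) if fit.x_grid.size == np.unique(x).size
            else np.digitize(x, fit.x_grid[:-1]),
            minlength=fit.f.size,
        )
        weighted_mean = np.average(fit.f, weights=np.maximum(weights, 1e-12))
        assert weighted_mean == pytest.approx(y.mean(), abs=0.05)

    def test_rejects_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_adaptive_spline(np.zeros(10), np.zeros(10), SplineConfig(seed=1))


class TestEffectSize:
    def test_sign_rules(self):
        x = np.linspace(0, 1, 5)
        assert signed_effect_size(x, np.linspace(0.1, 0.5, 5)) == pytest.approx(0.4)
        assert signed_effect_size(x, np.linspace(0.5, 0.1, 5)) == pytest.approx(-0.4)
        assert signed_effect_size(x, np.full(5, 0.3)) == 0.0


class TestThreshold:
    def test_linear_curve_analytic(self):
        # f = 0.1 + 0.4x on [0,1]: min 0.1, |gEff| 0.4, y* = 0.14 -> x = 0.1
        x = np.linspace(0, 1, 101)
        f = 0.1 + 0.4 * x
        thr = threshold_from_curve(x, f, signed_effect_size(x, f))
        assert thr == pytest.approx(0.1, abs=1e-9)

    def test_piecewise_hand_interpolated(self):
        x = np.array([-4.0, -3.0, -2.0, -1.0, 0.0])
        f = np.array([0.2, 0.2, 0.5, 0.3, 0.6])
        g = signed_effect_size(x, f)
        assert g == pytest.approx(0.4)
        # y* = 0.24; first crossing right of the (leftmost) argmin is in
        # (-3, -2): x = -3 + (0.24-0.2)/(0.5-0.2) = -2.8667
        thr = threshold_from_curve(x, f, g)
        assert thr == pytest.approx(-2.8667, abs=1e-3)

    def test_constant_curve_has_no_threshold(self):
        x = np.linspace(0, 1, 10)
        f = np.full(10, 0.3)
        assert threshold_from_curve(x, f, 0.0) is None

    def test_small_effect_excluded(self):
        x = np.linspace(0, 1, 10)
        f = 0.3 + 0.05 * x
        assert threshold_from_curve(x, f, signed_effect_size(x, f)) is None

    def test_negative_association_mirrors(self):
        x = np.linspace(0, 1, 101)
        f = 0.5 - 0.4 * x  # min at right end; y* = 0.14 at x = 0.9
        thr = threshold_from_curve(x, f, signed_effect_size(x, f))
        assert thr == pytest.approx(0.9, abs=1e-9)


class _FakeFit:
    def __init__(self, p, g=0.5):
        self.p_assoc = p
        self.g_eff = g
        self.q_value = None
        self.degenerate = False
        self.taxon = f"t{p}"
        self.n_detected = 100
        self.baseline = 0.2
        self.threshold = -2.0


class TestFDR:
    def test_bh_matches_hand_stepup(self):
        fits = [_FakeFit(p) for p in (0.01, 0.02, 0.03, 0.04)]
        association_significance(fits)
        # hand BH: q_i = min_{j>=i} p_j * m / j = 0.04 for all four
        assert [f.q_value for f in fits] == pytest.approx([0.04] * 4)

    def test_single_taxon_q_equals_p(self):
        fit = _FakeFit(0.013)
        association_significance([fit])
        assert fit.q_value == pytest.approx(0.013)

    def test_effect_floor_blocks_significance(self):
        fits = [_FakeFit(0.001, g=0.05)]
        tab = association_significance(fits)
        assert not tab["significant"].iloc[0]


class TestMeasurementErrorAveraging:
    def test_no_noise_limit_matches_single_fit(self):
        rng = np.random.default_rng(6)
        n = 1000
        x = rng.uniform(-4, -1, n)
        y = (rng.random(n) < expit(-2 + 1.2 * (x + 4))).astype(float)
        em0 = ErrorModel.constant(0.0)
        cfg = SplineConfig(seed=6, chains=2, warmup=500, draws=1000)
        avg = fit_with_measurement_error(x, y, em0, cfg, n_resamples=3)
        single = fit_adaptive_spline(x, y, SplineConfig(seed=99, chains=2, warmup=500, draws=1000))
        sup = np.max(np.abs(avg.f - np.interp(avg.x_grid, single.x_grid, single.f)))
        assert sup < 0.02

    def test_band_brackets_curve_and_effect_extracted(self):
        rng = np.random.default_rng(7)
        n = 700
        x = rng.uniform(-4, -1, n)
        y = (rng.random(n) < expit(-2 + 1.2 * (x + 4))).astype(float)
        em = ErrorModel.constant(0.15)
        fit = fit_with_measurement_error(
            x, y, em, SplineConfig(seed=7, chains=1, warmup=300, draws=300), n_resamples=3
        )
        assert np.all(fit.band_lo <= fit.f + 1e-12)
        assert np.all(fit.f <= fit.band_hi + 1e-12)
        assert np.all((0 <= fit.f) & (fit.f <= 1))
        assert fit.g_eff > 0.3
        assert fit.threshold is not None
        assert fit.x_grid[0] <= fit.threshold <= fit.x_grid[-1]
        assert fit.p_assoc < 0.05

    def test_heavy_low_abundance_noise_pulls_toward_baseline(self):
        # truth has elevated risk only at very low abundance; huge replicate
        # noise there should flatten the averaged curve toward baseline
        rng = np.random.default_rng(8)
        n = 1200
        x = rng.uniform(-5, -1, n)
        truth = np.where(x < -4, 0.6, 0.2)
        y = (rng.random(n) < truth).astype(float)
        em = ErrorModel(
            grid=np.array([-5.0, -4.0, -1.0]),
            sd_grid=np.array([1.5, 1.5, 0.0]),
            diagnostics=None,
        )
        cfg = SplineConfig(seed=8, chains=1, warmup=300, draws=300)
        noisy = fit_with_measurement_error(x, y, em, cfg, n_resamples=5)
        low = noisy.x_grid < -4
        # with sd 1.5 at the low end the signal there is diluted toward baseline
        assert np.max(np.abs(noisy.f[low] - noisy.baseline)) < np.max(0.6 - noisy.baseline)
        assert np.mean(np.abs(noisy.f[low] - noisy.baseline)) < 0.15


class TestAbsoluteAbundance:
    def test_absolute_scale_signal_separated_from_relative(self):
        # risk depends on absolute abundance; relative abundance is pure noise
        rng = np.random.default_rng(9)
        n = 900
        rel = rng.uniform(-4, -1, n)
        totals = rng.uniform(4, 8, n)  # log10 copies; varies independently
        abs_x = rel + totals
        y = (rng.random(n) < expit(-4.5 + 1.3 * (abs_x - 1.5))).astype(float)
        em = ErrorModel.constant(0.05)
        cfg = SplineConfig(seed=10, chains=1, warmup=300, draws=300)
        fit_abs = fit_absolute_abundance_risk(rel, totals, y, em, cfg, n_resamples=2)
        fit_rel = fit_with_measurement_error(rel, y, em, cfg, n_resamples=2)
        assert abs(fit_abs.g_eff) > abs(fit_rel.g_eff) + 0.1
        assert fit_abs.p_assoc < 0.05
        # covariate grid spans the absolute scale: log10 total + log10 RA
        assert fit_abs.x_grid[0] >= (rel + totals).min() - 1e-9
        assert fit_abs.x_grid[-1] <= (rel + totals).max() + 1e-9
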