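"""Uptake/retention fits, cumulated activity, IDW, decay correction."""
import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from celldose.decay import LU177_LAMBDA_PER_H
from celldose.kinetics import (
    INTERNALIZED,
    MEDIUM,
    MEMBRANE,
    FractionTimeSeries,
    KineticsError,
    cumulated_activity,
    decay_correct,
    fit_daily_retention,
    fit_uptake_curves,
    idw_extrapolate,
)


def make_series(times, f_cs, f_c, activity=1.0):
    f_cs = np.asarray(f_cs, float)
    f_c = np.asarray(f_c, float)
    return FractionTimeSeries(
        added_activity_mbq_ml=activity,
        times_h=np.asarray(times, float),
        fractions={
            MEDIUM: np.clip(1 - f_cs - f_c, 0, None),
            MEMBRANE: f_cs,
            INTERNALIZED: f_c,
        },
        cell_counts={0: 1.0},
    )


class TestUptakeFit:
    def test_noiseless_recovery_to_six_digits(self):
        t = np.arange(0.25, 4.01, 0.25)
        series = make_series(t, 0.001 * t, 0.01 * (1 - np.exp(-1.5 * t)))
        # scale: plateau 10 in arbitrary units via fractions x 1000
        model = fit_uptake_curves(series)
        assert model.internalized_plateau == pytest.approx(0.01, rel=1e-6)
        assert model.internalized_rate == pytest.approx(1.5, rel=1e-6)
        assert model.membrane_slope == pytest.approx(0.001, rel=1e-6)
        assert model.r2[INTERNALIZED] == pytest.approx(1.0)

    def test_default_truth_plateaus_near_two_hours(self):
        """Time to 95% of plateau = ln(20)/k, ~2 h at the default rate."""
        from celldose.synthetic import SyntheticConfig

        k = SyntheticConfig().internalized_rate_per_h
        assert np.log(20.0) / k == pytest.approx(2.0, rel=0.15)

    def test_noisy_plateau_recovery_median_bias(self):
        t = np.linspace(0.25, 4.0, 6)
        truth = 0.01 * (1 - np.exp(-1.5 * t))
        biases = []
        rng = np.random.default_rng(99)
        for _ in range(100):
            noisy = truth * rng.lognormal(-0.005, 0.1, size=t.size)
            series = make_series(t, 0.0005 * t, noisy)
            model = fit_uptake_curves(series, r2_flag_threshold=0.0)
            biases.append(model.internalized_plateau / 0.01 - 1.0)
        assert abs(np.median(biases)) < 0.05

    def test_too_few_points_rejected(self):
        series = make_series([1.0, 2.0, 3.0], [0, 0, 0], [0.1, 0.1, 0.1])
        with pytest.raises(KineticsError):
            fit_uptake_curves(series)

    def test_saturating_membrane_option(self):
        t = np.arange(0.25, 4.01, 0.25)
        series = make_series(t, np.full(t.size, 0.02), 0.01 * (1 - np.exp(-1.5 * t)))
        model = fit_uptake_curves(series, membrane_model="saturating",
                                  r2_flag_threshold=0.0)
        assert model.membrane_intercept == pytest.approx(0.02)
        assert model.membrane_slope == 0.0


class TestDailyRetention:
    def test_noiseless_rate_recovery(self):
        t = 24.0 * np.arange(1, 7)
        lam, sd, r2, flags = fit_daily_retention(t, np.exp(-0.024 * t))
        assert lam == pytest.approx(0.024, rel=1e-6)
        assert r2 == pytest.approx(1.0)

    def test_constant_series_rate_zero(self):
        t = 24.0 * np.arange(1, 7)
        lam, sd, r2, flags = fit_daily_retention(t, np.ones(6))
        assert abs(lam) <= max(sd, 1e-9)

    def test_increasing_series_flagged(self):
        t = 24.0 * np.arange(1, 5)
        lam, sd, r2, flags = fit_daily_retention(t, np.exp(0.01 * t))
        assert any("increas" in f for f in flags)

    def test_confidence_interval_coverage(self):
        """95% CI covers the true rate in >= 90 of 100 noisy realisations."""
        from scipy.stats import t as t_dist

        t = 24.0 * np.arange(1, 7)
        truth = 0.024
        rng = np.random.default_rng(5)
        q = t_dist.ppf(0.975, df=t.size - 2)
        covered = 0
        for _ in range(100):
            y = np.exp(-truth * t) * rng.lognormal(-0.00125, 0.05, size=6)
            lam, sd, _, _ = fit_daily_retention(t, y)
            if abs(lam - truth) <= q * sd:
                covered += 1
        assert covered >= 90


class TestCumulatedActivity:
    def test_zero_fraction(self):
        assert cumulated_activity(0.0, 1e6, 0.0, 24.0) == 0.0

    def test_no_decay_limit(self):
        val = cumulated_activity(0.5, 2.0, 1.0, 3.0, lambda_p_per_h=0.0)
        assert val == pytest.approx(0.5 * 2.0 * 2.0 * 3600.0)

    def test_closed_form_matches_quadrature(self):
        """Closed form vs adaptive quadrature, 1e-10 relative, over a grid."""
        for lam in (1e-4, LU177_LAMBDA_PER_H, 0.1):
            for t1, t2 in ((0.0, 24.0), (4.0, 24.0), (96.0, 120.0)):
                oracle, _ = quad(
                    lambda t: np.exp(-lam * t), t1, t2, epsabs=1e-14, epsrel=1e-13
                )
                got = cumulated_activity(1.0, 1.0, t1, t2, lam)
                assert got == pytest.approx(oracle * 3600.0, rel=1e-10)

    def test_bad_interval_rejected(self):
        with pytest.raises(KineticsError):
            cumulated_activity(1.0, 1.0, 5.0, 4.0)


class TestDecayCorrect:
    def test_zero_elapsed_identity(self):
        assert decay_correct(3.0, 0.0) == 3.0

    def test_one_half_life_doubles(self):
        half_life_h = np.log(2) / LU177_LAMBDA_PER_H
        assert decay_correct(1.0, half_life_h) == pytest.approx(2.0)

    def test_roundtrip_with_forward_decay(self):
        t = 37.3
        measured = 5.0 * np.exp(-LU177_LAMBDA_PER_H * t)
        assert decay_correct(measured, t) == pytest.approx(5.0, rel=1e-12)


class TestIDW:
    @staticmethod
    def grid(rows):
        return pd.DataFrame(
            rows,
            columns=["added_activity_MBq_per_ml", "time_h", "compartment", "fraction"],
        )

    def test_exact_at_node(self):
        g = self.grid([(0.5, 1.0, "internalized", 0.3), (1.0, 1.0, "internalized", 0.6)])
        assert idw_extrapolate(g, 0.5, 1.0, "internalized") == 0.3

    def test_constant_field(self):
        g = self.grid([(0.5, 1.0, "medium", 0.7), (2.5, 3.0, "medium", 0.7)])
        assert idw_extrapolate(g, 1.0, 2.0, "medium") == pytest.approx(0.7)

    def test_one_dimensional_hand_computation(self):
        """Nodes at x=0 (v=0) and x=1 (v=1), query x=0.25, p=2 -> 1/10."""
        g = self.grid([(1.0, 0.0, "medium", 0.0), (10.0, 0.0, "medium", 1.0)])
        # log10 axis turns activities 1 and 10 into x = 0 and 1
        got = idw_extrapolate(g, 10**0.25, 0.0, "medium", power=2.0)
        assert got == pytest.approx(0.1, rel=1e-9)

    def test_bounded_by_node_values(self):
        g = self.grid(
            [(0.1, 0.0, "medium", 0.2), (1.0, 2.0, "medium", 0.9), (2.5, 4.0, "medium", 0.5)]
        )
        v = idw_extrapolate(g, 0.6, 1.0, "medium")
        assert 0.2 <= v <= 0.9

    def test_extrapolation_warns(self):
        g = self.grid([(0.5, 1.0, "medium", 0.3), (2.5, 1.0, "medium", 0.6)])
        with pytest.warns(UserWarning, match="extrapolat"):
            idw_extrapolate(g, 0.1, 1.0, "medium")


def test_pipeline_cumulated_matches_generator_truth():
    """Fit + integrate on noiseless data reproduces analytic integrals <0.1%."""
    from celldose.kinetics import build_cumulated_table
    from celldose.synthetic import (
        SyntheticConfig,
        generate_uptake_dataset,
        ground_truth_cumulated,
    )

    cfg = SyntheticConfig(cv_fractions=0.0, cv_counts=0.0, cv_added_activity=0.0)
    series, _, _ = generate_uptake_dataset(cfg, seed=0)
    a0 = 1.0
    model = fit_uptake_curves(series[a0])
    got = build_cumulated_table(series[a0], model, a0_bq=a0 * 1e6)
    truth = ground_truth_cumulated(cfg, a0)
    for interval in truth.index:
        for channel in truth.columns:
            assert got.loc[interval, channel] == pytest.approx(
                truth.loc[interval, channel], rel=1e-3
            )
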