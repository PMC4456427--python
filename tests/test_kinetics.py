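import math

import numpy as np
import pytest

from ecistools.core import ChannelTrace, extract_channel
from ecistools.errors import (
    CalibrationError,
    DataError,
    DomainError,
    FitError,
)
from ecistools.kinetics import (
    WoundEvent,
    attachment_slope,
    coverage_from_capacitance,
    detect_wound,
    fit_healing_sigmoid,
    healing_time,
    migration_rate,
)
from ecistools.simulate import simulate_timecourse

from conftest import compressed_config

DT_H = 160.0 / 3600.0


def r_trace(times_h, values, well="A1"):
    return ChannelTrace(np.asarray(times_h, float),
                        np.asarray(values, float), "R", 4000.0, well)


def logistic(t, base, plat, k, t50):
    return base + (plat - base) / (1.0 + np.exp(-k * (t - t50)))


class TestDetectWound:
    def test_wound_time_on_simulated_trace(self):
        # compressed maturation, wound scheduled at exactly 600.0 h
        cfg = compressed_config(
            wound=compressed_config().wound.__class__(time_h=600.0),
            duration_h=620.0)
        ts, _ = simulate_timecourse(cfg)
        tr = extract_channel(ts, "A1", 4000.0, "R")
        ev = detect_wound(tr, 2600.0)
        assert abs(ev.t_wound_h - 600.0) <= DT_H
        assert ev.baseline_ohm == pytest.approx(2600.0, rel=0.01)

    def test_monotone_rising_trace_has_no_wound(self):
        t = np.arange(0, 24, DT_H)
        with pytest.raises(DataError, match="no wound"):
            detect_wound(r_trace(t, 3000 + 400 * t), 2600.0)

    def test_trace_never_covered_has_no_wound(self):
        t = np.arange(0, 24, DT_H)
        with pytest.raises(DataError, match="2x"):
            detect_wound(r_trace(t, np.full(t.size, 2600.0)), 2600.0)

    def test_two_wounds_returns_first_rest_by_windowing(self):
        t = np.arange(0, 72, DT_H)
        v = np.full(t.size, 8500.0)
        for tw in (20.0, 50.0):   # wound + fast recovery
            seg = (t >= tw) & (t < tw + 8.0)
            v[seg] = 2600.0 + 5900.0 * np.clip((t[seg] - tw) / 6.0, 0, 1)
        tr = r_trace(t, v)
        first = detect_wound(tr, 2600.0)
        assert abs(first.t_wound_h - 20.0) <= DT_H
        second = detect_wound(tr.slice(30.0, 72.0), 2600.0)
        assert abs(second.t_wound_h - 50.0) <= DT_H


class TestSigmoidFit:
    def test_noise_free_recovery_of_control_parameters(self):
        t = np.arange(0, 24, DT_H)
        tr = r_trace(t, logistic(t, 2600, 8500, 0.54, 7.06))
        fit = fit_healing_sigmoid(tr, WoundEvent(0.0, 2600.0), window_h=24.0)
        assert fit.converged
        assert fit.t50 == pytest.approx(7.06, abs=1e-6)
        assert fit.hill_slope == pytest.approx(0.54, abs=1e-6)
        assert fit.r_base == pytest.approx(2600.0, abs=1e-3)
        assert fit.r_plateau == pytest.approx(8500.0, abs=1e-3)

    def test_constant_trace_flagged_unconverged(self):
        t = np.arange(0, 24, DT_H)
        fit = fit_healing_sigmoid(r_trace(t, np.full(t.size, 5000.0)),
                                  WoundEvent(0.0, 5000.0), window_h=24.0)
        assert not fit.converged
        with pytest.raises(FitError):
            healing_time(fit)

    def test_too_few_samples_rejected(self):
        t = np.arange(0, 0.5, DT_H)
        with pytest.raises(DataError):
            fit_healing_sigmoid(r_trace(t, 3000 + t), WoundEvent(0.0, 2600.0),
                                window_h=0.5)

    def test_fit_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 24, DT_H)
        y = logistic(t, 2600, 8500, 0.54, 7.06) + rng.normal(0, 118.0, t.size)
        fit = fit_healing_sigmoid(r_trace(t, y), WoundEvent(0.0, 2600.0),
                                  window_h=24.0)
        # oracle: 200x200 grid over (t50, k) with analytic LSQ for the
        # two linear parameters (base, plateau)
        best = (np.inf, None)
        for t50 in np.linspace(4.0, 10.0, 200):
            for k in np.linspace(0.2, 1.0, 200):
                s = 1.0 / (1.0 + np.exp(-k * (t - t50)))
                design = np.column_stack([1.0 - s, s])
                coef, res, *_ = np.linalg.lstsq(design, y, rcond=None)
                sse = float(res[0]) if res.size else float(
                    np.sum((design @ coef - y) ** 2))
                if sse < best[0]:
                    best = (sse, (t50, k))
        t50_star, k_star = best[1]
        assert fit.t50 == pytest.approx(t50_star, abs=0.05)
        assert fit.hill_slope == pytest.approx(k_star, abs=0.01)

    def test_parameter_recovery_under_noise(self):
        # mean recovered parameters within one reference-SE scale of truth
        t = np.arange(0, 24, DT_H)
        truth = dict(base=2600.0, plat=8500.0, k=0.54, t50=7.06)
        t50s, ks = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = logistic(t, truth["base"], truth["plat"], truth["k"],
                         truth["t50"]) + rng.normal(0, 0.02 * 5900.0, t.size)
            fit = fit_healing_sigmoid(r_trace(t, y), WoundEvent(0.0, 2600.0),
                                      window_h=24.0)
            assert fit.converged
            t50s.append(fit.t50)
            ks.append(fit.hill_slope)
        assert np.mean(t50s) == pytest.approx(7.06, abs=0.27)
        assert np.mean(ks) == pytest.approx(0.54, abs=0.07)


class TestHealingTime:
    def test_half_threshold_is_t50(self):
        fit = _fit(0.54, 7.06)
        assert healing_time(fit, 0.5) == pytest.approx(7.06)

    def test_closed_form_at_95(self):
        fit = _fit(0.54, 7.06)
        expect = 7.06 + math.log(19.0) / 0.54   # 12.513 h
        assert healing_time(fit, 0.95) == pytest.approx(expect)
        assert expect == pytest.approx(12.51, abs=0.01)

    def test_strictly_monotone_in_threshold(self):
        fit = _fit(0.54, 7.06)
        assert healing_time(fit, 0.99) > healing_time(fit, 0.95)

    def test_strictly_decreasing_in_hill_slope(self):
        times = [healing_time(_fit(k, 7.06), 0.95)
                 for k in (0.3, 0.4, 0.54, 0.8)]
        assert np.all(np.diff(times) < 0)


def _fit(k, t50):
    from ecistools.kinetics import SigmoidFit
    return SigmoidFit(2600.0, 8500.0, k, t50, 1.0, True)


class TestMigrationRate:
    def test_control_rate(self):
        mr = migration_rate(11.69, 125.0)
        assert mr.rate_um_per_h == pytest.approx(10.69, abs=0.005)

    def test_case_rate(self):
        mr = migration_rate(14.53, 125.0)
        assert mr.rate_um_per_h == pytest.approx(8.60, abs=0.005)

    def test_linearity_in_radius(self):
        assert migration_rate(10.0, 250.0).rate_um_per_h == pytest.approx(
            2.0 * migration_rate(10.0, 125.0).rate_um_per_h)

    def test_diameter_convention(self):
        assert migration_rate(10.0, 125.0, "diameter").rate_um_per_h == \
            pytest.approx(25.0)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            migration_rate(0.0, 125.0)

    def test_rate_invariant_to_affine_rescaling_of_trace(self):
        t = np.arange(0, 24, DT_H)
        y = logistic(t, 2600, 8500, 0.54, 7.06)
        ev = WoundEvent(0.0, 2600.0)
        f1 = fit_healing_sigmoid(r_trace(t, y), ev, window_h=24.0)
        f2 = fit_healing_sigmoid(r_trace(t, 3.0 * y + 500.0), ev,
                                 window_h=24.0)
        r1 = migration_rate(healing_time(f1, 0.95)).rate_um_per_h
        r2 = migration_rate(healing_time(f2, 0.95)).rate_um_per_h
        assert r1 == pytest.approx(r2, rel=1e-6)


class TestCoverage:
    def test_endpoints_and_midpoint(self):
        t = np.arange(3.0)
        c_free, c_conf = 40e-9, 10e-9
        tr = ChannelTrace(t, np.array([c_free, 25e-9, c_conf]), "C",
                          64000.0, "A1")
        cov = coverage_from_capacitance(tr, c_free, c_conf)
        np.testing.assert_allclose(cov.coverage, [0.0, 0.5, 1.0])
        assert cov.clipped_fraction == 0.0

    def test_bad_calibration_rejected(self):
        tr = ChannelTrace(np.arange(2.0), np.array([1e-9, 2e-9]), "C",
                          64000.0, "A1")
        with pytest.raises(CalibrationError):
            coverage_from_capacitance(tr, 1e-9, 2e-9)

    def test_matches_simulator_front_model(self, fast_config):
        # area mixing makes the *parallel* capacitance exactly linear in
        # coverage, so the linear calibration recovers the front model
        ts, truth = simulate_timecourse(fast_config)
        tr = extract_channel(ts, "A1", 64000.0, "C", convention="parallel")
        tw = truth["wells"]["A1"]["wound_time_h"]
        v = truth["wells"]["A1"]["front_speed_um_h"]
        # calibrate from the simulator itself: cell-free at the wound
        # sample, confluent just before it
        iw = int(np.argmin(np.abs(tr.times_h - tw)))
        c_free = tr.values[iw]
        c_conf = tr.values[iw - 2]
        est = (c_free - tr.values) / (c_free - c_conf)  # two-point linear map
        from ecistools.simulate import simulate_wound_recovery_coverage
        sel = (tr.times_h >= tw) & (tr.times_h <= tw + 125.0 / v)
        expect = simulate_wound_recovery_coverage(tr.times_h[sel] - tw, v,
                                                  125.0)
        np.testing.assert_allclose(est[sel], expect, atol=1e-6)

    def test_series_capacitance_tracks_front_monotonically(self, fast_config):
        # the series convention is only approximately coverage-linear:
        # assert endpoints and monotone recovery instead of exact identity
        ts, truth = simulate_timecourse(fast_config)
        tr = extract_channel(ts, "A1", 64000.0, "C")
        tw = truth["wells"]["A1"]["wound_time_h"]
        v = truth["wells"]["A1"]["front_speed_um_h"]
        iw = int(np.argmin(np.abs(tr.times_h - tw)))
        cov = coverage_from_capacitance(tr, tr.values[iw], tr.values[iw - 2])
        sel = (tr.times_h >= tw) & (tr.times_h <= tw + 125.0 / v)
        c = cov.coverage[sel]
        assert c[0] == pytest.approx(0.0, abs=1e-9)
        assert c[-1] == pytest.approx(1.0, abs=0.01)
        assert np.all(np.diff(c) >= -1e-9)


class TestAttachmentSlope:
    def test_exact_line_recovers_slope(self):
        t = np.arange(0, 12, DT_H)
        fit = attachment_slope(r_trace(t, 1000.0 + 9.43 * t), (0.0, 12.0))
        assert fit.slope_ohm_per_h == pytest.approx(9.43, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_trace_gives_zero_slope(self):
        t = np.arange(0, 12, DT_H)
        fit = attachment_slope(r_trace(t, np.full(t.size, 1000.0)),
                               (0.0, 12.0))
        assert fit.slope_ohm_per_h == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_sums_on_small_fixture(self):
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        v = np.array([100.0, 104.0, 113.0, 119.0, 123.0])
        fit = attachment_slope(r_trace(t, v), (0.0, 24.0), min_samples=5,
                               plateau_fraction=1.0)
        n = t.size
        slope = (n * np.sum(t * v) - np.sum(t) * np.sum(v)) / (
            n * np.sum(t * t) - np.sum(t) ** 2)
        assert fit.slope_ohm_per_h == pytest.approx(slope, rel=1e-12)

    def test_stops_at_plateau(self):
        t = np.arange(0, 24, DT_H)
        v = np.minimum(1000.0 + 9.43 * t, 1000.0 + 9.43 * 6.0)
        fit = attachment_slope(r_trace(t, v), (0.0, 24.0))
        assert fit.slope_ohm_per_h == pytest.approx(9.43, rel=0.02)
        assert fit.window_h[1] <= 7.0

    def test_window_must_be_in_first_day(self):
        t = np.arange(0, 30, DT_H)
        with pytest.raises(DomainError):
            attachment_slope(r_trace(t, 1000 + t), (0.0, 30.0))

    def test_too_few_samples_rejected(self):
        with pytest.raises(DataError):
            attachment_slope(r_trace(np.arange(5.0), np.arange(5.0)),
                             (0.0, 24.0))
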