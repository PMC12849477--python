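"""Transformation frequency, induction rates, and 4PL reporter fits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from comphet import kinetics as k
from comphet import synthetic_data as sd


def _pc(sel, tot, sel_dil=1.0, tot_dil=1.0, ctrl_sel=0, ctrl_tot=None, t=0.0):
    return k.PlateCount(
        condition="c",
        time_h=t,
        selective_cfu=sel,
        total_cfu=tot,
        selective_dilution=sel_dil,
        total_dilution=tot_dil,
        control_selective_cfu=ctrl_sel,
        control_total_cfu=ctrl_tot if ctrl_tot is not None else tot,
    )


class TestTransformationFrequency:
    def test_peak_magnitude_arithmetic(self):
        entry = k.transformation_frequency(_pc(100, 10_000))
        assert not entry.censored
        assert entry.tf == pytest.approx(1e-2)

    def test_zero_selective_censored_at_limit(self):
        entry = k.transformation_frequency(_pc(0, 10_000))
        assert entry.censored
        assert entry.tf == entry.detection_limit == 1e-9

    def test_control_derived_limit(self):
        entry = k.transformation_frequency(_pc(2, 10_000, ctrl_sel=5, ctrl_tot=10_000))
        # selective count below the reversion background -> censored at 5e-4
        assert entry.censored
        assert entry.detection_limit == pytest.approx(5e-4)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            _pc(1, 0)

    @given(scale=st.floats(0.1, 10.0))
    def test_dilution_invariance(self, scale):
        """Scaling counts and inversely scaling dilutions leaves tf unchanged."""
        base = k.transformation_frequency(_pc(80, 8000, sel_dil=2.0, tot_dil=4.0))
        scaled = k.transformation_frequency(
            _pc(80, 8000, sel_dil=2.0 * scale, tot_dil=4.0 * scale)
        )
        assert scaled.tf == pytest.approx(base.tf)

    def test_poisson_recovery(self):
        # simulated platings from tf_true=1e-3 recover the mean within 3 se
        tfs = []
        for s in range(50):
            pc = sd.simulate_plating([1e-3], [0], 1e6, 0.0, seed=100 + s)[0]
            tfs.append(k.transformation_frequency(pc).tf)
        se = np.std(tfs, ddof=1) / np.sqrt(len(tfs))
        assert abs(np.mean(tfs) - 1e-3) < 3 * se


class TestInductionRate:
    def _series(self, times, tfs, censored=None):
        censored = censored or [False] * len(times)
        entries = [
            k.TFEntry(t, tf if not c else 1e-9, c, 1e-9)
            for t, tf, c in zip(times, tfs, censored)
        ]
        return k.TFSeries(entries)

    def test_exact_exponential_rise(self):
        times = np.arange(0, 13, 2.0)
        tfs = 10.0 ** (-6 + 0.5 * times)
        rate = k.max_induction_rate(self._series(times, tfs))
        assert rate.max_log_slope == pytest.approx(0.5, abs=1e-12)

    def test_flat_series_zero_rate(self):
        rate = k.max_induction_rate(self._series([0, 4, 8, 12], [1e-4] * 4))
        assert rate.max_log_slope == pytest.approx(0.0, abs=1e-12)

    def test_censored_points_excluded(self):
        times = [0, 4, 8, 12, 16]
        tfs = [1e-9, 1e-9, 1e-6, 1e-4, 1e-2]
        series = self._series(times, tfs, censored=[True, True, False, False, False])
        rate = k.max_induction_rate(series)
        assert rate.window[0] >= 8  # censored early points never enter a window
        assert np.isfinite(rate.max_log_slope)

    def test_insufficient_points_error(self):
        with pytest.raises(ValueError, match="uncensored"):
            k.max_induction_rate(self._series([0, 4], [1e-4, 1e-3]))

    def test_generative_slope_recovery(self):
        """At 6-8 timepoint sampling, the window slope tracks the true max slope."""
        params = sd.TFTrajectoryParams()  # defaults: 1e-8 -> 1e-2, onset 12 h, 0.5/h
        times = np.arange(0, 29, 4.0)  # 8 timepoints
        errs = []
        for s in range(20):
            tf_true = sd.simulate_tf_trajectory(params, times)
            counts = sd.simulate_plating(tf_true, times, 5e9, 1e-9, seed=200 + s)
            series = k.tf_series(counts)
            rate = k.max_induction_rate(series)
            errs.append(abs(rate.max_log_slope - 0.5) / 0.5)
        assert np.median(errs) <= 0.2


class TestOdAtPeak:
    def _series(self, times, tfs, censored=None):
        censored = censored or [False] * len(times)
        entries = [
            k.TFEntry(t, tf if not c else 1e-9, c, 1e-9)
            for t, tf, c in zip(times, tfs, censored)
        ]
        return k.TFSeries(entries)

    def test_peak_lookup(self):
        times = np.array([0.0, 5.0, 10.0, 15.0])
        od = np.array([0.2, 0.5, 0.9, 1.5])
        series = self._series(times, [1e-6, 1e-4, 1e-2, 1e-3])
        assert k.od_at_peak_tf(times, od, series) == (0.9, 10.0)

    def test_tie_takes_earliest(self):
        times = np.array([0.0, 5.0, 10.0])
        series = self._series(times, [1e-2, 1e-4, 1e-2])
        od, t = k.od_at_peak_tf(times, np.array([0.2, 0.5, 0.9]), series)
        assert (od, t) == (0.2, 0.0)

    def test_all_censored_errors(self):
        times = np.array([0.0, 5.0])
        series = self._series(times, [1e-9, 1e-9], censored=[True, True])
        with pytest.raises(ValueError, match="censored"):
            k.od_at_peak_tf(times, np.array([0.1, 0.2]), series)


class TestNormalizeReporter:
    def test_constant_ratio(self):
        nr = np.linspace(100, 1000, 20)
        out = k.normalize_reporter(2 * nr, nr)
        np.testing.assert_allclose(out, 2.0)

    def test_zero_nilered_masked_with_warning(self):
        nr = np.array([100.0, 0.0, 300.0])
        with pytest.warns(UserWarning, match="masking"):
            out = k.normalize_reporter(np.array([1.0, 1.0, 3.0]), nr)
        assert np.isnan(out[1]) and out[0] == pytest.approx(0.01)

    def test_all_below_floor_errors(self):
        with pytest.raises(ValueError):
            k.normalize_reporter(np.ones(3), np.zeros(3))

    def test_recovers_4pl_shape_pre_plateau(self):
        p4 = k.FourPLParams(a=0.05, d=1.0, c=12.0, b=4.0)
        rp = sd.ReporterParams(fourpl=p4, substrate_capacity=np.inf, growth=sd.GrowthParams())
        t = np.linspace(0, 30, 61)
        mug, nr = sd.simulate_reporter(rp, t, seed=1)
        norm = k.normalize_reporter(mug, nr)
        np.testing.assert_allclose(norm, k.fourpl(t, 0.05, 1.0, 12.0, 4.0), rtol=1e-9)


class TestFourPL:
    def test_noiseless_recovery(self):
        t = np.linspace(0.5, 25, 30)
        y = k.fourpl(t, 0.0, 1.0, 10.0, 4.0)
        fit = k.fit_four_pl(t, y)
        scale = 1.0  # d - a
        assert abs(fit.params.a - 0.0) / scale <= 1e-6
        assert abs(fit.params.d - 1.0) <= 1e-6
        assert abs(fit.params.c - 10.0) / 10.0 <= 1e-6
        assert abs(fit.params.b - 4.0) / 4.0 <= 1e-6

    def test_peak_time_closed_form_matches_numeric(self):
        """t* = c((b-1)/(b+1))^(1/b) against dense numeric differentiation."""
        for a, d, c, b in [(0, 1, 10, 4), (0.1, 2.0, 8.0, 2.5), (0, 1, 15, 1.5)]:
            params = k.FourPLParams(a=a, d=d, c=c, b=b)
            grid = np.linspace(1e-3, 4 * c, 400_001)
            numeric = grid[np.argmax(k.fourpl_derivative(grid, a, d, c, b))]
            closed = k.fourpl_peak_time(params, (0.0, 4 * c))
            assert closed == pytest.approx(numeric, rel=1e-3)

    def test_self_consistency_fixed_point(self):
        t = np.linspace(0.5, 25, 40)
        y = k.fourpl(t, 0.1, 1.3, 9.0, 3.0) + np.random.default_rng(1).normal(0, 0.01, t.size)
        fit1 = k.fit_four_pl(t, y)
        fit2 = k.fit_four_pl(t, fit1.predict(t), fit_window=fit1.fit_window)
        for name in ("a", "d", "c", "b"):
            assert getattr(fit2.params, name) == pytest.approx(
                getattr(fit1.params, name), abs=1e-8, rel=1e-8
            )

    def test_noisy_replicates_recover_c(self):
        """2% multiplicative noise, 4 replicates: c within 10% (median of 50 seeds)."""
        t = np.linspace(0.5, 25, 30)
        truth = k.fourpl(t, 0.0, 1.0, 10.0, 4.0)
        errs = []
        for s in range(50):
            rng = np.random.default_rng(s)
            reps = truth * (1 + rng.normal(0, 0.02, (4, t.size)))
            fit = k.fit_four_pl(t, reps.mean(axis=0))
            errs.append(abs(fit.params.c - 10.0) / 10.0)
        assert np.median(errs) <= 0.10

    def test_constant_data_degenerate_flag(self):
        t = np.linspace(0, 10, 11)
        fit = k.fit_four_pl(t, np.full(11, 0.7))
        assert fit.degenerate and fit.max_slope == 0.0

    def test_default_window_excludes_decline(self):
        t = np.linspace(0, 30, 61)
        y = k.fourpl(t, 0, 1, 10, 4)
        y[t > 20] *= np.exp(-0.2 * (t[t > 20] - 20))  # substrate depletion
        fit = k.fit_four_pl(t, y)
        assert fit.fit_window[1] <= 20.5
        assert fit.params.c == pytest.approx(10.0, rel=0.05)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError, match=">= 5"):
            k.fit_four_pl([0, 1, 2, 3], [0, 0.1, 0.5, 1.0])


class TestPeakTimeVsInoculum:
    def test_inverse_relation_negative_rank(self):
        fits = {od: 20.0 / np.log10(100 * od) for od in [0.02, 0.1, 1.0, 5.0]}
        table, rho = k.peak_time_vs_inoculum(fits)
        assert rho == pytest.approx(-1.0)
        assert list(table["initial_od"]) == sorted(table["initial_od"])

    def test_single_condition_errors(self):
        with pytest.raises(ValueError):
            k.peak_time_vs_inoculum({0.2: 10.0})

    def test_identical_conditions_flagged_zero(self):
        with pytest.warns(UserWarning, match="identical"):
            _, rho = k.peak_time_vs_inoculum({0.1: 5.0, 1.0: 5.0})
        assert rho == 0.0
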