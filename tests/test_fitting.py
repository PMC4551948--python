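"""Rate extraction by exponential, global and linear fitting."""

import numpy as np
import pytest

from anisokin import (
    Protocol,
    RateSet,
    biexp_parameters,
    fit_double_exponential_global,
    fit_kobs_linear,
    fit_single_exponential,
    incubation_conversion,
    kcat_fixed_offrates,
    kcat_from_amplitude_series,
    rate_ratio,
    simulate_polarized_trace,
)
from anisokin.simulate import OpticalParams
from anisokin.pipeline import analyze_incubation_series, trace_to_curve
from anisokin.traces import AnisotropyCurve


def _curve(t, r, err=1e-4):
    return AnisotropyCurve(time_s=np.asarray(t, float), r=np.asarray(r, float),
                           r_err=np.full(len(t), err), bin_width=1.0)


def _noiseless_curve(rates, es0, ep0, duration, optics=None):
    optics = optics or OpticalParams(shot_noise=False)
    proto = Protocol.dissociation(duration=duration, initial_es=es0,
                                  initial_ep=ep0)
    return trace_to_curve(simulate_polarized_trace(proto, rates, optics, 0))


WT = RateSet(k_on_S=8.8e3, k_off_S=1.80e-3, k_cat=1.86e-3, k_off_P=8.6e-3,
             k_on_P=8.0e3)


class TestSingleExponential:
    def test_noiseless_recovery_exact(self):
        curve = _noiseless_curve(WT.with_(k_cat=0.0, k_off_S=8.6e-3), 1, 0, 1200.0)
        res = fit_single_exponential(curve)
        assert abs(res["k"] - 8.6e-3) < 1e-9

    def test_constant_curve_flagged_degenerate(self):
        t = np.arange(200.0)
        res = fit_single_exponential(_curve(t, np.full(200, 0.15)))
        assert "degenerate" in res.flags

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_single_exponential(_curve(np.arange(5.0), np.ones(5)))

    def test_rising_association_curve(self):
        # association is a rising exponential: amplitude negative, same rate
        t = np.arange(0.5, 400.0)
        k_obs = 0.012
        r = 0.25 - 0.2 * np.exp(-k_obs * t)
        res = fit_single_exponential(_curve(t, r))
        assert res["k"] == pytest.approx(k_obs, abs=1e-9)
        assert res["A"] < 0


class TestDoubleExponentialGlobal:
    def test_single_noiseless_curve_exact(self):
        d = biexp_parameters(WT, 0.8, 0.2)
        t = np.arange(0.5, 2500.0)
        r = 0.05 + 0.2 * d(t)
        res = fit_double_exponential_global(_curve(t, r))
        assert res["k1"] == pytest.approx(WT.k_off_P, abs=1e-8)
        assert res["k2"] == pytest.approx(WT.k_cat + WT.k_off_S, abs=1e-8)
        assert res.per_curve[0]["A1"] == pytest.approx(0.2 * d.A1, abs=1e-8)

    def test_shared_rates_beat_independent_fits_on_parameter_count(self):
        # five curves share rates but differ in amplitudes: the global fit
        # matches the summed residuals of per-curve fits with fewer params
        t = np.arange(0.5, 2000.0)
        curves = []
        for p in (0.0, 0.2, 0.4, 0.7, 1.0):
            d = biexp_parameters(WT, 1 - p, p)
            curves.append(_curve(t, 0.05 + 0.2 * d(t)))
        glob = fit_double_exponential_global(curves)
        indep = [fit_double_exponential_global([c]) for c in curves]
        n_glob = 2 + 2 * 5 + 1
        n_indep = 5 * (2 + 2 + 1)
        assert glob.rss <= sum(r.rss for r in indep) + 1e-10
        assert n_glob < n_indep

    def test_fixed_rates_recover_kcat_by_subtraction(self):
        # synthetic reactive curve; with both rates fixed the slow rate
        # equals k_cat + k_off_S, so k_cat falls out by subtraction
        p = incubation_conversion(WT.k_cat, 30.0)
        d = biexp_parameters(WT, 1 - p, p)
        t = np.arange(0.5, 2500.0)
        curve = _curve(t, 0.05 + 0.2 * d(t))
        res = fit_double_exponential_global(
            [curve], fixed={"k1": 8.6e-3, "k2": WT.k_cat + 1.80e-3})
        assert res.per_curve[0]["A2"] == pytest.approx(0.2 * d.A2, rel=1e-6)
        assert res.per_curve[0]["A1"] == pytest.approx(0.2 * d.A1, rel=1e-6)

    def test_fixed_rates_must_be_positive_distinct(self):
        c = _curve(np.arange(20.0), np.ones(20) * 0.1)
        with pytest.raises(ValueError, match="positive and distinct"):
            fit_double_exponential_global([c], fixed={"k1": 1e-3, "k2": 1e-3})

    def test_poorly_separated_rates_flagged(self):
        rates = WT.with_(k_cat=0.0, k_off_S=6e-3, k_off_P=8.6e-3)
        rng = np.random.default_rng(0)
        t = np.arange(0.5, 1500.0)
        d = biexp_parameters(rates, 0.5, 0.5)
        r = 0.05 + 0.2 * d(t) + rng.normal(0, 2e-3, t.size)
        res = fit_double_exponential_global(_curve(t, r, err=2e-3))
        assert "identifiability" in res.flags


class TestKcatFromAmplitudeSeries:
    @staticmethod
    def _series(k_cat, times, rates=None):
        rates = (rates or WT).with_(k_cat=k_cat)
        out = {}
        for ti in times:
            p = incubation_conversion(k_cat, ti)
            d = biexp_parameters(rates, 1 - p, p)
            out[ti] = (d.A1, d.A2)
        return out

    def test_slow_catalysis_recovery(self):
        times = [0.0, 1800.0, 3600.0, 7200.0, 12600.0, 18000.0]
        res = kcat_from_amplitude_series(self._series(0.17e-3, times))
        assert res["k_cat"] == pytest.approx(0.17e-3, rel=1e-7)

    def test_dead_enzyme_flagged_inactive(self):
        times = [0.0, 3600.0, 18000.0]
        res = kcat_from_amplitude_series(self._series(0.0, times))
        assert res["k_cat"] == 0.0
        assert "inactive" in res.flags

    def test_two_incubation_times_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            kcat_from_amplitude_series(self._series(1e-3, [0.0, 600.0]))


class TestKcatFixedOffrates:
    def test_noiseless_reactive_curve_recovery(self):
        p = incubation_conversion(WT.k_cat, 30.0)
        curve = _noiseless_curve(WT, 1 - p, p, 3000.0)
        res = kcat_fixed_offrates(curve, WT.k_off_S, WT.k_off_P)
        assert abs(res["k_cat"] - WT.k_cat) < 1e-9

    def test_dead_enzyme_reported_at_boundary(self):
        curve = _noiseless_curve(WT.with_(k_cat=0.0), 1.0, 0.0, 3000.0)
        res = kcat_fixed_offrates(curve, WT.k_off_S, WT.k_off_P)
        assert "boundary" in res.flags

    def test_invalid_offrate_order_rejected(self):
        curve = _noiseless_curve(WT, 1.0, 0.0, 500.0)
        with pytest.raises(ValueError):
            kcat_fixed_offrates(curve, 8.6e-3, 1.8e-3)

    def test_misspecified_product_offrate_detected_by_residuals(self):
        p = incubation_conversion(WT.k_cat, 30.0)
        curve = _noiseless_curve(WT, 1 - p, p, 3000.0)
        good = kcat_fixed_offrates(curve, WT.k_off_S, WT.k_off_P)
        bad = kcat_fixed_offrates(curve, WT.k_off_S, 2 * WT.k_off_P)
        assert bad.rss > 100 * max(good.rss, 1e-20)
        assert bad["k_cat"] != pytest.approx(WT.k_cat, rel=0.05)


class TestKobsLinear:
    def test_exact_points_on_a_line(self):
        k_on, k_off = 1.2e4, 2.3e-3
        kobs = {E: k_on * E + k_off for E in (0.10e-6, 0.25e-6, 0.50e-6, 0.75e-6)}
        res = fit_kobs_linear(kobs)
        assert res["k_on"] == pytest.approx(k_on, rel=1e-12)
        assert res["k_off"] == pytest.approx(k_off, rel=1e-12)

    def test_single_concentration_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_kobs_linear({1e-7: 1e-3})

    def test_negative_intercept_flagged_not_clamped(self):
        kobs = {1e-7: (0.5e-3, 1e-5), 5e-7: (4.5e-3, 1e-5), 1e-6: (9.5e-3, 1e-5)}
        res = fit_kobs_linear(kobs)
        assert res["k_off"] < 0
        assert "negative_intercept" in res.flags


class TestRateRatio:
    def test_printed_association_constants(self):
        ratio, err = rate_ratio((8.8, 1.6), (3.9, 0.2))
        assert ratio == pytest.approx(2.2564, abs=1e-4)
        assert ratio < 3.0

    def test_identity_and_exact_inputs(self):
        assert rate_ratio((2.0, 0.0), (2.0, 0.0)) == (1.0, 0.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            rate_ratio((1.0, 0.1), (0.0, 0.1))


class TestMethodAgreement:
    def test_amplitude_and_fixed_offrate_methods_agree(self):
        # the two k_cat strategies applied to the same synthetic ensemble
        # give estimates whose joint confidence intervals overlap
        from anisokin.simulate import simulate_incubation_series
        rates = WT.with_(k_cat=0.6e-3)
        optics = OpticalParams()
        times = [0.0, 900.0, 1800.0, 3600.0, 7200.0]
        traces = simulate_incubation_series(
            Protocol.reactive(0.0, duration=3000.0), rates, optics, times, 8)
        curves = {t: trace_to_curve(tr) for t, tr in zip(times, traces)}
        amp = analyze_incubation_series(curves)
        fixed = kcat_fixed_offrates(curves[900.0], rates.k_off_S, rates.k_off_P)
        lo_a, hi_a = amp.ci95("k_cat")
        lo_f, hi_f = fixed.ci95("k_cat")
        assert max(lo_a, lo_f) <= min(hi_a, hi_f)
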