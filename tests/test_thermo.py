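"""Arrhenius fitting, transition-state decomposition, and extrapolation."""

import math

import numpy as np
import pytest

from anisokin import (
    celsius_to_kelvin,
    eyring_decompose,
    extrapolate_rate,
    fit_arrhenius,
    fit_piecewise_arrhenius,
)
from anisokin.thermo import R_KCAL, round_sig


def _arrhenius_table(A, Ea, temps_c, noise=None, seed=0):
    rng = np.random.default_rng(seed)
    table = {}
    for tc in temps_c:
        T = celsius_to_kelvin(tc)
        k = A * math.exp(-Ea / (R_KCAL * T))
        if noise:
            k *= rng.lognormal(0.0, noise)
            table[T] = (k, noise * k)
        else:
            table[T] = k
    return table


class TestFitArrhenius:
    def test_exact_recovery(self):
        table = _arrhenius_table(5e12, 40.4, [15, 17.5, 20, 22])
        fit = fit_arrhenius(table, weighted=False)
        assert fit.Ea == pytest.approx(40.4, abs=1e-9)
        assert fit.A == pytest.approx(5e12, rel=1e-8)

    def test_two_temperatures_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_arrhenius(_arrhenius_table(1e12, 40.0, [15, 22]))

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            fit_arrhenius({288.15: 1e-3, 290.15: 0.0, 295.15: 2e-3})

    def test_noisy_recovery_unbiased_with_calibrated_errors(self):
        # 10% multiplicative noise over 15-22 degC: the refit Ea is unbiased
        # (median within 5%) and the reported standard error tracks the
        # across-replicate scatter
        fits = [fit_arrhenius(_arrhenius_table(5e12, 40.4, [15, 17.5, 20, 22],
                                               noise=0.10, seed=s))
                for s in range(100)]
        eas = np.array([f.Ea for f in fits])
        errs = np.array([f.Ea_err for f in fits])
        assert np.median(eas) == pytest.approx(40.4, rel=0.05)
        assert 0.7 < eas.std() / errs.mean() < 1.4


class TestEyring:
    def test_activation_enthalpy_arithmetic(self):
        fit = fit_arrhenius(_arrhenius_table(5e12, 40.4, [15, 17.5, 20, 22]),
                            weighted=False)
        ey = eyring_decompose(fit, 295.15)
        assert ey.dH_a == pytest.approx(40.4 - R_KCAL * 295.15, abs=1e-6)
        assert ey.dH_a == pytest.approx(39.81, abs=0.01)

    def test_round_trip_identity(self):
        fit = fit_arrhenius(_arrhenius_table(3.7e11, 38.2, [15, 18, 21, 24]),
                            weighted=False)
        for mol in ("uni", "bi"):
            ey = eyring_decompose(fit, 295.15, molecularity=mol)
            A_back, Ea_back = ey.reconstruct()
            assert Ea_back == pytest.approx(fit.Ea, abs=1e-10)
            assert A_back == pytest.approx(fit.A, rel=1e-10)

    def test_rate_ratio_maps_to_entropy_difference(self):
        # equal Ea, rate ratio 10.94 at 295.15 K: the whole difference is
        # entropic, ddS = R ln(ratio)
        ratio = 1.86e-3 / 0.17e-3
        f_fast = fit_arrhenius(_arrhenius_table(1e12 * ratio, 40.4, [15, 18, 22]),
                               weighted=False)
        f_slow = fit_arrhenius(_arrhenius_table(1e12, 40.4, [15, 18, 22]),
                               weighted=False)
        dds = (eyring_decompose(f_fast, 295.15).dS_a
               - eyring_decompose(f_slow, 295.15).dS_a)
        assert dds == pytest.approx(R_KCAL * math.log(ratio), abs=1e-12)
        assert dds == pytest.approx(4.75e-3, abs=2e-5)

    def test_rebuilt_rates_match_arrhenius_prediction(self):
        fit = fit_arrhenius(_arrhenius_table(5e12, 40.4, [15, 17.5, 20, 22]),
                            weighted=False)
        ey = eyring_decompose(fit, 295.15)
        A, Ea = ey.reconstruct()
        for T in np.linspace(288.15, 295.15, 7):
            k_tst = A * math.exp(-Ea / (R_KCAL * T))
            assert k_tst == pytest.approx(fit.predict(T), rel=1e-10)


class TestExtrapolation:
    def test_catalytic_rate_at_30C(self):
        k30 = extrapolate_rate(40.4, 1.86e-3, celsius_to_kelvin(22.0),
                               celsius_to_kelvin(30.0))
        assert k30 == 0.011  # two significant figures

    def test_identity_at_reference(self):
        assert extrapolate_rate(40.4, 1.86e-3, 295.15, 295.15,
                                round_sig=None) == pytest.approx(1.86e-3)

    def test_zero_barrier_is_temperature_independent(self):
        assert extrapolate_rate(0.0, 5e-3, 295.15, 330.0,
                                round_sig=None) == pytest.approx(5e-3)

    def test_monotone_increasing_in_temperature(self):
        ks = [extrapolate_rate(40.4, 1.86e-3, 295.15, T, round_sig=None)
              for T in np.linspace(280, 340, 13)]
        assert np.all(np.diff(ks) > 0)

    def test_invalid_temperature_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_rate(40.4, 1e-3, 295.15, -1.0)

    def test_round_sig(self):
        assert round_sig(0.011455) == 0.011
        assert round_sig(4.4721e4) == 45000


class TestPiecewiseArrhenius:
    @staticmethod
    def _two_regime_table(T_break=295.15, Ea_lo=40.0, Ea_hi=5.0,
                          temps_c=(10, 13, 16, 19, 22, 25, 28, 31, 34, 37),
                          noise=None, seed=0):
        rng = np.random.default_rng(seed)
        k_break = 1.86e-3
        table = {}
        for tc in temps_c:
            T = celsius_to_kelvin(tc)
            Ea = Ea_lo if T <= T_break else Ea_hi
            k = k_break * math.exp(-(Ea / R_KCAL) * (1 / T - 1 / T_break))
            if noise:
                k *= rng.lognormal(0, noise)
                table[T] = (k, noise * k)
            else:
                table[T] = k
        return table

    def test_breakpoint_recovered_within_grid_spacing(self):
        table = self._two_regime_table(noise=0.03)
        fit = fit_piecewise_arrhenius(table)
        assert abs(fit.breakpoint - 295.15) <= 3.0  # grid step is 3 degC
        lo, hi = fit.segments
        assert lo[1] == pytest.approx(40.0, abs=6.0)
        assert hi[1] == pytest.approx(5.0, abs=6.0)

    def test_single_regime_data_shows_no_spurious_break(self):
        table = self._two_regime_table(Ea_lo=40.0, Ea_hi=40.0, noise=0.05)
        fit = fit_piecewise_arrhenius(table)
        lo, hi = fit.segments
        # variance of the slope difference from the full joint covariance
        c = fit.seg_cov
        sd_diff = R_KCAL * math.sqrt(c[1, 1] + c[2, 2] - 2 * c[1, 2])
        assert abs(lo[1] - hi[1]) < 2.5 * sd_diff

    def test_breakpoint_at_boundary_rejected(self):
        table = self._two_regime_table()
        Tmax = max(table)
        with pytest.raises(ValueError, match="strictly inside"):
            fit_piecewise_arrhenius(table, breakpoint=Tmax)

    def test_too_few_points_for_free_break(self):
        table = self._two_regime_table(temps_c=(10, 16, 22, 28))
        with pytest.raises(ValueError, match="at least 5"):
            fit_piecewise_arrhenius(table)
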