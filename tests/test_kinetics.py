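"""Closed forms of the three-state scheme against first principles and the
brute-force ODE integrator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anisokin import (
    RateSet,
    SpeciesState,
    association_bound_fraction,
    biexp_parameters,
    dissociation_bound_fraction,
    incubation_conversion,
    ode_oracle,
)
from conftest import random_rate_sets


def _bound_via_oracle(rates, es0, ep0, t):
    s0 = SpeciesState(S=1.0 - es0 - ep0, ES=es0, EP=ep0, P=0.0)
    return np.array(
        [s.bound for s in ode_oracle(rates.with_(k_on_S=0.0, k_on_P=0.0), s0, 0.0, t)]
    )


class TestDissociationClosedForm:
    def test_single_exponential_half_life(self):
        rates = RateSet(k_on_S=0, k_off_S=1.80e-3, k_cat=0, k_off_P=1e-2, k_on_P=0)
        t_half = math.log(2) / 1.80e-3
        assert dissociation_bound_fraction(rates, 1.0, 0.0, t_half) == pytest.approx(0.5)

    @pytest.mark.parametrize("es0,ep0", [(1.0, 0.0), (0.3, 0.5), (0.0, 1.0)])
    def test_initial_condition(self, es0, ep0, wt_rates):
        assert dissociation_bound_fraction(wt_rates, es0, ep0, 0.0) == pytest.approx(
            es0 + ep0, abs=1e-14
        )

    def test_matches_ode_on_stated_grid(self):
        rates = RateSet(k_on_S=0, k_off_S=1.0e-3, k_cat=1.0e-3, k_off_P=8.0e-3, k_on_P=0)
        t = np.linspace(0.0, 2000.0, 41)
        closed = dissociation_bound_fraction(rates, 1.0, 0.0, t)
        oracle = _bound_via_oracle(rates, 1.0, 0.0, t)
        np.testing.assert_allclose(closed, oracle, rtol=1e-8)

    @pytest.mark.parametrize("rates", random_rate_sets(15, seed=11))
    def test_matches_ode_random_rates(self, rates):
        t = np.linspace(0.0, 3.0 / max(rates.k_off_P, rates.k_cat + rates.k_off_S), 25)
        closed = dissociation_bound_fraction(rates, 0.7, 0.2, t)
        oracle = _bound_via_oracle(rates, 0.7, 0.2, t)
        np.testing.assert_allclose(closed, oracle, rtol=1e-8, atol=1e-12)

    def test_degenerate_rates_no_blowup(self):
        # fast and slow rates coincide: the linear-in-t limiting form applies
        rates = RateSet(k_on_S=0, k_off_S=1e-3, k_cat=1e-3, k_off_P=2e-3, k_on_P=0)
        t = np.linspace(0.0, 2000.0, 21)
        vals = dissociation_bound_fraction(rates, 1.0, 0.0, t)
        assert np.all(np.isfinite(vals))
        np.testing.assert_allclose(vals, _bound_via_oracle(rates, 1.0, 0.0, t),
                                   rtol=1e-6)

    def test_monotone_decay_when_product_releases_faster(self):
        for rates in random_rate_sets(20, seed=3):
            if rates.k_off_P < rates.k_cat + rates.k_off_S:
                continue
            t = np.linspace(0.0, 5.0 / (rates.k_cat + rates.k_off_S), 200)
            vals = dissociation_bound_fraction(rates, 0.8, 0.1, t)
            assert np.all(np.diff(vals) <= 1e-15)

    @pytest.mark.parametrize(
        "bad", [dict(es0=-0.1, ep0=0.0), dict(es0=0.6, ep0=0.6),
                dict(es0=float("nan"), ep0=0.0)]
    )
    def test_invalid_fractions_rejected(self, bad, wt_rates):
        with pytest.raises(ValueError):
            dissociation_bound_fraction(wt_rates, bad["es0"], bad["ep0"], 10.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            RateSet(k_on_S=1e4, k_off_S=-1e-3, k_cat=0, k_off_P=1e-2, k_on_P=1e4)


class TestBiexpParameters:
    def test_worked_amplitudes(self):
        rates = RateSet(k_on_S=0, k_off_S=1e-3, k_cat=1e-3, k_off_P=8e-3, k_on_P=0)
        d = biexp_parameters(rates, 1.0, 0.0)
        assert d.k1 == pytest.approx(8e-3)
        assert d.k2 == pytest.approx(2e-3)
        assert d.A2 == pytest.approx(7.0 / 6.0)
        assert d.A1 == pytest.approx(-1.0 / 6.0)

    def test_no_conversion_decouples(self, wt_rates):
        d = biexp_parameters(wt_rates.with_(k_cat=0.0), 0.4, 0.5)
        assert (d.A1, d.A2) == pytest.approx((0.5, 0.4))

    @given(
        es0=st.floats(0, 1), ep0=st.floats(0, 1),
        k_off_S=st.floats(1e-4, 1e-2), k_cat=st.floats(0, 1e-2),
        k_off_P=st.floats(1e-4, 1e-1),
    )
    @settings(max_examples=60, deadline=None)
    def test_amplitude_sum_is_initial_bound(self, es0, ep0, k_off_S, k_cat, k_off_P):
        if es0 + ep0 > 1:
            es0, ep0 = es0 / 2, ep0 / 2
        rates = RateSet(k_on_S=0, k_off_S=k_off_S, k_cat=k_cat,
                        k_off_P=k_off_P, k_on_P=0)
        d = biexp_parameters(rates, es0, ep0)
        if d.degenerate:
            assert d.A2 == pytest.approx(es0 + ep0, abs=1e-9)  # value at t = 0
        else:
            assert d.A1 + d.A2 == pytest.approx(es0 + ep0, abs=1e-9)

    def test_amplitudes_affine_in_conversion(self, wt_rates):
        # at fixed es0 + ep0, both amplitudes are affine in ep0
        ps = np.linspace(0.0, 1.0, 7)
        a1 = np.array([biexp_parameters(wt_rates, 1 - p, p).A1 for p in ps])
        a2 = np.array([biexp_parameters(wt_rates, 1 - p, p).A2 for p in ps])
        for arr in (a1, a2):
            assert np.allclose(np.diff(arr, 2), 0.0, atol=1e-12)

    def test_degenerate_flagged_and_consistent(self):
        rates = RateSet(k_on_S=0, k_off_S=1e-3, k_cat=1e-3, k_off_P=2e-3, k_on_P=0)
        d = biexp_parameters(rates, 1.0, 0.0)
        assert d.degenerate
        t = np.linspace(0, 1500, 11)
        np.testing.assert_allclose(
            d(t), dissociation_bound_fraction(rates, 1.0, 0.0, t), rtol=1e-12
        )


class TestIncubationConversion:
    def test_wt_ten_minutes(self):
        assert incubation_conversion(1.86e-3, 600.0) == pytest.approx(0.672, abs=5e-4)

    def test_limits(self):
        assert incubation_conversion(1e-3, 0.0) == 0.0
        assert incubation_conversion(1e-3, 1e9) == pytest.approx(1.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            incubation_conversion(1e-3, -1.0)


class TestAssociation:
    def test_half_time(self):
        f = association_bound_fraction(1e4, 0.0, 6e-6, math.log(2) / 0.06)
        assert f == pytest.approx(0.5)

    def test_no_enzyme_no_binding(self):
        t = np.linspace(0, 1000, 11)
        assert np.all(association_bound_fraction(1e4, 1e-3, 0.0, t) == 0.0)

    def test_equilibrium_plateau(self):
        k_on, k_off, E = 1e4, 2e-3, 3e-7
        f_inf = association_bound_fraction(k_on, k_off, E, 1e9)
        assert f_inf == pytest.approx(k_on * E / (k_on * E + k_off))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            association_bound_fraction(1e4, 1e-3, -1e-9, 1.0)


class TestOdeOracle:
    def test_all_rates_zero_state_constant(self):
        rates = RateSet(k_on_S=0, k_off_S=0, k_cat=0, k_off_P=0, k_on_P=0)
        s0 = SpeciesState(S=0.2, ES=0.3, EP=0.4, P=0.1)
        for s in ode_oracle(rates, s0, 1e-9, np.linspace(0, 1000, 5)):
            assert s.as_array() == pytest.approx(s0.as_array(), abs=1e-10)

    def test_conservation_with_rebinding(self, wt_rates):
        s0 = SpeciesState(S=0.5, ES=0.25, EP=0.25, P=0.0)
        states = ode_oracle(wt_rates, s0, 1e-6, np.linspace(0, 2000, 9))
        for s in states:
            assert s.as_array().sum() == pytest.approx(1.0, abs=1e-9)

    def test_dilution_justifies_neglecting_rebinding(self, wt_rates):
        # at the 0.5 nM post-dilution concentration the rebinding flux is
        # k_on * E ~ 1e-5 1/s, far below the off-rates; the closed form and
        # the full scheme agree to better than 1%
        t = np.linspace(0.0, 2000.0, 21)
        closed = dissociation_bound_fraction(wt_rates, 1.0, 0.0, t)
        s0 = SpeciesState(S=0.0, ES=1.0, EP=0.0, P=0.0)
        full = np.array([s.bound for s in ode_oracle(wt_rates, s0, 1.5e-9, t)])
        assert np.max(np.abs(full - closed)) < 0.01
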