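"""Radiobiology chain: protraction factor, BED, LQ survival, Poisson TCP."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mammodose import analytic_dose as A
from mammodose import dvh_radiobio as RB
from mammodose import phantom as P


@pytest.fixture
def params():
    return RB.RadiobiologyParams()


class TestProtractionFactor:
    def test_reference_value(self):
        # n=10, mu=0.69/h, Tf=0.17 h
        assert RB.protraction_g(10, 0.69, 0.17) == pytest.approx(0.0962, abs=2e-4)

    def test_acute_fraction_limit(self):
        assert RB.protraction_g(10, 0.69, 1e-6 / 0.69) == pytest.approx(0.1, abs=1e-5)

    def test_single_acute_fraction(self):
        assert RB.protraction_g(1, 0.69, 1e-9) == pytest.approx(1.0, abs=1e-6)

    @given(st.floats(min_value=1e-4, max_value=0.2 / 0.69))
    @settings(max_examples=50, deadline=None)
    def test_series_expansion_agreement(self, tf):
        # |G - (1/n)(1 - mu*Tf/3)| < 1e-3 for mu*Tf < 0.2
        n, mu = 10, 0.69
        g = RB.protraction_g(n, mu, tf)
        assert abs(g - (1 / n) * (1 - mu * tf / 3)) < 1e-3

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            RB.protraction_g(0, 0.69, 0.17)
        with pytest.raises(ValueError):
            RB.protraction_g(10, -1.0, 0.17)


class TestBedAndSurvival:
    def test_bed_values(self, params):
        assert RB.bed(0.0, 0.0, params.g_factor, 10.0) == 0.0
        assert RB.bed(34.0, 3.4, params.g_factor, 10.0) == pytest.approx(35.11, abs=0.01)
        assert RB.bed(34.0, 3.4, 0.0, 10.0) == 34.0  # infinite-repair limit

    def test_bed_at_least_dose(self, params):
        d = np.linspace(0, 80, 30)
        assert np.all(RB.bed(d, d / 10, params.g_factor, 10.0) >= d)

    def test_bed_invalid(self, params):
        with pytest.raises(ValueError):
            RB.bed(34.0, 3.4, params.g_factor, 0.0)

    def test_survival_reference_value(self, params):
        # ln S = -10.534 + 0.231 -> S = 3.35e-5 at 34 Gy in 10 fractions
        assert RB.surviving_fraction(34.0, 3.4, params) == pytest.approx(3.35e-5, rel=0.01)

    def test_survival_untreated(self):
        p = RB.RadiobiologyParams(t_eff_days=0.0)
        assert RB.surviving_fraction(0.0, 0.0, p) == 1.0

    def test_survival_capped_at_one(self, params):
        # repopulation alone cannot push S above 1
        assert RB.surviving_fraction(0.0, 0.0, params) == 1.0

    def test_survival_monotone_in_dose(self, params):
        d = np.linspace(0.1, 80, 50)
        s = RB.surviving_fraction(d, 3.4, params)
        assert np.all(np.diff(s) < 0)

    def test_strict_sign_flag_lowers_survival(self, params):
        strict = RB.RadiobiologyParams(strict_repopulation_sign=True)
        assert RB.surviving_fraction(34.0, 3.4, strict) < RB.surviving_fraction(
            34.0, 3.4, params
        )

    def test_mu_consistent_with_half_time(self, params):
        assert params.mu_per_h == pytest.approx(0.69, rel=0.01)
        assert params.alpha_beta_gy == pytest.approx(10.0)


class TestApplyDrf:
    def test_identity_and_scaling(self):
        dvh = A.DVH(np.array([40.0, 50.0]), np.array([0.5, 0.5]))
        same = RB.apply_drf(dvh, 1.0)
        assert np.array_equal(same.dose_gy, dvh.dose_gy)
        scaled = RB.apply_drf(dvh, 0.95)
        assert scaled.dose_gy[0] == pytest.approx(38.0)
        assert scaled.total_volume == dvh.total_volume

    def test_invalid_drf(self):
        dvh = A.DVH(np.array([40.0]), np.array([1.0]))
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                RB.apply_drf(dvh, bad)


class TestTcp:
    def test_uniform_dvh_reference(self, params):
        dvh = A.DVH(np.array([34.0]), np.array([1.0]))
        res = RB.tcp_from_dvh(dvh, params)
        assert res.tcp == pytest.approx(0.9933, abs=5e-4)

    def test_single_bin_equals_closed_form(self, params):
        for dose in (20.0, 34.0, 50.0):
            dvh = A.DVH(np.array([dose]), np.array([1.0]))
            s = RB.surviving_fraction(dose, dose / params.n_fractions, params)
            expected = math.exp(-params.k_clonogens * s)
            assert RB.tcp_from_dvh(dvh, params).tcp == pytest.approx(expected, abs=1e-12)

    def test_untreated_limit(self, params):
        dvh = A.DVH(np.array([0.0]), np.array([1.0]))
        res = RB.tcp_from_dvh(dvh, params)
        assert res.mean_survival == 1.0
        assert res.tcp == pytest.approx(math.exp(-200.0), abs=1e-60)

    @given(st.integers(min_value=2, max_value=12))
    @settings(max_examples=20, deadline=None)
    def test_refinement_invariance(self, n_split):
        # splitting a bin into sub-bins at the same dose leaves TCP unchanged
        params = RB.RadiobiologyParams()
        dvh = A.DVH(np.array([30.0, 45.0]), np.array([0.4, 0.6]))
        split = A.DVH(
            np.concatenate([np.full(n_split, 30.0), [45.0]]),
            np.concatenate([np.full(n_split, 0.4 / n_split), [0.6]]),
        )
        a = RB.tcp_from_dvh(dvh, params).tcp
        b = RB.tcp_from_dvh(split, params).tcp
        assert a == pytest.approx(b, abs=1e-12)

    def test_monotone_under_dose_increase(self, params):
        lo = A.DVH(np.array([30.0, 40.0]), np.array([0.5, 0.5]))
        hi = A.DVH(np.array([32.0, 42.0]), np.array([0.5, 0.5]))
        assert RB.tcp_from_dvh(hi, params).tcp >= RB.tcp_from_dvh(lo, params).tcp

    def test_strictly_decreasing_in_clonogen_number(self):
        dvh = A.DVH(np.array([34.0]), np.array([1.0]))
        tcps = [
            RB.tcp_from_dvh(dvh, RB.RadiobiologyParams(k_clonogens=k)).tcp
            for k in (100.0, 200.0, 400.0)
        ]
        assert tcps[0] > tcps[1] > tcps[2]

    def test_tcp_in_unit_interval_consistent_with_survival(self, params, balloon_dvh):
        res = RB.tcp_from_dvh(balloon_dvh, params)
        assert 0.0 <= res.tcp <= 1.0
        assert res.tcp == pytest.approx(
            math.exp(-params.k_clonogens * res.mean_survival), abs=1e-12
        )

    def test_rejects_unnormalized_volumes(self, params):
        dvh = A.DVH(np.array([34.0]), np.array([0.7]))
        with pytest.raises(ValueError):
            RB.tcp_from_dvh(dvh, params)


@pytest.fixture
def balloon_dvh(water):
    return A.analytic_dvh(P.BalloonGeometry(4.0, water))


class TestParamsIO:
    def test_round_trip(self):
        p = RB.RadiobiologyParams(td_days=12.0, t_eff_days=4.0)
        back = RB.params_from_text(RB.params_to_text(p))
        assert back == p

    def test_validation(self):
        with pytest.raises(ValueError):
            RB.RadiobiologyParams(alpha_per_gy=-0.1)
        with pytest.raises(ValueError):
            RB.RadiobiologyParams(n_fractions=0)
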