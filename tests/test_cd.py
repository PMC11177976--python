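"""Coincidence-detector algebra: closed forms, Poisson oracle, properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chirpic import (
    ee_all_active,
    ee_exactly_l,
    ei_inhibit,
    inactive_term,
    shift,
    window_integral,
)
from chirpic.frontend import RateFunction


class TestWindowIntegral:
    def test_constant_rate_steady_state(self, const_rate):
        y = window_integral(const_rate(100.0), 1e-3)
        assert y[-1] == pytest.approx(0.1, rel=1e-6)

    def test_zero_rate(self, const_rate):
        assert np.all(window_integral(const_rate(0.0), 1e-3) == 0.0)

    def test_clamped_at_one(self, const_rate):
        y = window_integral(const_rate(2000.0), 1e-3)
        assert y[-1] == 1.0
        assert y.max() == 1.0

    def test_partial_sums_before_delta(self, const_rate):
        x = const_rate(100.0, fs=10_000.0)
        y = window_integral(x, 1e-3)  # 10 samples
        # at t < delta the accumulating partial sum is returned
        assert y[4] == pytest.approx(100.0 * 5 / 10_000.0, rel=1e-9)

    def test_subsample_window_rejected(self, const_rate):
        with pytest.raises(ValueError):
            window_integral(const_rate(10.0, fs=1000.0), 1e-4)


class TestShift:
    def test_whole_sample_delay_with_zero_fill(self, const_rate):
        x = const_rate(50.0, dur=0.01, fs=10_000.0)
        y = shift(x, 2e-3)
        assert np.all(y.lam[:20] == 0.0)
        assert np.all(y.lam[20:] == 50.0)
        assert y.n == x.n

    def test_negative_delay_rejected(self, const_rate):
        with pytest.raises(ValueError):
            shift(const_rate(1.0), -1e-3)


class TestClosedForms:
    def test_ee_two_constant_inputs(self, const_rate):
        # lambda_EE = 2 r (r delta) = 2*100*0.1 = 20 spikes/s
        out = ee_all_active([const_rate(100.0), const_rate(100.0)], 1e-3)
        assert out.lam[-1] == pytest.approx(20.0, rel=1e-2)

    def test_ee_annihilated_by_silent_input(self, const_rate):
        out = ee_all_active([const_rate(100.0), const_rate(0.0)], 1e-3)
        assert np.all(out.lam == 0.0)

    def test_exactly_l_equals_all_active_at_l_n(self, const_rate):
        inputs = [const_rate(80.0), const_rate(120.0), const_rate(60.0)]
        a = ee_exactly_l(inputs, 3, 1e-3)
        b = ee_all_active(inputs, 1e-3)
        assert np.allclose(a.lam, b.lam)

    def test_exactly_2_of_3_identical(self, const_rate):
        # 3 * [2 r (r delta)] * (1 - r delta) = 3*20*0.9 = 54 spikes/s
        inputs = [const_rate(100.0) for _ in range(3)]
        out = ee_exactly_l(inputs, 2, 1e-3)
        assert out.lam[-1] == pytest.approx(54.0, rel=1e-2)

    def test_inactive_term_cases(self, const_rate):
        assert np.all(inactive_term([], 1e-3) == 1.0)
        assert np.all(inactive_term([const_rate(0.0)], 1e-3) == 1.0)
        y = inactive_term([const_rate(100.0)], 1e-3)
        assert y[-1] == pytest.approx(0.9, rel=1e-6)

    def test_ei_survival_power(self, const_rate):
        # 100 * (1 - 0.1)^2 = 81
        out = ei_inhibit(const_rate(100.0), const_rate(100.0), 1e-3, m=2)
        assert out.lam[-1] == pytest.approx(81.0, rel=1e-3)

    def test_ei_identities(self, const_rate):
        exc = const_rate(100.0)
        assert np.array_equal(ei_inhibit(exc, const_rate(500.0), 1e-3, 0).lam, exc.lam)
        assert np.allclose(ei_inhibit(exc, const_rate(0.0), 1e-3, 5).lam, exc.lam)

    def test_l_out_of_range_rejected(self, const_rate):
        inputs = [const_rate(10.0), const_rate(10.0)]
        with pytest.raises(ValueError):
            ee_exactly_l(inputs, 1, 1e-3)
        with pytest.raises(ValueError):
            ee_exactly_l(inputs, 3, 1e-3)

    def test_mismatched_lengths_rejected(self, const_rate):
        with pytest.raises(ValueError):
            ee_all_active([const_rate(10.0, dur=0.1), const_rate(10.0, dur=0.2)], 1e-3)


def _poisson_spikes(rng, rate, n_bins, dt):
    return rng.random(n_bins) < rate * dt


def _recent(spikes, k):
    """True where the train has >= 1 spike in the trailing k bins (inclusive)."""
    c = np.cumsum(spikes)
    out = c.copy()
    out[k:] -= c[:-k]
    return out > 0


class TestPoissonOracle:
    """Coincidence rates vs direct simulation of Poisson spike trains.

    rΔ = 0.02 keeps the first-order window algebra within the Monte-Carlo
    error of true Poisson coincidence counting (the algebra deviates at
    O((rΔ)²): ∫λdt vs 1 - exp(-rΔ))."""

    DT = 2e-5
    T = 100.0
    DELTA = 0.5e-3
    RATE = 40.0

    def _trains(self, n):
        rng = np.random.default_rng(1234)
        n_bins = int(self.T / self.DT)
        return [_poisson_spikes(rng, self.RATE, n_bins, self.DT) for _ in range(n)]

    def test_ee_all_active_two_inputs(self, const_rate):
        a, b = self._trains(2)
        k = int(self.DELTA / self.DT)
        count = np.sum(a & _recent(b, k)) + np.sum(b & _recent(a, k))
        rate_mc = count / self.T
        se = np.sqrt(count) / self.T
        model = ee_all_active(
            [const_rate(self.RATE), const_rate(self.RATE)], self.DELTA
        ).lam[-1]
        assert abs(model - rate_mc) < 3 * se

    def test_ee_exactly_2_of_3(self, const_rate):
        trains = self._trains(3)
        k = int(self.DELTA / self.DT)
        recent = [_recent(t, k) for t in trains]
        count = 0
        for i, j, o in [(0, 1, 2), (0, 2, 1), (1, 2, 0)]:
            # one of the active pair fires now, the other fired recently,
            # and the third input was silent throughout the window
            count += np.sum(trains[i] & recent[j] & ~recent[o])
            count += np.sum(trains[j] & recent[i] & ~recent[o])
        rate_mc = count / self.T
        se = np.sqrt(count) / self.T
        model = ee_exactly_l(
            [const_rate(self.RATE) for _ in range(3)], 2, self.DELTA
        ).lam[-1]
        assert abs(model - rate_mc) < 3 * se


@st.composite
def rate_ensembles(draw):
    n_inputs = draw(st.integers(2, 4))
    n = 400
    rng = np.random.default_rng(draw(st.integers(0, 2**31 - 1)))
    rates = [
        RateFunction(rng.uniform(0, 300, n) * draw(st.floats(0.0, 1.0)), 20_000.0)
        for _ in range(n_inputs)
    ]
    return rates


class TestProperties:
    @settings(max_examples=25, deadline=None)
    @given(rate_ensembles())
    def test_permutation_symmetry_and_nonnegativity(self, inputs):
        out = ee_all_active(inputs, 1e-3)
        rev = ee_all_active(inputs[::-1], 1e-3)
        assert np.allclose(out.lam, rev.lam)
        assert np.all(out.lam >= 0)
        out2 = ee_exactly_l(inputs, len(inputs), 1e-3)
        assert np.allclose(out2.lam, out.lam)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 20), st.integers(0, 20), st.floats(0, 400), st.floats(0, 400))
    def test_ei_monotone_in_m_and_inhibition(self, m1, m2, r1, r2):
        def const(rate):
            return RateFunction(np.full(1000, rate), 20_000.0)

        exc = const(150.0)
        lo_m, hi_m = sorted((m1, m2))
        lo_r, hi_r = sorted((r1, r2))
        # pointwise non-increasing in the inhibitory rate (fixed m) ...
        a = ei_inhibit(exc, const(lo_r), 1e-3, hi_m)
        b = ei_inhibit(exc, const(hi_r), 1e-3, hi_m)
        assert np.all(b.lam <= a.lam + 1e-12)
        # ... and in m (fixed inhibitory rate)
        c = ei_inhibit(exc, const(hi_r), 1e-3, lo_m)
        assert np.all(b.lam <= c.lam + 1e-12)
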