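"""Masting-metric definitions against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mastgrad import metrics as m
from mastgrad.timeseries_io import SeedCropSeries


def naive_ar1(x):
    """Double-loop lag-1 autocorrelation, divisor-n autocovariance convention."""
    x = np.asarray(x, float)
    n = len(x)
    mean = sum(x) / n
    num = 0.0
    for t in range(n - 1):
        num += (x[t] - mean) * (x[t + 1] - mean)
    den = 0.0
    for t in range(n):
        den += (x[t] - mean) ** 2
    return num / den


def naive_cvp(x):
    x = np.asarray(x, float)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / (n - 1)
    return np.sqrt(var) / mean


def naive_mast_flags(x):
    x = np.asarray(x, float)
    mean = sum(x) / len(x)
    sd = np.sqrt(sum((v - mean) ** 2 for v in x) / (len(x) - 1))
    if sd == 0:
        return np.zeros(len(x), bool)
    d = (x - mean) / sd
    return d > abs(min(d))


class TestPointValues:
    @pytest.mark.parametrize("values,expected", [
        ([2, 2, 2, 2], 0.0),
        ([0, 4], 1.4142135623730951),
        ([1, 2, 3, 4, 5], 0.5270462766947299),
    ])
    def test_cvp_hand_values(self, values, expected):
        assert m.cvp(values) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("cv,expected", [
        (0.0, 0.0),
        (1.0, np.sqrt(0.5)),
        (3.0, 3.0 / np.sqrt(10.0)),
    ])
    def test_kcvp_closed_form(self, cv, expected):
        assert m.kcvp_from_cvp(cv) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("values,expected", [
        ([1, 0, 1, 0, 1, 0], -5.0 / 6.0),
        (list(range(1, 11)), 0.7),
    ])
    def test_ar1_hand_values(self, values, expected):
        assert m.ar1(values) == pytest.approx(expected, abs=1e-12)

    def test_mast_years_worked_fixture(self):
        x = [0, 0, 0, 10, 0, 0, 0, 10, 0, 0]
        flags = m.mast_years(x)
        assert list(np.where(flags)[0]) == [3, 7]
        assert m.psd(x) == pytest.approx(0.2)
        assert m.cvp(x) == pytest.approx(2.1081851067789197, abs=1e-10)

    def test_mast_years_tie_at_threshold_not_mast(self):
        # symmetric series: max deviate equals |min deviate|, strict rule fails
        assert not m.mast_years([1, 2, 3]).any()

    def test_constant_series_has_no_mast_years(self):
        assert not m.mast_years([3.0] * 8).any()
        assert m.psd([3.0] * 8) == 0.0


class TestErrorsAndMissing:
    def test_zero_mean_series_is_missing(self):
        with pytest.raises(ValueError, match="zero-mean"):
            m.cvp([0.0, 0.0, 0.0])

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            m.cvp([1.0])
        with pytest.raises(ValueError):
            m.ar1([1.0])
        with pytest.raises(ValueError):
            m.mast_years([1.0, 2.0])

    def test_constant_series_ar1_missing(self):
        with pytest.raises(ValueError, match="zero-variance"):
            m.ar1([5.0, 5.0, 5.0])

    def test_negative_kcvp_input_rejected(self):
        with pytest.raises(ValueError):
            m.kcvp_from_cvp(-0.1)

    def test_compute_all_flags_missing_on_constant_series(self):
        s = SeedCropSeries("const", "X", np.arange(2000, 2012), np.full(12, 4.0))
        res = m.compute_all(s)
        assert res.cvp == 0.0 and res.kcvp == 0.0 and res.psd == 0.0
        assert np.isnan(res.ar1)
        assert "ar1" in res.missing_reasons

    def test_compute_all_on_worked_fixture(self):
        s = SeedCropSeries("f", "X", np.arange(2000, 2010),
                           np.array([0, 0, 0, 10, 0, 0, 0, 10, 0, 0], float))
        res = m.compute_all(s)
        assert res.cvp == pytest.approx(2.1082, abs=1e-4)
        assert res.kcvp == pytest.approx(res.cvp / np.sqrt(1 + res.cvp**2), abs=1e-12)
        assert res.kcvp == pytest.approx(0.9035, abs=1e-4)
        assert res.psd == pytest.approx(0.2)
        assert res.n_years == 10


class TestOracleEquivalence:
    def test_matches_bruteforce_on_random_series(self):
        rng = np.random.default_rng(12345)
        for _ in range(300):
            n = int(rng.integers(3, 61))
            x = rng.lognormal(0.0, 0.8, n)
            assert m.ar1(x) == pytest.approx(naive_ar1(x), abs=1e-12)
            assert m.cvp(x) == pytest.approx(naive_cvp(x), abs=1e-12)
            assert np.array_equal(m.mast_years(x), naive_mast_flags(x))


class TestInvariances:
    @given(st.lists(st.floats(0.01, 1e4), min_size=4, max_size=40),
           st.floats(0.1, 50), st.floats(-100, 100))
    @settings(max_examples=60, deadline=None)
    def test_affine_invariance(self, values, a, b):
        x = np.asarray(values)
        if np.std(x, ddof=1) < 1e-9 * max(1.0, abs(np.mean(x))):
            return
        # skip knife-edge ties of the strict mast-year rule: a deviate exactly
        # at the threshold flips under floating-point rescaling
        d = (x - x.mean()) / x.std(ddof=1)
        if np.min(np.abs(np.abs(d) - np.abs(d.min()))[d > 0], initial=np.inf) < 1e-7:
            return
        ax = a * x + b
        assert m.ar1(ax) == pytest.approx(m.ar1(x), rel=1e-7, abs=1e-9)
        assert m.psd(ax) == pytest.approx(m.psd(x))
        if np.mean(a * x) > 1e-9:
            assert m.cvp(a * x) == pytest.approx(m.cvp(x), rel=1e-7)

    @given(st.floats(0.0, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_kcvp_round_trip(self, cv):
        k = m.kcvp_from_cvp(cv)
        assert 0 <= k < 1
        assert m.cvp_from_kcvp(k) == pytest.approx(cv, abs=1e-10)

    def test_kcvp_monotone(self):
        grid = np.linspace(0, 10, 200)
        k = [m.kcvp_from_cvp(c) for c in grid]
        assert np.all(np.diff(k) > 0)

    def test_deviates_sum_to_zero_and_threshold_nonnegative(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.lognormal(0, 1, int(rng.integers(3, 50)))
            d = (x - x.mean()) / x.std(ddof=1)
            assert abs(d.sum()) < 1e-9 * len(x)
            assert abs(d.min()) >= 0

    def test_extreme_year_raises_cvp_lowers_ar1(self):
        # near-constant drifting baseline: strongly positive lag-1 correlation
        base = 10 + 0.001 * np.arange(31, dtype=float)
        spiked = base.copy()
        spiked[15] = 100.0  # one bumper crop mid-series
        assert m.cvp(spiked) > m.cvp(base)
        assert m.ar1(spiked) < m.ar1(base)

    def test_psd_below_half_and_one(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            x = rng.lognormal(0, 1, int(rng.integers(3, 40)))
            assert m.psd(x) < 1.0


def test_gap_warning(recwarn):
    import warnings

    s = SeedCropSeries("g", "X", np.array([2000, 2001, 2005, 2006]),
                       np.array([1.0, 4.0, 2.0, 8.0]))
    with pytest.warns(UserWarning, match="gap"):
        m.compute_all(s)
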