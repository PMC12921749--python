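"""Normality screen, Mann-Whitney U (with exhaustive-enumeration oracle),
and the seasonal autocorrelation / Ljung-Box machinery."""

import itertools
import math

import numpy as np
import pytest

from epichannel import (
    DegenerateInputError,
    PeriodSpec,
    SyntheticConfig,
    ValidationError,
    compare_periods,
    mann_whitney,
    normality_test,
    seasonal_acf,
    simulate,
)
from conftest import make_series


# -- independent Mann-Whitney oracle ------------------------------------------


def oracle_mann_whitney(x, y):
    """Exact two-sided Mann-Whitney by full enumeration of arrangements.

    U counts pairs where an x exceeds a y (ties half).  The p-value is
    2 * P(U >= max(Ux, Uy)) under random relabelling, capped at 1.
    """
    def u_stat(a, b):
        return sum(
            1.0 if ai > bj else 0.5 if ai == bj else 0.0
            for ai in a for bj in b
        )

    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = max(u_stat(x, y), u_stat(y, x))
    total = ge = 0
    for positions in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in positions]
        b = [pooled[i] for i in range(len(pooled)) if i not in positions]
        total += 1
        # max(Ua, Ub) >= u_obs captures both tails at once
        if max(u_stat(a, b), u_stat(b, a)) >= u_obs - 1e-12:
            ge += 1
    return u_obs, ge / total, total


class TestMannWhitney:
    def test_three_vs_three_separated_matches_enumeration(self):
        """(1,2,3) vs (4,5,6): all 20 arrangements enumerated by the oracle."""
        u, p, total = oracle_mann_whitney([1, 2, 3], [4, 5, 6])
        assert total == 20
        got = mann_whitney([1, 2, 3], [4, 5, 6])
        assert got.statistic == pytest.approx(0.0)  # U of first sample
        assert max(got.statistic, 9 - got.statistic) == u
        assert got.p_value == pytest.approx(p)  # = 2/20

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 6)
                                       for n2 in range(n1, 6)])
    def test_matches_enumeration_all_small_sizes(self, n1, n2, rng):
        """Exact p agrees with full enumeration for every n1, n2 <= 5."""
        for _ in range(3):
            x = rng.permutation(np.arange(1, n1 + n2 + 1))[:n1].astype(float)
            y = np.setdiff1d(np.arange(1, n1 + n2 + 1), x).astype(float)
            u, p, total = oracle_mann_whitney(list(x), list(y))
            got = mann_whitney(x, y)
            assert total == math.comb(n1 + n2, n1)
            assert got.p_value == pytest.approx(p, abs=1e-12)

    def test_identical_samples_give_p_near_one(self):
        """(1..10) vs (1..10): fully tied, z = 0, p = 1."""
        got = mann_whitney(np.arange(1, 11), np.arange(1, 11))
        assert got.statistic == pytest.approx(50.0)  # n1*n2/2
        assert got.p_value == pytest.approx(1.0)

    def test_large_shift_strictly_decreases_p(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        p0 = mann_whitney(x, y).p_value
        p_shift = mann_whitney(x + 100.0, y).p_value
        assert p_shift < p0
        assert p_shift < 1e-6

    def test_ties_take_midrank_asymptotic_path(self):
        got = mann_whitney([1, 2, 2, 3], [2, 3, 3, 4])
        assert "asymptotic" in got.test_name
        assert 0 < got.p_value < 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1, 2])

    def test_compare_periods_uses_all_weekly_counts(self, full_series):
        res = compare_periods(full_series, PeriodSpec((2014, 2019), (2020, 2024)))
        assert (res.n1, res.n2) == (6 * 52, 5 * 52)
        # default scenario halves 2020 counts: difference is detectable
        assert res.p_value < 0.05


class TestNormality:
    def test_seasonal_counts_are_non_normal(self):
        series, _ = simulate(SyntheticConfig(seed=5))
        sample = series.data.to_numpy()[:200]
        res = normality_test(sample)
        assert res.p_value < 0.05

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            normality_test([1, 2])

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            normality_test([1, 1, 1, 1])


class TestSeasonalAcf:
    def test_pure_sinusoid_lag52(self):
        """Sample ACF of cos(2*pi*t/52) at lag 52 equals (n-52)/n exactly
        (the closed form for any exactly lag-52-periodic series)."""
        n = 572
        x = np.cos(2 * np.pi * np.arange(n) / 52)
        res = seasonal_acf(x)
        assert res.seasonal_lag_acf == pytest.approx((n - 52) / n, abs=1e-6)
        assert res.seasonality_p < 1e-10

    def test_periodic_block_peaks_at_seasonal_lag(self, rng):
        """A repeated 52-week random block has its ACF maximum at lag 52;
        the closed form (n-52)/n holds there too."""
        block = rng.normal(size=52)
        x = np.tile(block, 11)
        res = seasonal_acf(x)
        assert int(res.lags[np.argmax(res.acf_values)]) == 52
        assert res.seasonal_lag_acf == pytest.approx(520 / 572, abs=1e-9)

    def test_acf_values_bounded(self, full_series):
        res = seasonal_acf(full_series)
        assert np.all(np.abs(res.acf_values) <= 1.0)
        assert len(res.acf_values) == 52

    def test_iid_noise_rarely_flags_seasonality(self):
        """Ljung-Box at lag 52 keeps its nominal level on white noise."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            x = rng.negative_binomial(10, 10 / 110, size=572).astype(float)
            if seasonal_acf(x).seasonality_p > 0.05:
                hits += 1
        assert hits >= 90

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            seasonal_acf(np.arange(40.0))

    def test_constant_series_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            seasonal_acf(np.full(600, 7.0))

    def test_default_scenario_certifies_seasonality(self, full_series):
        assert seasonal_acf(full_series).seasonality_p < 1e-4
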