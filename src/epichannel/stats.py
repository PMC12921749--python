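"""Supporting statistics: normality screen, rank comparison, seasonal ACF.

Three routines back the surveillance analysis:

* Shapiro–Wilk normality screening of weekly counts (which motivates the
  rank-based comparison — seasonal count data are essentially never
  normal);
* a two-tailed Mann–Whitney U comparison of baseline-period versus
  comparison-period weekly counts, exact for small untied samples and a
  midrank / tie-corrected normal approximation otherwise;
* the sample autocorrelation function to the annual lag (52 weeks), with a
  Ljung–Box portmanteau p-value at that lag as the seasonality certificate
  and Bartlett bands for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.tsa.stattools import acf as sm_acf

from .errors import DegenerateInputError, ValidationError
from .io_calendar import PeriodSpec, WeeklySeries

ALPHA = 0.05  # two-tailed significance threshold reported alongside tests

# exact Mann-Whitney is used when the smaller sample is at most this large
# and there are no cross-sample ties; period samples (~312 vs ~260 weeks)
# always take the tie-corrected normal approximation
EXACT_MAX_N = 8


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n1: int
    n2: int | None = None
    two_tailed: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class AcfResult:
    """Sample ACF at lags 1..max_lag plus the lag-max portmanteau p-value."""

    lags: np.ndarray
    acf_values: np.ndarray
    seasonality_p: float
    ljung_box_stat: float
    bartlett_halfwidth: np.ndarray  # half-width of the 95% band per lag

    @property
    def seasonal_lag_acf(self) -> float:
        return float(self.acf_values[-1])


def normality_test(sample) -> TestResult:
    """Shapiro–Wilk W test of a sample of counts.

    Requires 3 <= n <= 5000 and a non-constant sample.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or not (3 <= len(x) <= 5000):
        raise ValidationError(f"Shapiro–Wilk needs 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant sample: normality test undefined")
    w, p = sps.shapiro(x)
    return TestResult("shapiro-wilk", float(w), float(p), n1=len(x))


def mann_whitney(x, y) -> TestResult:
    """Two-tailed Mann–Whitney U on two samples.

    The U statistic counts, over all pairs, how often an ``x`` value exceeds
    a ``y`` value (ties count one half).  The exact null distribution is
    used when the smaller sample has at most 8 values and the samples share
    no tied values; otherwise the midrank normal approximation with
    tie-corrected variance (no continuity correction, so the z statistic is
    the classical tie-corrected one).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return TestResult(
        f"mann-whitney-u ({method})",
        float(res.statistic),
        float(res.pvalue),
        n1=len(x),
        n2=len(y),
    )


def compare_periods(observed: WeeklySeries, spec: PeriodSpec) -> TestResult:
    """Mann–Whitney U between baseline-period and comparison-period counts."""
    base = observed.counts_for_years(spec.baseline_years)
    comp = observed.counts_for_years(spec.comparison_years)
    if base.empty or comp.empty:
        raise ValidationError("both periods must contain observations")
    return mann_whitney(base.to_numpy(), comp.to_numpy())


def seasonal_acf(observed: WeeklySeries | np.ndarray, max_lag: int = 52) -> AcfResult:
    """Sample ACF to the annual lag with a Ljung–Box seasonality p-value.

    Accepts a WeeklySeries (flattened in calendar order) or a plain 1-D
    array.  The series must be longer than ``max_lag + 1`` and non-constant.
    ``seasonality_p`` is the Ljung–Box p-value of the joint null that all
    autocorrelations up to ``max_lag`` vanish; a seasonal series rejects it
    overwhelmingly.
    """
    if isinstance(observed, WeeklySeries):
        x = observed.data.sort_index().to_numpy(dtype=float)
    else:
        x = np.asarray(observed, dtype=float)
    if len(x) <= max_lag + 1:
        raise ValidationError(
            f"series length {len(x)} too short for max_lag={max_lag}"
        )
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant series has undefined autocorrelation")
    values, confint, qstat, pvals = sm_acf(
        x, nlags=max_lag, qstat=True, alpha=ALPHA, fft=True
    )
    halfwidth = (confint[1:, 1] - confint[1:, 0]) / 2.0
    return AcfResult(
        lags=np.arange(1, max_lag + 1),
        acf_values=values[1:],
        seasonality_p=float(pvals[-1]),
        ljung_box_stat=float(qstat[-1]),
        bartlett_halfwidth=halfwidth,
    )
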