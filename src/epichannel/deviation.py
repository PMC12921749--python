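"""Excess / deficit of reported cases against an endemic channel.

For a single week the point estimate of the deviation is
``count - p50``; the channel yields bounds ``count - p75`` (lower) and
``count - p25`` (upper), so lower <= point <= upper always.  Annual and
period summaries are the same construction with sums: observed total minus
the sum of the channel medians (resp. p75, p25) over the weeks covered.
Because every quantity is linear in the counts, the period point estimate
equals the sum of its annual points, which equal the sums of the weekly
points.

Percent change between a baseline and a comparison period is computed from
the medians of all weekly counts pooled within each period:
``100 * (comparison_median - baseline_median) / baseline_median``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .channel import EndemicChannel
from .errors import UndefinedChangeError, ValidationError
from .io_calendar import PeriodSpec, WeeklySeries


@dataclass(frozen=True)
class DeviationSummary:
    """Excess (positive) or deficit (negative) with channel-derived bounds.

    ``point`` compares the observed total with the summed channel medians;
    ``lower``/``upper`` replace the medians with p75/p25.  ``n_weeks`` is
    the number of week-slots actually summed; ``partial`` flags that some
    expected weeks were missing from the observations.
    """

    scope: str  # "week" | "year" | "period"
    point: float
    lower: float
    upper: float
    observed_total: int
    expected_total: float
    n_weeks: int
    partial: bool = False

    def __post_init__(self) -> None:
        if not (self.lower <= self.point <= self.upper):
            raise ValidationError(
                f"deviation bounds out of order: {self.lower}, {self.point}, {self.upper}"
            )


@dataclass(frozen=True)
class PercentChange:
    """Percent change of the weekly median between two periods."""

    baseline_median: float
    comparison_median: float

    @property
    def change_pct(self) -> float:
        if self.baseline_median <= 0:
            raise UndefinedChangeError(
                "percent change undefined: baseline median is zero"
            )
        return 100.0 * (self.comparison_median - self.baseline_median) / self.baseline_median

    def rounded(self, ndigits: int = 1) -> float:
        """Change in percent, rounded the way report tables print it."""
        return round(self.change_pct, ndigits)


def weekly_deviation(
    observed: WeeklySeries, year: int, week: int, channel: EndemicChannel
) -> DeviationSummary:
    """Deviation of a single observed week from the channel."""
    try:
        count = int(observed.data.loc[(year, week)])
    except KeyError:
        raise ValidationError(
            f"{observed.disease_id}: no observation for year={year}, week={week}"
        ) from None
    p25, p50, p75 = channel.triple(week)
    return DeviationSummary(
        scope="week",
        point=count - p50,
        lower=count - p75,
        upper=count - p25,
        observed_total=count,
        expected_total=p50,
        n_weeks=1,
    )


def _summed_deviation(
    observed: WeeklySeries, years: Iterable[int], channel: EndemicChannel, scope: str
) -> DeviationSummary:
    obs_total = 0
    s25 = s50 = s75 = 0.0
    n_weeks = 0
    partial = False
    for year in years:
        if year not in observed.years:
            raise ValidationError(f"{observed.disease_id}: year {year} not in series")
        counts = observed.counts_for_year(year)
        counts = counts[counts.index <= 52]
        if len(counts) < 52:
            partial = True
        for week, count in counts.items():
            p25, p50, p75 = channel.triple(int(week))
            obs_total += int(count)
            s25 += p25
            s50 += p50
            s75 += p75
            n_weeks += 1
    return DeviationSummary(
        scope=scope,
        point=obs_total - s50,
        lower=obs_total - s75,
        upper=obs_total - s25,
        observed_total=obs_total,
        expected_total=s50,
        n_weeks=n_weeks,
        partial=partial,
    )


def annual_deviation(
    observed: WeeklySeries, year: int, channel: EndemicChannel
) -> DeviationSummary:
    """Excess/deficit of one observed year versus the channel medians.

    Missing weeks are skipped (the sum runs over available weeks) and the
    result carries ``partial=True``.
    """
    return _summed_deviation(observed, [year], channel, "year")


def period_deviation(
    observed: WeeklySeries, years: tuple[int, int], channel: EndemicChannel
) -> DeviationSummary:
    """Excess/deficit accumulated over an inclusive year range."""
    if years[1] < years[0]:
        raise ValidationError("period year range must be non-empty")
    return _summed_deviation(
        observed, range(years[0], years[1] + 1), channel, "period"
    )


def percent_change_from_medians(
    baseline_median: float, comparison_median: float
) -> PercentChange:
    """Percent change from two already-computed weekly medians.

    This is the arithmetic used for the printed period tables: feed it the
    weekly median of each period and read off ``change_pct``.
    """
    pc = PercentChange(float(baseline_median), float(comparison_median))
    pc.change_pct  # force the zero-baseline check eagerly
    return pc


def percent_change(observed: WeeklySeries, spec: PeriodSpec) -> PercentChange:
    """Percent change of the pooled weekly median between the two periods.

    Medians pool *all* weekly counts within each period (not medians of
    annual medians), matching how period tables label "weekly median cases".
    """
    base = observed.counts_for_years(spec.baseline_years)
    comp = observed.counts_for_years(spec.comparison_years)
    if base.empty or comp.empty:
        raise ValidationError("both periods must contain observations")
    return percent_change_from_medians(
        float(np.median(base.to_numpy())), float(np.median(comp.to_numpy()))
    )


# -- report tables -------------------------------------------------------------


def annual_deviation_table(
    series_by_disease: dict[str, WeeklySeries],
    channels: dict[str, EndemicChannel],
    years: Iterable[int],
) -> pd.DataFrame:
    """One row per disease; per year the point estimate and channel bounds.

    Mirrors the annual excess/deficit table layout: point with
    (lower to upper) bounds, counts rounded to integers.
    """
    years = list(years)
    rows = []
    for disease, series in series_by_disease.items():
        row: dict[str, object] = {"disease": disease}
        for year in years:
            d = annual_deviation(series, year, channels[disease])
            row[f"point_{year}"] = round(d.point)
            row[f"lower_{year}"] = round(d.lower)
            row[f"upper_{year}"] = round(d.upper)
        rows.append(row)
    return pd.DataFrame(rows)


def period_summary_table(
    series_by_disease: dict[str, WeeklySeries],
    channels: dict[str, EndemicChannel],
    spec: PeriodSpec,
) -> pd.DataFrame:
    """Period summary: medians of both periods, total excess/deficit with
    bounds, and the percent change — one row per disease."""
    rows = []
    for disease, series in series_by_disease.items():
        base = series.counts_for_years(spec.baseline_years)
        comp = series.counts_for_years(spec.comparison_years)
        dev = period_deviation(series, spec.comparison, channels[disease])
        pc = percent_change(series, spec)
        rows.append(
            {
                "disease": disease,
                "baseline_median": float(np.median(base.to_numpy())),
                "comparison_median": float(np.median(comp.to_numpy())),
                "total_point": round(dev.point),
                "total_lower": round(dev.lower),
                "total_upper": round(dev.upper),
                "change_pct": pc.rounded(1),
            }
        )
    return pd.DataFrame(rows)
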