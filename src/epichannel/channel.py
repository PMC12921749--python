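"""Endemic-channel construction and zone classification.

The endemic channel summarizes the expected behaviour of a disease: for
each epidemiological week, the 25th, 50th and 75th percentiles of the
counts observed at that same week across the baseline years.  An observed
week is then placed in one of four zones by comparing its count with the
three percentiles:

====================  =======================
count < p25           success
p25 <= count <= p50   safety
p50 < count <= p75    alert
count > p75           epidemic
====================  =======================

Boundary ties use the left-closed convention above: a count exactly equal
to a percentile takes the lower-activity label.  With only a handful of
baseline years the percentile interpolation rule materially changes the
channel, so it is explicit and configurable (``linear`` — the common
spreadsheet/statistics default — ``nearest`` or ``midpoint``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import IncompleteBaselineError, ValidationError
from .io_calendar import WeeklySeries

PercentileMethod = Literal["linear", "nearest", "midpoint"]
PERCENTILE_METHODS: tuple[str, ...] = ("linear", "nearest", "midpoint")

ZONES = ("success", "safety", "alert", "epidemic")


@dataclass
class EndemicChannel:
    """Per-week (p25, p50, p75) triples over a baseline year range.

    ``per_week`` is a 52-row DataFrame indexed by week with columns
    ``p25, p50, p75``; the ordering invariant p25 <= p50 <= p75 is checked
    on construction.
    """

    per_week: pd.DataFrame
    baseline_years: tuple[int, int]
    n_baseline: int
    method: str = "linear"

    def __post_init__(self) -> None:
        pw = self.per_week
        if list(pw.columns) != ["p25", "p50", "p75"]:
            raise ValidationError("channel frame must have columns p25, p50, p75")
        if len(pw) != 52 or list(pw.index) != list(range(1, 53)):
            raise ValidationError("channel must cover weeks 1..52 exactly")
        if (pw < 0).any().any():
            raise ValidationError("channel percentiles must be non-negative")
        if not ((pw["p25"] <= pw["p50"]) & (pw["p50"] <= pw["p75"])).all():
            raise ValidationError("percentile ordering p25 <= p50 <= p75 violated")

    def triple(self, week: int) -> tuple[float, float, float]:
        row = self.per_week.loc[week]
        return float(row["p25"]), float(row["p50"]), float(row["p75"])

    def to_csv(self, path: str | Path) -> None:
        self.per_week.rename_axis("week").to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, baseline_years: tuple[int, int],
                 n_baseline: int, method: str = "linear") -> "EndemicChannel":
        pw = pd.read_csv(path, index_col="week")
        return cls(pw, baseline_years, n_baseline, method)


@dataclass
class ZoneSeries:
    """Zone label of every observed week of one year against a channel."""

    year: int
    labels: pd.Series  # index: week, values in ZONES
    missing_weeks: list[int] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        """Number of weeks per zone."""
        vc = self.labels.value_counts()
        return {z: int(vc.get(z, 0)) for z in ZONES}


def build_channel(
    series: WeeklySeries,
    baseline: tuple[int, int],
    method: PercentileMethod = "linear",
) -> EndemicChannel:
    """Build the per-week percentile channel from the baseline years.

    Every week 1..52 must be observed in at least two baseline years;
    otherwise the week and the years missing it are named in the error.
    """
    if method not in PERCENTILE_METHODS:
        raise ValidationError(
            f"unknown percentile method {method!r}; choose from {PERCENTILE_METHODS}"
        )
    years = list(range(baseline[0], baseline[1] + 1))
    absent = [y for y in years if y not in series.years]
    if absent:
        raise IncompleteBaselineError(
            f"{series.disease_id}: baseline years {absent} not present in series"
        )
    base = series.counts_for_years(years)
    rows = {}
    for week in range(1, 53):
        idx = base.index.get_level_values("week") == week
        obs = base[idx]
        if len(obs) < 2:
            have = set(obs.index.get_level_values("year"))
            raise IncompleteBaselineError(
                f"{series.disease_id}: week {week} observed in only {len(obs)} "
                f"baseline year(s); missing {sorted(set(years) - have)}"
            )
        rows[week] = np.percentile(obs.to_numpy(), [25, 50, 75], method=method)
    per_week = pd.DataFrame.from_dict(rows, orient="index", columns=["p25", "p50", "p75"])
    return EndemicChannel(
        per_week=per_week,
        baseline_years=baseline,
        n_baseline=len(years),
        method=method,
    )


def classify_week(count: float, p25: float, p50: float, p75: float) -> str:
    """Zone of a single count (left-closed boundary convention)."""
    if count < p25:
        return "success"
    if count <= p50:
        return "safety"
    if count <= p75:
        return "alert"
    return "epidemic"


def classify_zones(observed: WeeklySeries, year: int, channel: EndemicChannel) -> ZoneSeries:
    """Label every observed week of ``year`` against the channel.

    Weeks absent from the observed year get no label and are listed in
    ``missing_weeks``.
    """
    if year not in observed.years:
        raise ValidationError(f"{observed.disease_id}: year {year} not in series")
    counts = observed.counts_for_year(year)
    counts = counts[counts.index <= 52]
    labels = pd.Series(
        [classify_week(float(c), *channel.triple(int(w))) for w, c in counts.items()],
        index=counts.index,
        dtype="object",
        name="zone",
    )
    missing = sorted(set(range(1, 53)) - set(counts.index))
    return ZoneSeries(year=year, labels=labels, missing_weeks=missing)
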