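"""Weekly surveillance series I/O and epidemiological-week normalization.

Surveillance bulletins report counts by epidemiological week (1–52, with an
occasional week 53 in long years).  Everything downstream of this module —
channel construction, deviation sums, the rank tests — assumes exactly 52
weeks per year, so :func:`normalize_weeks` is the single place where week-53
policy is applied.  Missing weeks are kept *absent* and flagged in metadata,
never imputed as zero: a zero is a report of no cases, a gap is no report.

The on-disk format is a long CSV with columns ``disease, year, week, count``
(UTF-8, header required), one row per disease-week.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .errors import DiseaseNotFoundError, FormatError, ValidationError

CSV_COLUMNS = ("disease", "year", "week", "count")

Week53Policy = Literal["merge", "drop"]


@dataclass
class WeeklySeries:
    """One disease's weekly counts indexed by (year, epidemiological week).

    Parameters
    ----------
    disease_id
        Short label for the disease, as it appears in the CSV.
    data
        Integer counts with a two-level index ``(year, week)``, sorted.
    metadata
        Diagnostics accumulated by processing steps: ``missing_weeks`` maps
        a year to the week numbers absent from it, ``incomplete_years``
        lists years with fewer than 52 weeks after normalization.
    """

    disease_id: str
    data: pd.Series
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = self.data
        if not isinstance(s.index, pd.MultiIndex) or s.index.nlevels != 2:
            s = s.copy()
            s.index = pd.MultiIndex.from_tuples(list(s.index), names=["year", "week"])
        s = s.sort_index()
        s.index = s.index.set_names(["year", "week"])
        if s.index.has_duplicates:
            dup = s.index[s.index.duplicated()][0]
            raise ValidationError(
                f"{self.disease_id}: duplicate entry for year={dup[0]}, week={dup[1]}"
            )
        weeks = s.index.get_level_values("week")
        bad = (weeks < 1) | (weeks > 53)
        if bad.any():
            y, w = s.index[bad][0]
            raise ValidationError(f"{self.disease_id}: week {w} of {y} outside 1..53")
        if (s < 0).any():
            y, w = s.index[s < 0][0]
            raise ValidationError(
                f"{self.disease_id}: negative count {s.loc[(y, w)]} at year={y}, week={w}"
            )
        years = s.index.get_level_values("year").unique()
        if len(years) > 1 and set(years) != set(range(years.min(), years.max() + 1)):
            missing = sorted(set(range(years.min(), years.max() + 1)) - set(years))
            raise ValidationError(
                f"{self.disease_id}: years not contiguous, missing {missing}"
            )
        self.data = s.astype("int64")

    # -- convenience accessors -------------------------------------------------

    @property
    def years(self) -> list[int]:
        return sorted(self.data.index.get_level_values("year").unique())

    def __len__(self) -> int:
        return len(self.data)

    def counts_for_year(self, year: int) -> pd.Series:
        """Counts of one year indexed by week; raises KeyError if absent."""
        out = self.data.xs(year, level="year")
        return out

    def counts_for_years(self, years: Iterable[int]) -> pd.Series:
        ys = set(years)
        mask = self.data.index.get_level_values("year").isin(ys)
        return self.data[mask]

    def to_frame(self) -> pd.DataFrame:
        df = self.data.rename("count").reset_index()
        df.insert(0, "disease", self.disease_id)
        return df


@dataclass(frozen=True)
class PeriodSpec:
    """Two disjoint inclusive year ranges: a baseline and a comparison period.

    The canonical use is baseline 2014–2019 (pre-pandemic) against
    comparison 2020–2024 (pandemic).
    """

    baseline: tuple[int, int]
    comparison: tuple[int, int]

    def __post_init__(self) -> None:
        b0, b1 = self.baseline
        c0, c1 = self.comparison
        if b1 < b0 or c1 < c0:
            raise ValidationError("period ranges must be non-empty (start <= end)")
        if b1 >= c0:
            raise ValidationError(
                f"baseline {self.baseline} must precede and not overlap "
                f"comparison {self.comparison}"
            )

    @property
    def baseline_years(self) -> list[int]:
        return list(range(self.baseline[0], self.baseline[1] + 1))

    @property
    def comparison_years(self) -> list[int]:
        return list(range(self.comparison[0], self.comparison[1] + 1))


def _frame_to_series(df: pd.DataFrame, disease_id: str) -> WeeklySeries:
    sub = df[df["disease"] == disease_id]
    if sub.empty:
        raise DiseaseNotFoundError(
            f"disease {disease_id!r} not present; found "
            f"{sorted(df['disease'].unique())}"
        )
    data = pd.Series(
        sub["count"].to_numpy(),
        index=pd.MultiIndex.from_arrays(
            [sub["year"].to_numpy(), sub["week"].to_numpy()], names=["year", "week"]
        ),
    )
    return WeeklySeries(disease_id=disease_id, data=data)


def read_weekly_csv(path: str | Path, disease_id: str) -> WeeklySeries:
    """Read one disease's weekly counts from a long-format surveillance CSV.

    Raises
    ------
    FormatError
        If a required column is missing.
    ValidationError
        If a count is negative or not an integer (the offending row is named).
    DiseaseNotFoundError
        If ``disease_id`` has no rows.
    """
    df = pd.read_csv(path, dtype={"disease": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; need {list(CSV_COLUMNS)}")
    for col in ("year", "week", "count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            row = int(df.index[bad][0]) + 2  # 1-based, plus header line
            raise ValidationError(
                f"{path}: non-integer {col} {df[col][bad].iloc[0]!r} at line {row}"
            )
        df[col] = vals.astype("int64")
    if (df["count"] < 0).any():
        row = int(df.index[df["count"] < 0][0]) + 2
        raise ValidationError(f"{path}: negative count at line {row}")
    return _frame_to_series(df, disease_id)


def list_diseases(path: str | Path) -> list[str]:
    """Disease labels present in a surveillance CSV, sorted."""
    df = pd.read_csv(path, usecols=["disease"], dtype=str)
    return sorted(df["disease"].unique())


def write_weekly_csv(series: WeeklySeries | Iterable[WeeklySeries], path: str | Path) -> None:
    """Write one or several series back to the long CSV schema."""
    if isinstance(series, WeeklySeries):
        series = [series]
    frames = [s.to_frame() for s in series]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def normalize_weeks(raw: WeeklySeries, policy: Week53Policy = "merge") -> WeeklySeries:
    """Collapse epidemiological week 53 and flag incomplete years.

    ``merge`` (default) adds any week-53 count into week 52 of the same
    year, conserving the annual total; ``drop`` discards it.  Years that end
    up with fewer than 52 weeks are recorded in
    ``metadata["missing_weeks"]`` / ``metadata["incomplete_years"]`` — they
    are *not* zero-filled.
    """
    if policy not in ("merge", "drop"):
        raise ValidationError(f"unknown week-53 policy {policy!r}")
    s = raw.data
    weeks = s.index.get_level_values("week")
    w53 = s[weeks == 53]
    body = s[weeks <= 52]
    if not w53.empty and policy == "merge":
        add = pd.Series(
            w53.to_numpy(),
            index=pd.MultiIndex.from_arrays(
                [w53.index.get_level_values("year"), [52] * len(w53)],
                names=["year", "week"],
            ),
        )
        body = body.add(add, fill_value=0).astype("int64")

    missing: dict[int, list[int]] = {}
    for year in sorted(body.index.get_level_values("year").unique()):
        have = set(body.xs(year, level="year").index)
        gap = sorted(set(range(1, 53)) - have)
        if gap:
            missing[int(year)] = gap
    meta = dict(raw.metadata)
    meta["week53_policy"] = policy
    if missing:
        meta["missing_weeks"] = missing
        meta["incomplete_years"] = sorted(missing)
    return WeeklySeries(disease_id=raw.disease_id, data=body, metadata=meta)
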