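#!/usr/bin/env python
"""Quantify annual and period excess/deficit against the endemic channels.

Produces the two report tables: per-year point estimates with channel
bounds (observed minus summed p50, bounded by p75/p25 sums), and the
period summary with pooled weekly medians and percent change.
"""

from pathlib import Path

from epichannel import (
    PeriodSpec,
    annual_deviation_table,
    build_channel,
    list_diseases,
    normalize_weeks,
    period_summary_table,
    read_weekly_csv,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SPEC = PeriodSpec((2014, 2019), (2020, 2024))


def main() -> None:
    csv = RESULTS / "synthetic_weekly.csv"
    series_by_disease, channels = {}, {}
    for disease in list_diseases(csv):
        s = normalize_weeks(read_weekly_csv(csv, disease))
        series_by_disease[disease] = s
        channels[disease] = build_channel(s, SPEC.baseline)

    annual = annual_deviation_table(series_by_disease, channels, SPEC.comparison_years)
    annual.to_csv(RESULTS / "deviation_annual.csv", index=False)
    period = period_summary_table(series_by_disease, channels, SPEC)
    period.to_csv(RESULTS / "deviation_period.csv", index=False)

    print(period.to_string(index=False))
    for _, row in period.iterrows():
        direction = "deficit" if row["total_point"] < 0 else "excess"
        print(
            f"{row['disease']}: weekly median {row['baseline_median']:.0f} -> "
            f"{row['comparison_median']:.0f} ({row['change_pct']:+.1f}%), "
            f"total {direction} {row['total_point']:+.0f} "
            f"({row['total_lower']:.0f} to {row['total_upper']:.0f})"
        )


if __name__ == "__main__":
    main()
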