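#!/usr/bin/env python
"""Build the 2014-2019 endemic channel of each disease and classify the
2020-2024 weeks into success / safety / alert / epidemic zones.

Reads results/synthetic_weekly.csv (from 01), writes one channel CSV per
disease, the pooled zone labels, and channel-vs-observed figures.
"""

from pathlib import Path

import pandas as pd

from epichannel import (
    build_channel,
    classify_zones,
    list_diseases,
    normalize_weeks,
    read_weekly_csv,
)
from epichannel.plotting import plot_channel_years

RESULTS = Path(__file__).resolve().parents[1] / "results"
BASELINE = (2014, 2019)
COMPARISON_YEARS = range(2020, 2025)


def main() -> None:
    csv = RESULTS / "synthetic_weekly.csv"
    (RESULTS / "channels").mkdir(exist_ok=True, parents=True)
    (RESULTS / "figures").mkdir(exist_ok=True)
    zone_rows = []
    for disease in list_diseases(csv):
        series = normalize_weeks(read_weekly_csv(csv, disease))
        channel = build_channel(series, BASELINE)
        channel.to_csv(RESULTS / "channels" / f"channel_{disease}.csv")
        plot_channel_years(
            series, channel, COMPARISON_YEARS,
            RESULTS / "figures" / f"channel_{disease}.png",
        )
        summary = []
        for year in COMPARISON_YEARS:
            zs = classify_zones(series, year, channel)
            for week, zone in zs.labels.items():
                zone_rows.append(
                    {"disease": disease, "year": year, "week": week, "zone": zone}
                )
            c = zs.counts()
            summary.append(f"{year}: {c['success']}/{c['safety']}/{c['alert']}/{c['epidemic']}")
        print(f"{disease} weeks per zone (success/safety/alert/epidemic) — "
              + "; ".join(summary))
    pd.DataFrame(zone_rows).to_csv(RESULTS / "zones.csv", index=False)
    print(f"wrote {RESULTS / 'zones.csv'} and per-disease channels/figures")


if __name__ == "__main__":
    main()
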