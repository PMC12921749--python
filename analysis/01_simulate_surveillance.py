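#!/usr/bin/env python
"""Generate the synthetic surveillance panel used by the downstream steps.

Three generic disease archetypes mimic the regimes seen in national
weekly-bulletin data, each with a known mean surface and an imposed
pandemic-period disruption starting in 2020:

* winter_virus      - strong winter seasonality, deep two-year collapse
                      (rotavirus-like reporting breakdown);
* steady_bacterium  - no seasonality, slow upward trend, reporting excess
                      through the whole 2020-2024 period (TB-like);
* vaccine_preventable - moderate seasonality, sustained 75% reduction over
                      2020-2024 (chickenpox-like suppression).

Writes results/synthetic_weekly.csv (the CSV contract consumed by every
later step), the true weekly means, and the generator configs.
"""

from pathlib import Path

from epichannel import SyntheticConfig, simulate, write_weekly_csv

RESULTS = Path(__file__).resolve().parents[1] / "results"

CONFIGS = [
    SyntheticConfig(
        disease_id="winter_virus", base_rate=120.0, seasonal_amplitude=0.9,
        peak_week=4, dispersion=12.0, disruption_start=(2020, 10),
        disruption_end=(2021, 52), disruption_multiplier=0.3, seed=101,
    ),
    SyntheticConfig(
        disease_id="steady_bacterium", base_rate=280.0, seasonal_amplitude=0.05,
        peak_week=20, trend=0.02, dispersion=30.0, disruption_start=(2020, 10),
        disruption_end=(2024, 52), disruption_multiplier=1.3, seed=102,
    ),
    SyntheticConfig(
        disease_id="vaccine_preventable", base_rate=900.0, seasonal_amplitude=0.5,
        peak_week=8, dispersion=15.0, disruption_start=(2020, 10),
        disruption_end=(2024, 52), disruption_multiplier=0.25, seed=103,
    ),
]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "configs").mkdir(exist_ok=True)
    panel, truths = [], []
    for cfg in CONFIGS:
        series, truth = simulate(cfg)
        panel.append(series)
        cfg.to_yaml(RESULTS / "configs" / f"{cfg.disease_id}.yaml")
        dis_years = (cfg.disruption_start[0], cfg.disruption_end[0])
        truths.append(
            {
                "disease": cfg.disease_id,
                "disruption_years": f"{dis_years[0]}-{dis_years[1]}",
                "disruption_multiplier": cfg.disruption_multiplier,
                "true_period_deviation": round(
                    truth.true_period_deficit(dis_years), 1
                ),
                "true_2020_2024_deviation": round(
                    truth.true_period_deficit((2020, 2024)), 1
                ),
            }
        )
        print(
            f"{cfg.disease_id}: {len(series)} weeks, "
            f"true {dis_years[0]}-{dis_years[1]} deviation "
            f"{truth.true_period_deficit(dis_years):+.0f} cases"
        )
    write_weekly_csv(panel, RESULTS / "synthetic_weekly.csv")

    import pandas as pd

    pd.DataFrame(truths).to_csv(RESULTS / "ground_truth_summary.csv", index=False)
    print(f"wrote {RESULTS / 'synthetic_weekly.csv'}")


if __name__ == "__main__":
    main()
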