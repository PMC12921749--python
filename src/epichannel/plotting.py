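"""Channel-versus-observed figures.

One panel per comparison year: the observed weekly curve drawn over the
shaded channel bands (success below p25, safety to p50, alert to p75,
epidemic above).  Layout mirrors the usual endemic-channel presentation;
cosmetic details are deliberately minimal.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .channel import EndemicChannel
from .io_calendar import WeeklySeries


def plot_channel_years(
    series: WeeklySeries,
    channel: EndemicChannel,
    years: Iterable[int],
    path: str | Path,
) -> Path:
    """Save a one-column figure of observed weekly counts over the channel."""
    years = list(years)
    fig, axes = plt.subplots(
        len(years), 1, figsize=(8, 2.2 * len(years)), sharex=True, squeeze=False
    )
    weeks = channel.per_week.index
    for ax, year in zip(axes[:, 0], years):
        ax.fill_between(weeks, 0, channel.per_week["p25"], alpha=0.25,
                        color="tab:green", label="success")
        ax.fill_between(weeks, channel.per_week["p25"], channel.per_week["p50"],
                        alpha=0.25, color="tab:olive", label="safety")
        ax.fill_between(weeks, channel.per_week["p50"], channel.per_week["p75"],
                        alpha=0.25, color="tab:orange", label="alert")
        obs = series.counts_for_year(year)
        obs = obs[obs.index <= 52]
        ax.plot(obs.index, obs.to_numpy(), color="black", lw=1.2, label="observed")
        ax.set_ylabel(f"{year}\ncases")
        ax.set_xlim(1, 52)
    axes[0, 0].legend(ncol=4, fontsize=8, loc="upper right")
    axes[-1, 0].set_xlabel("epidemiological week")
    fig.suptitle(
        f"{series.disease_id}: weekly cases vs endemic channel "
        f"({channel.baseline_years[0]}–{channel.baseline_years[1]})"
    )
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
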