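# epichannel

Endemic-channel analysis of weekly notifiable-disease surveillance counts:
per-week percentile channels from a baseline period, outbreak-zone
classification, excess/deficit quantification with channel-derived bounds,
period percent changes, and the supporting statistics (Shapiro–Wilk,
Mann–Whitney U, lag-52 autocorrelation with Ljung–Box).

## Who this is for

Epidemiologists and public-health analysts who have weekly case counts by
epidemiological week — e.g. transcribed from national surveillance
bulletins — and want to ask: *was disease activity in a given week, year or
multi-year period above or below its historical norm, and by how many
cases?* The motivating use case is quantifying how the 2020–2024 pandemic
period disrupted reporting of endemic and vaccine-preventable diseases
relative to a 2014–2019 baseline.

## The method

For a baseline of years *B* (default 2014–2019), the **endemic channel** of
a disease is, for each epidemiological week *w* ∈ 1..52, the triple

> (P25ʷ, P50ʷ, P75ʷ) — the 25th/50th/75th percentiles of {countʸ٫ʷ : y ∈ B}.

An observed week is classified into a **zone** by its position in the
channel: below P25 → *success*, in [P25, P50] → *safety*, in (P50, P75] →
*alert*, above P75 → *epidemic* (ties take the lower-activity zone).

The **excess or deficit** of cases over any scope (week, year, period) is

> point = Σ observed − Σ P50,  with bounds  lower = Σ observed − Σ P75 and
> upper = Σ observed − Σ P25,

so lower ≤ point ≤ upper always, and period values are exactly the sum of
their weekly values. The **percent change** between two periods is
100 × (m₂ − m₁)/m₁ where mᵢ is the median of all weekly counts pooled
within period *i*. Period differences are tested with a two-tailed
Mann–Whitney U (exact for small untied samples, midrank/tie-corrected
normal approximation otherwise); seasonality is certified by the sample
ACF to lag 52 with a Ljung–Box portmanteau p-value at the annual lag.

A negative-binomial generator with a single annual harmonic, optional
trend, and a multiplicative "pandemic" disruption over a contiguous week
block provides simulated series with known ground truth for validating the
whole pipeline (see `docs/methods.md`).

## Worked example

```sh
epichannel simulate --out weekly.csv --seed 5
epichannel analyze --input weekly.csv --baseline 2014:2019 \
    --period 2020:2024 --outdir out --plots
```

`analyze` writes the channel CSV (`week,p25,p50,p75`), zone labels, the
annual and period deviation tables, a stats summary, figures, and a
`run_log.json` recording every policy choice. The same computations are
available as a library; the default simulated scenario (a strongly
seasonal disease whose reporting halves during 2020) gives:

```python
>>> from epichannel import *
>>> series, truth = simulate(SyntheticConfig())
>>> ch = build_channel(series, (2014, 2019))
>>> d = annual_deviation(series, 2020, ch)
>>> round(d.point), round(d.lower), round(d.upper)
(-2712, -3875, -1714)
>>> percent_change(series, PeriodSpec((2014, 2019), (2020, 2024))).rounded(1)
-15.3
>>> seasonal_acf(series).seasonality_p < 1e-4
True
```

Reading: in 2020 the disease reported ~2,712 fewer cases than the channel
median expected; even against the most conservative bound (P75) the
deficit is at least 1,714 cases. Pooled weekly medians fell 15.3% between
the periods (the disruption covers one of five comparison years), and the
lag-52 Ljung–Box test overwhelmingly rejects non-seasonality.

The numbered scripts under `analysis/` run the full narrative on a
three-disease synthetic panel (a collapsing winter virus, a steadily
increasing bacterium, a suppressed vaccine-preventable disease) and write
their tables under `results/`.

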