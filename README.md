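# phenovis

Offline analytics for digital-phenotyping relapse monitoring in psychiatry.

Smartphone platforms used in schizophrenia research collect **active data**
(short daily surveys: mood, sleep, social, anxiety, psychosis sections on
ordinal scales) and **passive data** (GPS pings). Clinicians reviewing such
data retrospectively want to know: *did this patient's behavior become
anomalous in the month before a logged relapse?* phenovis turns the raw
tables into the derivatives that answer this, as a plain Python library and
CLI — no server, no live platform connection.

## What it computes

- **Imputation** — survey adherence is never complete. Missing responses are
  filled per patient on the full daily grid either by *LOCF* (last
  observation carried forward) or by *MICE* (chained equations: each
  question regressed on the others in its section, iterated, results
  rounded to legal ordinal levels).
- **Per-section MCA trends** — each section's completed responses form a
  dates × (question, level) indicator matrix `Z`. Correspondence analysis of
  `Z` (standardized residuals `S = D_r^{-1/2}(P − rc^T)D_c^{-1/2}`, thin SVD,
  principal inertias `λ_k = σ_k²`, row principal coordinates
  `D_r^{-1/2}UΣ`) yields a daily score on the first component — the
  section's trend — plus **eigengaps** on the inertia proportions
  (`p₁ − p₂`, `p₂ − p₃`): a large first eigengap means responses are
  dominated by one consistent dimension.
- **Date-clustering coassociation** — every date becomes an *aggregate
  vector* (per-section means, length 5) or a *complete vector* (all
  responses concatenated). An ensemble of clusterings (k-means and Ward at
  several k, plus silhouette-selected "natural" clustering, restarted with
  derived seeds) condenses into a **coassociation matrix**: entry (i, j) is
  the fraction of partitions placing dates i and j in the same cluster.
  A pre-relapse month shows up as a high-coassociation block.
- **Passive features** — dwell-weighted k-means over locally projected GPS
  pings gives ranked **significant locations** (home = top dwell); per day,
  dwell fractions across locations and the **home-time percentage**.
- **Window statistics** — trend mean/SD inside the 30-day pre-relapse
  window vs an earliest-clean-month control window; a section is flagged
  when `sd(relapse) / sd(control) ≥ 2`.
- **Reports** — a static two-panel comparative HTML report (trend lines,
  eigengap bars, coassociation heatmaps, home-time calendars, dwell pie
  calendars) embedding the exact numbers and parameters used.
- **Synthetic cohorts** — a generator plants both relapse signatures
  (response-SD inflation, elevated home time) in fully deterministic
  multi-patient datasets, so the entire pipeline is testable offline.

## Worked example

```python
import pandas as pd
import phenovis as pv

# one synthetic patient: 120 days, relapse on day 90
cfg = pv.SynthConfig(n_patients=1, span_days=120, relapse_spec={0: [90]}, seed=7)
survey, gps, annotation = pv.generate_patient(cfg, 0)

complete = pv.impute(survey, pv.ImputationConfig(method="mice", seed=7))
trends = {s: pv.mca_trend(pv.fit_section(complete, cfg.schema, s))
          for s in cfg.schema.sections}

span = (complete.df["date"].min(), complete.df["date"].max())
windows = pv.define_windows(annotation, span)
summary = pv.flag_anomalous_windows(pv.summarize_windows(trends, windows))
print(summary[["section", "window", "n", "mean", "sd", "flagged"]]
      .round(2).to_string(index=False))

locations = pv.find_significant_locations(gps, pv.PassiveConfig(seed=7))
daily = pv.daily_summaries(gps, locations, pv.PassiveConfig(seed=7))
r = annotation.relapse_dates[0]
pre = (daily.index >= r - pd.Timedelta(days=30)) & (daily.index < r)
print(f"home time: control {daily.home_time_pct[~pre].mean():.1f}% vs "
      f"pre-relapse {daily.home_time_pct[pre].mean():.1f}%")
```

prints

```
  section    window  n  mean   sd  flagged
     mood   control 30 -0.23 0.60    False
     mood relapse-1 30  0.74 1.09    False
    sleep   control 30 -0.20 0.44    False
    sleep relapse-1 30  0.63 1.20     True
   social   control 30 -0.04 0.82    False
   social relapse-1 30  0.61 1.17    False
  anxiety   control 30 -0.32 0.38    False
  anxiety relapse-1 30  0.93 1.17     True
psychosis   control 30 -0.38 0.46    False
psychosis relapse-1 30  0.85 0.97     True
home time: control 59.9% vs pre-relapse 86.3%
```

Every section's trend SD rises in the pre-relapse month (three of five by
more than the 2× flagging ratio under this seed), and mean home time jumps
from ~60% to ~86% — the two planted signatures, recovered by the two
independent data streams.

The same run from the shell:

```bash
phenovis simulate --out data/ --n-patients 24 --seed 0
phenovis run --data data/ --out results/ --seed 0
# single stages: phenovis impute / mca / cluster / passive / windows / report
```

`run` writes per-patient CSVs (trends, eigengaps, coassociation matrices,
daily location summaries, window summaries), a two-panel HTML report per
patient, a cohort index page, and a run manifest with every seed and
parameter; repeating with the same seed reproduces all CSVs byte for byte.

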