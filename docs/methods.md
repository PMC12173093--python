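# Methods

This note documents the statistical procedures phenovis implements, the
defaults it ships, and what the synthetic validation does and does not
establish.

## Data model

Active data are long-format ordinal survey responses keyed by
(patient, date, section, question). A schema declares five sections —
mood, sleep, social, anxiety, psychosis — with an ordered question list per
section and the legal integer levels per question (defaults: 5/4/3/5/4
questions, levels 0–3). Passive data are GPS pings (patient, timestamp,
latitude, longitude). Relapse annotations are clinically logged dates.
Dates are calendar days in the patient's local time; GPS timestamps are
bucketed to local days, matching the clinical reading of "home time per
day". Duplicate survey rows (mobile resubmissions) keep the last
occurrence, with a logged warning.

## Imputation

Both methods operate per patient on the full calendar-day grid from the
first to the last observed survey date, so sparse reporting still yields a
daily series.

**LOCF** fills each missing cell of a question's daily series with the most
recent earlier observation. Cells before the first observation follow the
`leading_missing_policy`: `backfill_first` (default) copies the first
observed value backwards; `drop_date` leaves those days absent. A question
with zero observations for a patient is an error — there is nothing to
carry.

**MICE** completes each patient-section dates × questions matrix by chained
equations: missing cells start at the column mode, then each question in
turn is regressed on the others (linear model on the integer-coded levels
via scikit-learn's iterative imputer) and its missing cells replaced by
predictions, for `mice_iterations` sweeps (default 10). Final fills are
snapped to the nearest legal level; observed cells are never altered; the
procedure is deterministic given the seed. The pipeline consumes a single
completed table, so `mice_chains` defaults to 1; with more chains,
posterior-sampling chains are averaged and re-rounded. Columns with fewer
than two observations fall back to a mode fill with a warning. Imputation
is per section (the questions of a section are the variable set), matching
the per-section MCA downstream; this is an interpretation the data layout
makes natural, not a constraint of the method.

A practical caveat established during validation: on ~20%-missing data,
LOCF's carried-forward runs make window SDs of the downstream MCA trend
heavy-tailed, which roughly doubles the false-positive rate of the
SD-ratio relapse screen relative to MICE. The SD screen should therefore be
read on MICE-imputed trends; the package's validation does so.

## Per-section MCA

Each section's completed responses are one-hot coded into an indicator
matrix `Z` (rows = dates, columns = (question, level) pairs in schema
order; each row sums to the question count Q; never-used levels keep their
all-zero column). The analysis is standard correspondence analysis of `Z`:

- correspondence matrix `P = Z / N` with `N = n·Q`,
- margins `r = P·1`, `c = Pᵀ·1`; zero-mass columns are excluded (they carry
  no inertia),
- standardized residuals `S = D_r^{-1/2} (P − r cᵀ) D_c^{-1/2}` — the
  rank-one subtraction removes the trivial constant dimension,
- thin SVD `S = U Σ Vᵀ`; principal inertias `λ_k = σ_k²` sorted
  non-increasing; row principal coordinates `F = D_r^{-1/2} U Σ`,
- retained components: `min(n, J_effective) − 1`.

The **trend** is the first column of `F`, indexed by date. SVD sign
indeterminacy is fixed so each component's scores correlate non-negatively
with the dates' mean raw response (exact ties: leading loading positive),
making trends reproducible run to run. When all dates answered identically
the total inertia is zero; the fit returns all-zero eigenvalues and scores
with a `degenerate` flag rather than failing.

**Eigengaps** are computed on inertia *proportions* `p_k = λ_k / Σλ`
(`first = p₁ − p₂`, `second = p₂ − p₃`, zero-padded below three
components), so the consistency diagnostic is scale-free across sections
with different question counts. No Benzécri/Greenacre correction is applied
by default. Tests verify the eigenstructure against an independent
eigendecomposition of `S Sᵀ` at 1e-8 on hundreds of random designs; the
per-component score comparison is restricted to simple eigenvalues, since
repeated eigenvalues only determine an eigenspace, not its basis.

## Date vectors, ensembles, coassociation

Per date, the **aggregate vector** (AV) holds the five per-section mean
responses; the **complete vector** (CV) concatenates all responses in
schema order. Vectors are used unstandardized — all components share the
ordinal scale — with an optional z-score mode, and Euclidean distance
throughout.

The default ensemble per vector kind is k-means and Ward agglomerative at
k ∈ {2, 3, 4} plus "natural" clustering (k = argmax of mean silhouette over
k ∈ [2, 6] with a k-means base; silhouette ties break toward the smallest
k), each restarted 5 times with seeds derived deterministically from the
master seed — 35 partitions. The **coassociation matrix** entry (i, j) is
the fraction of partitions placing dates i and j together: symmetric, unit
diagonal, entries exact multiples of 1/E. No consensus partition is
extracted; the matrix itself is the deliverable, rendered as a heatmap with
a marker one month before each relapse.

## Passive features

Pings are projected to planar meters by an equirectangular projection about
the patient's median coordinate (adequate at city scale). Each ping carries
a dwell weight equal to the gap to the next ping, capped at 60 minutes so
recording outages cannot dominate; the last ping's unobserved dwell is
imputed with the median capped gap, which makes uniformly sampled traces
weight every ping equally (and makes dwell fractions invariant to uniform
changes of ping rate). Dwell-weighted k-means with
k = min(`max_locations`=6, occupied ~200 m grid cells) clusters the pings;
clusters whose centroids fall within one radius (200 m) of each other are
fused — plain k-means otherwise over-splits a single dwell cloud — and
clusters holding <1% of total dwell are dropped. Locations are ranked by
total dwell; **home** is rank 1, exact ties broken by earliest first visit.

Daily summaries assign each ping to its nearest significant location within
the radius (else "other") and report per-local-day dwell fractions (summing
to 1 on days with pings), the home-time percentage, and a ping count; days
without pings appear explicitly and render as blank calendar cells. "Home
time" as dwell fraction at the top-ranked location is an operational
definition chosen here; no published operationalization is reproduced.

## Windows and flagging

For each relapse date r the relapse window is `[r − 30 d, r)`, clipped to
the study span and to earlier relapse windows so windows never overlap
("month" is fixed at 30 days for determinism; a different length is a
policy knob). The control window is the earliest 30-day stretch free of any
relapse window, also overridable. Per section × window the trend's n,
arithmetic mean and sample SD (ddof = 1; SD 0 for single-value windows) are
tabulated. A section is flagged anomalous for a relapse window when
`sd(relapse) / max(sd(control), 1e-6) ≥ ratio_threshold` (default 2.0 —
an artifact default chosen to operationalize "remarkably higher", not an
estimated quantity).

## Synthetic generator

The generator is the package's study condition, not a tuning surface. Per
day, section and question, a latent Gaussian is drawn with the section's
baseline mean (defaults 1.0–1.8 across sections) and SD 0.5; questions
within a section share a daily factor with correlation 0.6 — this is what
makes cross-question regression informative for MICE and gives MCA a
dominant component. Inside each 30-day pre-relapse window the latent SD is
multiplied by 3.0 and the mean shifted by +0.5 (erratic, elevated
responding). Values snap to the nearest legal level; responses are deleted
MCAR with probability 0.2. GPS traces emit 48 pings/day; each ping is at
the home coordinate with probability 0.6 (0.85 inside pre-relapse windows)
else at one of 3 fixed "other" locations 0.5–3 km away, with 30 m Gaussian
jitter. Survey, GPS and relapse draws use independent seed streams per
(seed, patient), so cohorts are byte-reproducible. The default cohort is 24
patients over 180 days.

What this emulates: ordinal scales, realistic missingness, within-section
correlation, and the two relapse signatures (response-SD inflation,
elevated home time) as step changes confined to a 30-day window. What it
does not: MNAR/adherence-driven missingness, gradual prodromes, weekly or
seasonal rhythms, travel, measurement drift, or any attempt to match real
clinical distributions. Passing the recovery tests therefore shows the
pipeline detects the planted effect sizes under clean assumptions — not
that it would perform identically on clinical data.

## Numerical and validation choices

- Validation problem sizes: oracle checks use ≥200 random indicator
  matrices (≤10 dates × ≤12 columns) at 1e-8; signature-recovery rates use
  100 single-relapse patients over 120 days (surveys) and 75 days (GPS),
  with MICE at 5 sweeps for the survey screen; the end-to-end determinism
  check runs the full 24-patient cohort twice and compares CSVs byte for
  byte.
- Matrices are written to CSV at 12 significant digits and round-trip
  within 1e-9; NaNs require an explicit allow-missing flag.
- Zero-inertia MCA, all-identical clustering inputs, empty GPS days, and
  truncated windows all have defined degenerate behaviors (flagged results,
  single-cluster partitions, blank cells, reduced n) rather than errors.
- Per-patient failures in a cohort run are logged and skipped; the run
  fails only if every patient fails.

## Limitations

The significant-location step is a deliberately simple k-means surrogate,
not a re-implementation of published GPS-statistics methods; trajectory
segmentation, time-of-day priors and multi-day dwell modeling are out of
scope. The anomaly screen is retrospective and univariate per section;
no prospective or multivariate relapse prediction is attempted. MICE uses
linear conditional models on integer-coded levels — proportional-odds
models would respect the ordinal scale more faithfully at higher cost.
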