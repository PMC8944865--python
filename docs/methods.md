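# Methods

This note documents the models, conventions and parameter choices behind
`sleepscape`, and what its synthetic-data tests do and do not establish.

## Epoch model and time conventions

All scoring happens on a uniform epoch grid (default 30 s, the PSG scoring
convention) with the three-letter alphabet sleep/wake/missing.  Timestamps
are naive local time; no DST handling is attempted.  Analysis days run noon
to noon, half-open `[noon, noon)`, so a night's sleep is never split across
day boundaries; the synthetic generator likewise starts and ends cohorts at
noon.

## Synthetic cohorts

The generator is structural, not dynamical: each night's onset and duration
are drawn directly from an archetype (onset mean and jitter, duration mean
and SD, a per-day onset drift of `period − 24` h, optional weekend shift),
then midawake bouts (Poisson count; short bouts clipped below 60 min, long
bouts forced ≥ 60 min with probability `long_midawake_prob`) and afternoon
naps are carved in.  This choice makes the ground truth exactly the list of
planted intervals — recomputable from the emitted series by run-length
inspection — at the cost of not modelling homeostatic/circadian interaction
(the van der Pol model is reserved for *fitting*, keeping the test loop
honest).  Per-subject seeds derive from (master seed, archetype name,
within-archetype index), so cohorts are reproducible and invariant to the
order archetypes are listed in.

Acceleration traces are gravity baseline plus Gaussian noise with
state-dependent SD — defaults 15 mg asleep, 60 mg awake at 20 Hz — plus
Poisson-arriving 1–10 s movement bursts (extra 250 mg SD) during wake, so
wake carries a broadband jerk signature beyond variance alone.  Nonwear
spans collapse to ~1 mg noise, safely below the 13 mg detection threshold.
The sleep SD sits deliberately above that threshold so genuine sleep is not
mistaken for nonwear.  These choices mimic the *contrast* wrist devices
show between states, not any particular device's noise floor; classifier
scores on this data demonstrate the pipeline operates in the intended
performance regime (sensitivity ≥ 95%, specificity ≥ 80%), not that any
real-world accuracy is achieved.  Real recordings add artifacts the
generator omits: posture changes during sleep, quiet wakefulness, device
calibration error, temperature drift.

The pseudo-corruption generator flips state over runs of 1..`max_flip_run`
epochs started independently per epoch with probability `flip_rate`
(overlaps unioned before inversion).  It exists to evaluate the bout-repair
threshold: corruption strictly shorter than the smoothing threshold is
provably removable, and the sweep utility measures sensitivity/specificity
per candidate threshold.

## Sleep/wake scoring

Jerk is the first difference of acceleration times the sampling rate.  Per
epoch and axis the rectangular-window periodogram is integrated into 8
log-spaced bands from 0.1 Hz to Nyquist (sub-0.1 Hz bins fold into band 1;
DC is excluded, so band powers sum to the epoch's mean-square jerk by
Parseval).  The classifier is an XGBoost tree ensemble, depth 4, 200 trees,
learning rate 0.1, single-threaded hist method for determinism; the reported
training objective is accuracy + F measure (sleep positive) on a stratified
25% held-out split.  Bayesian hyperparameter search is out of scope; the
fixed values can be overridden per call.

Bout smoothing applies two passes in a fixed, documented order: first every
maximal wake run strictly shorter than 10 min flanked by sleep (or by one
series boundary plus sleep) flips to sleep, then the symmetric sleep pass.
Missing epochs break runs and never flip.  The order matters only in
pathological alternating inputs; it is fixed so results are reproducible.

## Windows and indexes

Sleep windows merge maximal sleep runs whenever the intervening gap is
≤ 60 min (inclusive) *and* contains no missing epochs — missing data breaks
windows, which keeps the conservation law ST + WT = window length exact.
Windows longer than 3.75 h (strict) are long, the rest short; windows belong
to the noon-to-noon day containing their onset and are not split at noon.
Sleep percentage counts every sleep epoch in the day, inside or outside
windows.  Midawake bouts are maximal wake runs between the day's first
window onset and last window offset, long-term if ≥ 60 min; because gaps
over 60 min never merge, long-term midawakes are exactly the inter-window
gaps of the nightly span.

The per-subject vector has 21 entries in a fixed registry order: three
general features (period, amplitude, total window count) and MN/SD over
valid days of nine daily features (phase, ST long, WT long, ST short,
WT short, sleep percentage, long/short window length, long-window count).
MN/SD use the sample SD (n−1; 0 for a single day).  Records qualify via
their longest run of consecutive days with < 5 h nonwear (strict), at least
4 and at most 7 days.

## Rhythm indexes

**Period.**  Wake minutes per 10-min bin are folded at every candidate
period K·10 min, K from 30 to 210 (5–35 h).  The statistic
Qp = N·Σ_h n_h(M̄_h − M̄)² / Σ_i(x_i − M̄)² is the ANOVA form whose null
distribution is χ² with K−1 degrees of freedom; the period maximizes
Qp − χ²₀.₉₉(K−1), ties to the smallest period.  The grid granularity is one
bin (10 min ≈ 0.17 h) because folding requires integer columns.  A
zero-variance record has no defined period and is rejected.

**Amplitude.**  Population SD over mean of the binned wake values — scale
free, and exactly √2 and 4√2/13 for the two reference square waves (duty
1/3 over 0–10 and 3–7 min), which the tests pin to 1e−9.

**Phase.**  The van der Pol oscillator ẍ − μ(1−x²)ẋ + x = 0 is integrated
(RK45, tolerances 1e−9) onto its limit cycle, one cycle is extracted between
successive upward zero crossings (with a convergence check on successive
cycle lengths), min–max normalized to [0, 1], rotated so the minimum sits at
phase zero, and time-rescaled to 24 h.  μ defaults to 1.0 (a mildly
relaxational cycle); at μ → 0 the waveform reduces to (1 − cos)/2, verified
in tests.  The day's epochs are encoded wake = 1, sleep = 0, missing = 0.5
(neutral), and the waveform is slid circularly over the day at 1-min
resolution minimizing SSE (computed via FFT cross-correlation; ties to the
smallest shift).  Phase is the time from the day's starting noon to the
fitted minimum, mapped to (0, 24] — so a minimum at midnight gives 12.00 and
a minimum at 02:00 gives 14.00, placing "morning" phenotypes at low phase
and "night" phenotypes at high phase.  The fit always uses the fixed 24-h
cycle rather than the estimated period: phase is defined against clock time,
and day-to-day drift is already captured by the phase SD.  Phase MN/SD are
naive (non-circular) statistics on (0, 24]; cohorts concentrated near the
wrap point would need circular statistics, a known limitation.

## Landscape clustering

Index tables are standardized per column (sample SD; zero-variance columns
become 0 with a warning).  The default embedding is UMAP to 3-D with
n_neighbors 50 and min_dist 0, seeded and therefore deterministic; PCA,
t-SNE and PCA+UMAP are selectable for comparison.  DBSCAN runs on the
embedding with min_samples 20 (matching the size-20 split rule).  Because
UMAP's coordinate scale varies with n and data, the default radius is read
off the data by the standard k-distance heuristic — 1.5× the median distance
to the 20th neighbour — which keeps dense blobs connected while separating
gaps an order of magnitude wider; a fixed eps remains available in the
configuration.

The divisive procedure re-standardizes, re-embeds and re-clusters inside
each node; a split is accepted only when at least two children have ≥ 20
members.  Children below that size fold into the largest accepted sibling
(preserving the partition property); DBSCAN noise is recorded on the node
and excluded from its children.  Recursion stops at depth 3.  Leaves are
then regrouped by Ward's method on their mean z-profiles, constrained within
each first-layer cluster so top-level relationships survive; the dendrogram
is cut at a configurable group count per first-layer cluster (default 2,
capped by leaf count).  Labels are hierarchical (``1``, ``2a``, ``2b``, …,
first-layer clusters numbered by size).

The outlier branch flags any subject at or beyond the 2.28th/97.72th
percentile (linear interpolation, boundaries inclusive) in any of six
designated indexes — default WT long MN, ST long SD, ST short MN, sleep
percentage MN, phase MN, period, chosen as the axes along which extreme
phenotypes (insomnia-like, hypersomnia-like, morning/night types, non-24-h
cycles) separate — and re-clusters just those subjects.  For independent
continuous indexes the flagged fraction converges to 1 − (1 − 0.0456)⁶ ≈
24.4%; on real, correlated indexes it is larger.

## Problem sizes and verification

The test-suite and acceptance-script runs use sizes chosen to exercise each
claim while staying desk-scale: 1,000 random series against the brute-force
window/smoothing oracles; 200 planted-phase days at 10% epoch noise (≥ 95%
recovered within 0.5 h); a 70-subject classifier cohort (50 train / 20
test, one day each at 20 Hz); a 2,000-subject four-archetype clustering
cohort (recovery scored on the first clustering layer, since the planted
truth is a four-way top-level structure and deeper leaves capture
within-archetype substructure); and a 20,000-subject outlier ensemble.
Passing these establishes internal correctness and planted-truth recovery
under the generator's assumptions, not performance on any real cohort.

## Known limitations

Binary sleep/wake only (no staging, no apnea); no device calibration or
temperature correction; no binary device-format parsing; naive circular
statistics for phase; the periodogram's 10-min period granularity; and
synthetic validation in place of polysomnography ground truth.
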