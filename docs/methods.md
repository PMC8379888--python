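# Methods

This note records the models, conventions and design choices behind
`demandclust`, in the order the pipeline runs them.

## Demand model and domain types

Demand is modelled at two resolutions.  An `EventLog` holds individual
arrivals at minute resolution (needed for waiting-time analysis); a
`DemandSeries` holds one non-negative integer count per calendar day and is
the unit of feature construction, clustering and forecasting.  A `Calendar`
fixes the observation window and holiday intervals; weeks are 7-day blocks
counted from the window start, and the number of weeks is `ceil(days/7)`.

The default `study_calendar()` spans 693 days (2018-01-01 to 2019-11-24,
exactly 99 weeks, starting a Monday) with four week-aligned 7-day holidays,
leaving 95 service weeks.  A week *intersecting* a holiday interval counts as
a holiday week; with week-aligned holidays this equals one holiday week per
holiday.  The window length and holidays are ordinary parameters — nothing
downstream assumes this particular calendar.

Series with fewer than `min_total = 51` total demands are dropped before
clustering (`filter_by_total_demand`): below that a series is so sporadic
that most features are estimated from a handful of days and no stable
pattern can be asserted.

## Synthetic generator

`generate_series` draws, for every non-holiday day, a Bernoulli demand
indicator with probability `p_demand` modulated by a 7-weight day-of-week
profile (normalised so the mean daily probability stays `p_demand`); demand
days receive a size from one of three families:

| family | parameters | mean | CV² |
|---|---|---|---|
| `constant` | mean | mean | 0 |
| `shifted_poisson` | lam | 1 + lam | lam/(1+lam)² |
| `lognormal` (rounded to ≥ 1) | mean, sigma | ≈ mean | ≈ exp(sigma²) − 1 |

Each demand unit gets an intraday timestamp from a 24-weight hourly profile
(default: business-hours peaked) plus a uniform minute.  Per-series random
substreams derive from `SeedSequence((panel_seed, series_index))`, so panels
are reproducible and series are independent.

The day-level Bernoulli occurrence + conditional size structure is the
demand-arrival assumption under which the CV²/AII quadrant scheme was
derived, which makes the generator the right null model for exercising the
classifier.  What it deliberately does *not* emulate: autocorrelated
occurrence (outbreak clustering), long-run trend or seasonality beyond the
weekly profile, and size/interval dependence.  Passing tests therefore show
the pipeline recovers Bernoulli-style planted structure, not that it handles
trending or bursty real-world demand.

### Pattern presets

The four presets were calibrated once so that 99-week panels land at
realistic CV²/AII levels for daily health-service demand and are mutually
well separated:

| preset | p_demand | sizes | AII ≈ | CV² ≈ |
|---|---|---|---|---|
| erratic | 0.62 | lognormal(8, 0.672) | 1.7 | 0.57 |
| lumpy | 0.38 | lognormal(4, 0.708) | 2.7 | 0.65 |
| slow | 0.18 | shifted_poisson(0.3) | 5.7 | 0.16 |
| smooth | 0.85 | shifted_poisson(1.5) | 1.2 | 0.24 |

Each preset also carries a distinct weekly profile (a weekday-heavy clinic,
a midweek-peaked service, a flat ward, a weekday-only desk): distinct
day-of-week mixes are a genuine feature of distinct departments, and they
give the weekly-shape feature group planted structure instead of pure noise.
The intraday and weekly profiles are plausible placeholders, not estimates
from real data; swap in measured profiles via `PatternSpec` when available.

Note the deliberate tension in the erratic preset: its AII (≈1.7) sits
*above* the classic 1.32 cutoff, as frequent-but-volatile daily
health-service demand really does.  Under the classic quadrants such series
read "lumpy"; under cutoffs calibrated for this domain (CV² ≈ 0.32,
AII ≈ 1.85 — the thresholds the learned groups themselves exhibit) they read
"erratic".  `sbc_classify` keeps the classic defaults and takes cutoffs as
parameters.

## Features

`compute_cv2` uses population variance over nonzero daily sizes (the
sample/population distinction matters only for very short series; population
is the convention here and is what the brute-force test oracles implement).
`compute_aii` averages day-index gaps between consecutive demand days;
demand outside the window is ignored, and both statistics require at least
two demand days (otherwise `FeatureUndefinedError` names the series and
feature).

The default registry has six groups: size level (nonzero mean/median/max,
daily mean), size variability (CV, CV², std, skew of nonzero sizes),
intermittence (AII, log AII, zero-day proportion, max zero run, log1p max
zero run, demand-day count), temporal dependence (lag-1..7 autocorrelation),
trend (slope of weekly totals, last/first-quarter volume ratio with +1
smoothing) and weekly shape (7 day-of-week demand shares).  The log variants
in the intermittence group exist because AII and zero-run length are
ratio-scaled and right-skewed across a mixed panel: without them a few
highly intermittent series dominate the z-scored Euclidean geometry and the
frequent patterns collapse into one cluster.  The registry is an ordered,
user-extensible structure; drop in a replacement group to reproduce any
specific published feature list.

Features are z-scored per column within the analysed panel before
clustering (constant columns become zero).  Unstandardised clustering would
be dominated by volume features; if a use case demands raw features, pass
`FeatureMatrix.raw` yourself.

## Clustering battery and consensus

`run_battery` clusters every feature group with every linkage (default:
single, complete, average, Ward — the four standard agglomerative criteria)
on Euclidean distances of the standardised group features, cutting each tree
at `k_hier = 4`.  Everything is deterministic: scipy's linkage and
`fcluster(criterion="maxclust")`, no random initialisation anywhere.

One-hot encoding maps label `c` of run `r` to position `r·k + (c−1)`; rows
have exactly `R` ones, so cosine similarity reduces to
(number of agreeing runs)/R — an integer over R, invariant to relabelling
clusters within any run.

`partition_similarity` clusters the *multiset of off-diagonal pairwise
similarities* (not a per-series aggregate) into `k_sim = 3` levels with an
exact 1-D k-means: a dynamic program over contiguous splits of the sorted
values, optimal because 1-D SSE-optimal partitions are contiguous.  The
`seed` argument is accepted for API symmetry but unused.  Values equidistant
between two level centroids go to the lower level (conservative: fewer high
edges).  Fewer than three distinct values is reported as a degenerate
partition, not silently forced.

`build_consensus` connects all high-level pairs and reads groups off the
connected components.  **Sparse-bridge pruning** formalises the manual step
of cutting a single series' stray edges: an edge (u, v) is pruned when, for
either endpoint w (with far endpoint x), removing w splits the graph such
that x's component differs from the component holding most of w's other
neighbours, both components have ≥ `min_component` (3) nodes, and w has
≤ `min_support` (2) neighbours on x's side.  The test is evaluated for both
endpoints — not only the lower-degree one — because the bridge node of two
glued cliques can easily be the *higher*-degree endpoint of its cross-edges.
All qualifying edges are identified on the unpruned graph and removed
simultaneously, so the result does not depend on edge order.  Pruning is
configurable and can be disabled.

`reassign_small_groups` merges groups of ≤ `max_small` (2) series, for
pattern-labelling purposes, into the larger group with which they share the
*fewest* low-level pairs — a low-similarity link is positive evidence of
disagreement across the battery, so fewer such links means closer kinship.
Ties are flagged unresolved and left standing rather than broken silently.
The fine-grained groups are retained alongside the merged pattern groups.

Group labels come from a majority CV²/AII quadrant vote over members
(`label_groups`), robust to a single outlying member; boundary values count
as the high side on both axes.  Vote ties are flagged.

## Forecasting

Croston keeps exponentially smoothed estimates of nonzero size `ẑ` and
inter-demand interval `p̂`, updated only on demand periods with a common
smoothing constant α; the per-period forecast is `ẑ/p̂`, held between
demands.  Initialisation: `ẑ₀` = first nonzero size, `p̂₀` = first
inter-demand interval (the classic choice); the forecast for period t uses
the state after the last demand strictly before t, and forecasts are NaN up
to and including the second demand period.  SBA multiplies the Croston
forecast by (1 − α/2).  Two identities pin the implementation: constant
demand c every d periods is an exact fixed point with forecast c/d, and
SBA/Croston = 1 − α/2 holds elementwise to machine precision.

`compare_methods` splits each series chronologically (default 75/25),
selects α per method from a small grid {0.05, 0.1, 0.15, 0.2} by training
MAE, and declares the winner by test MAE scaled by the in-sample naïve-mean
MAE (MAE and RMSE are also reported — the right error metric for
intermittent demand is genuinely contested, so all three are kept).  Series
whose test tail has no demand are flagged and excluded from win counts.

## Service analysis

`actual_metrics` reports: demand days and service days (distinct days with
≥ 1 arrival / occasion) and their ratio; the mean patient waiting time in
hours from each arrival to the first service occasion at or after it (an
arrival after the day's service waits for the next occasion — forced by the
definition; arrivals with no later occasion are warned about and excluded);
and inter-demand intervals, defined as maximal runs of zero-demand days
strictly between demand days, reported per calendar week and as a mean run
length.  The interval definition is the natural zero-run reading; it
reproduces the qualitative ordering (slow demand: few, long intervals) but
other readings exist.

Fixed weekly strategies place one occasion per listed weekday per
non-holiday week at 17:00 (Saturdays at noon); next-day strategies serve the
day after each demand day.  Ideal service occasions = occasions/week ×
(calendar weeks − holiday weeks).  `strategy_gap` evaluates a strategy on a
demand log and reports the waiting-time gap (actual minus under-strategy
mean wait) and the service-day gap (actual service days minus ideal
occasions).  One service day is assumed to clear all waiting demand — no
queueing or capacity model.

## Pipeline, determinism and problem sizes

`run_pipeline` wires the stages together from a YAML config (schema in
`examples/config.yaml`), writes every artifact as CSV/GraphML/JSON and a
manifest with SHA-256 checksums; a fixed (config, seed) pair reproduces
byte-identical outputs.  The CLI is a thin wrapper that runs the pipeline up
to a named stage.

Test and acceptance problem sizes are desk-scale by design: 40-series
panels over 99 weeks for recovery experiments (ten panels per run), 50
series per arm for the forecasting comparison, and 200–1000 random cases
per oracle-equivalence suite.  These sizes give stable verdicts (recovery
has been exact on every panel tried at the default presets) while keeping a
full run in seconds.

## Known limitations

* The consensus depends on the 3-level split of similarities; with very few
  series the off-diagonal multiset is small and the level split is coarse.
* Bridge pruning targets the single-glue-node topology; two groups glued by
  several independent cross-edges are (correctly, but irrevocably) one
  component.
* Croston/SBA are the only forecasters, and α is selected from a small grid
  per series; no prediction intervals.
* The generator's independence assumptions understate the difficulty of
  real demand (see above); treat synthetic recovery rates as an upper bound.
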