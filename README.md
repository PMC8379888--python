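# demandclust

Pattern classification and service analysis for **intermittent daily demand**
in health-service operations — the kind of demand a hospital teleconsultation
or referral desk sees: many zero-demand days, bursts of requests on others.
The package is for operations analysts who need to (a) group departments by
demand pattern, (b) pick the right intermittent-demand forecaster per group,
and (c) judge whether the current service schedule wastes staffed days or
patient waiting time.

## The method

Classical demand classification places a series in a quadrant by two
statistics of its daily counts:

* **CV²** — squared coefficient of variation of the nonzero demand sizes,
  `CV² = σ²/μ²` (population variance); high CV² = volatile sizes;
* **AII** — average inter-demand interval, the mean day gap between
  consecutive demand days; AII = 1 means demand every day, high AII =
  intermittent demand,

with conventional cutoffs CV² = 0.49 and AII = 1.32 separating
smooth / erratic / slow / lumpy demand.  Those cutoffs were tuned for spare
parts, and daily health-service demand straddles them awkwardly, so the
package's centrepiece learns the grouping from the data with an **ensemble of
hierarchical clusterings**:

1. **Features, in groups.** Six feature groups per series (size level, size
   variability, intermittence, temporal dependence, trend, weekly shape),
   z-scored within the panel.
2. **Clustering battery.** Every feature group × every linkage criterion
   (single, complete, average, Ward; Euclidean distances), each tree cut at
   k = 4 → 24 base clusterings.
3. **One-hot cosine consensus.** Base labels are one-hot encoded; the cosine
   similarity of two series' encodings equals the fraction of runs that put
   them in the same cluster — a label-permutation-invariant co-membership
   score.  An exact 1-D k-means (dynamic program over contiguous splits, no
   initialisation randomness) splits the pairwise scores into high / middle /
   low.
4. **Graph consensus.** Series joined by high-level edges form a graph;
   connected components are the consensus groups.  Sparse bridges (one series
   whose few cross-edges glue two dense groups) are pruned; tiny groups are
   merged into the neighbour they share the *fewest* low-similarity links
   with.  Groups are then labelled by majority CV²/AII quadrant vote.

Validation closes the loop twice: **Croston vs SBA** forecasting (SBA =
Croston × (1 − α/2); its bias correction should win precisely on the
high-CV² groups), and **service analysis** — demand-days/service-days
efficiency ratios and mean patient waiting time under fixed weekly service
strategies (n occasions per week at 17:00, Saturdays at noon, holiday weeks
skipped).

Since real teleconsultation records are restricted, the package ships a
calibrated synthetic generator: day-level Bernoulli demand occurrence with a
day-of-week profile, positive integer demand sizes (constant,
shifted-Poisson, or discretised lognormal), intraday arrival times, and
holiday closures, with presets planting the four patterns at realistic
CV²/AII levels.

## Worked example

`examples/03_consensus_pipeline.py` generates a 40-series panel (10 series
from each pattern preset over a 99-week calendar) and runs the full
consensus pipeline:

```
battery: 24 runs; similarity level centroids (low/mid/high): (0.19, 0.42, 0.82)
group of 10 series -> erratic  CV2 [0.48, 0.71] AII [1.66, 1.80]
group of 10 series -> lumpy    CV2 [0.44, 0.81] AII [2.68, 2.93]
group of 10 series -> slow     CV2 [0.14, 0.22] AII [4.90, 6.33]
group of 10 series -> smooth   CV2 [0.22, 0.25] AII [1.21, 1.25]
ARI vs planted patterns: 1.000
```

Reading: the 780 pairwise co-membership scores fall into three bands
(centroids 0.19/0.42/0.82); the high band's graph has exactly four
components, matching the planted patterns perfectly (adjusted Rand index
1.0), and each group's CV²/AII ranges sit where its pattern should — e.g.
the "slow" group is the most intermittent (AII 4.9–6.3) with the stablest
sizes.  The other examples cover generation (`01`), quadrant classification
and why domain cutoffs matter (`02`), Croston-vs-SBA validation (`04`) and
fixed-strategy service analysis (`05`); each prints a short annotated
table.

A thin CLI wraps the same pipeline for shell use:

```bash
demandclust all --config examples/config.yaml --out-dir out/
```

writing feature matrices, the label matrix, the similarity matrix and
levels, graph exports, the per-series pattern report, the forecasting
comparison and service reports, plus a `manifest.json` with checksums.

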