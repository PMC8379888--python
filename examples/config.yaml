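# Pipeline configuration for the `demandclust` CLI.
# Run:  demandclust all --config examples/config.yaml --out-dir out/
calendar:
  start: 2018-01-01
  end: 2019-11-24            # 693 days = 99 weeks
  holidays:                   # closed date ranges; weeks touching one are
    - [2018-02-12, 2018-02-18]   # skipped by fixed weekly schedules
    - [2018-10-01, 2018-10-07]
    - [2019-02-04, 2019-02-10]
    - [2019-09-30, 2019-10-06]
seed: 1
# Either a synthetic panel ...
panel:
  - {pattern: erratic, n_series: 10}
  - {pattern: lumpy, n_series: 10}
  - {pattern: slow, n_series: 10}
  - {pattern: smooth, n_series: 10}
# ... or an event-log CSV with columns series_id,timestamp:
# event_log_path: data/events.csv
min_total: 51        # drop series with fewer than this many demands
linkages: [single, complete, average, ward]
k_hier: 4            # clusters per base run
k_sim: 3             # similarity levels (high / middle / low)
prune: true          # sparse-bridge pruning of the high-similarity graph
max_small: 2         # groups this small get merged for pattern labelling
alphas: [0.05, 0.1, 0.15, 0.2]
split: 0.75          # chronological train fraction for forecasting
strategies:
  - {name: four_weekly, service_days: [monday, tuesday, wednesday, saturday]}
  - {name: two_weekly, service_days: [wednesday, friday]}
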