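import datetime as dt

import numpy as np
import pytest

from demandclust import (
    Calendar,
    DemandSeries,
    PanelSpec,
    PATTERN_PRESETS,
    aggregate_daily,
    build_consensus,
    compute_aii,
    compute_cv2,
    cosine_similarity,
    extract_features,
    generate_panel,
    one_hot_encode,
    partition_similarity,
    reassign_small_groups,
    run_battery,
    study_calendar,
)


def make_series(counts, sid="s", start=dt.date(2022, 1, 3)):
    return DemandSeries(series_id=sid, start_date=start, counts=np.asarray(counts))


@pytest.fixture
def week_cal():
    # Monday..Sunday, no holidays
    return Calendar(start=dt.date(2022, 1, 3), end=dt.date(2022, 1, 9))


@pytest.fixture(scope="session")
def panel_recovery_results():
    """Full pipeline on ten 40-series 4-pattern panels (shared, expensive).

    Returns a list of dicts with the planted labels, the consensus result
    and the per-series (cv2, aii) stats for each panel seed.
    """
    cal = study_calendar()
    results = []
    for seed in range(10):
        blocks = tuple(
            (PATTERN_PRESETS[name], 10)
            for name in ("erratic", "lumpy", "slow", "smooth")
        )
        logs, planted = generate_panel(PanelSpec(blocks=blocks, calendar=cal, seed=seed))
        series = [aggregate_daily(log, cal) for log in logs]
        fm = extract_features(series)
        lm = run_battery(fm)
        sim = cosine_similarity(one_hot_encode(lm))
        sp = partition_similarity(sim, lm.series_ids)
        cr = reassign_small_groups(build_consensus(sp), sp)
        stats = {s.series_id: (compute_cv2(s), compute_aii(s)) for s in series}
        results.append(
            {
                "planted": dict(zip([log.series_id for log in logs], planted)),
                "consensus": cr,
                "stats": stats,
            }
        )
    return results
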