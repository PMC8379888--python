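"""Generate a synthetic intermittent-demand panel with planted patterns.

Builds a 99-week calendar with four week-long holidays, draws three series
from each of the four pattern presets, and prints each pattern's average
inter-demand interval (AII, days between demand days) and squared
coefficient of variation of demand sizes (CV²).  High AII = intermittent
demand; high CV² = volatile demand sizes.
"""

from demandclust import (
    PATTERN_PRESETS,
    PanelSpec,
    aggregate_daily,
    compute_aii,
    compute_cv2,
    generate_panel,
    study_calendar,
)

cal = study_calendar()
blocks = tuple((PATTERN_PRESETS[name], 3) for name in ("erratic", "lumpy", "slow", "smooth"))
logs, planted = generate_panel(PanelSpec(blocks=blocks, calendar=cal, seed=0))

print(f"calendar: {cal.n_days} days, {cal.n_weeks} weeks, {cal.n_holiday_weeks} holiday weeks")
print(f"{'series':<12}{'pattern':<10}{'total':>7}{'AII':>7}{'CV2':>7}")
for log, pattern in zip(logs, planted):
    s = aggregate_daily(log, cal)
    print(
        f"{log.series_id:<12}{pattern:<10}{s.total:>7}"
        f"{compute_aii(s):>7.2f}{compute_cv2(s):>7.2f}"
    )
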