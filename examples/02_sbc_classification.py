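"""Classify individual series with the classic CV²/AII quadrant scheme.

Each series falls in one of four quadrants relative to the cutoffs
CV² = 0.49 and AII = 1.32: smooth (low/low), erratic (high CV², low AII),
slow (low CV², high AII), lumpy (high/high).  The example shows that the
classic cutoffs put frequent-but-volatile daily health-service demand on
the "lumpy" side — the motivation for learning groups from the data with
the consensus pipeline instead of fixed cutoffs.
"""

from demandclust import (
    PATTERN_PRESETS,
    aggregate_daily,
    compute_aii,
    compute_cv2,
    generate_series,
    sbc_classify,
    study_calendar,
)

cal = study_calendar()
print(f"{'planted':<10}{'CV2':>7}{'AII':>7}  {'classic quadrant':<18}{'domain cutoffs'}")
for name in ("erratic", "lumpy", "slow", "smooth"):
    s = aggregate_daily(generate_series(PATTERN_PRESETS[name], cal, seed=5), cal)
    cv2, aii = compute_cv2(s), compute_aii(s)
    classic = sbc_classify(cv2, aii)
    domain = sbc_classify(cv2, aii, cv2_cut=0.32, aii_cut=1.85)
    print(f"{name:<10}{cv2:>7.2f}{aii:>7.2f}  {classic:<18}{domain}")
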