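"""Service efficiency and quality under fixed weekly strategies.

Evaluates an erratic-demand department against fixed schedules of 4 and 2
service occasions per week (17:00, Saturdays at noon) over a 99-week
window with 4 holiday weeks.  Reported: the demand-day/service-day
efficiency ratio, the mean patient waiting time under each schedule, and
the ideal number of service occasions (occasions/week × 95 service
weeks) — denser schedules buy shorter waits at the cost of more service
days.
"""

from demandclust import (
    PATTERN_PRESETS,
    FixedStrategy,
    actual_metrics,
    generate_series,
    ideal_service_times,
    schedule_services,
    study_calendar,
    waiting_time_gap,
)

cal = study_calendar()
log = generate_series(PATTERN_PRESETS["erratic"], cal, seed=4, series_id="erratic-demo")

strategies = {
    "4/week (Mon-Wed+Sat)": FixedStrategy(services_per_week=4, service_days=(0, 1, 2, 5)),
    "2/week (Wed,Fri)": FixedStrategy(services_per_week=2, service_days=(2, 4)),
}
reports = {}
for name, strat in strategies.items():
    svc = schedule_services(strat, cal, demand_log=log)
    rep = actual_metrics(log, svc, cal)
    reports[name] = rep
    print(
        f"{name:<22} ideal occasions {ideal_service_times(strat, cal):>4}"
        f"  demand/service ratio {rep.ratio:4.2f}"
        f"  mean wait {rep.mean_wait_h:5.2f} h"
    )
dense, sparse = reports["4/week (Mon-Wed+Sat)"], reports["2/week (Wed,Fri)"]
print(f"waiting-time cost of the sparser schedule: "
      f"{waiting_time_gap(sparse, dense):.2f} h per patient")
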