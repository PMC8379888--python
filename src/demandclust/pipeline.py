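"""End-to-end pipeline: panel → features → consensus → labels → reports.

`run_pipeline` wires the modules together and writes every intermediate
artifact (CSV/GraphML/JSON) plus a manifest with SHA-256 checksums, so a run
is fully auditable and byte-reproducible given (config, seed).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from . import core_io, features, forecasting, patterns, service, synthetic

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for one pipeline run.

    Either ``event_log_path`` points at an existing event-log CSV, or
    ``panel`` describes a synthetic panel to generate.  Remaining fields
    mirror the method's tunables: the small-series filter, linkage battery,
    cluster counts, pruning, small-group merging, the forecasting grid and
    the fixed service strategies to evaluate.
    """

    calendar: core_io.Calendar
    panel: synthetic.PanelSpec | None = None
    event_log_path: str | None = None
    min_total: int = 51
    linkages: tuple[str, ...] = cns.DEFAULT_LINKAGES
    k_hier: int = 4
    k_sim: int = 3
    prune: cns.PruneConfig = field(default_factory=cns.PruneConfig)
    max_small: int = 2
    alphas: tuple[float, ...] = forecasting.DEFAULT_ALPHAS
    split: float = 0.75
    strategies: tuple[tuple[str, service.FixedStrategy], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.panel is None and self.event_log_path is None:
            raise ValueError("config needs a panel spec or an event-log path")
        if self.k_hier < 2 or self.k_sim < 2:
            raise ValueError("cluster counts must be >= 2")
        if not (0.0 < self.split < 1.0):
            raise ValueError("split must be in (0, 1)")


_STRATEGY_DAYS = {name: i for i, name in enumerate(service.WEEKDAY_NAMES)}


def load_config(path) -> RunConfig:
    """Read a YAML run config (documented schema in docs/methods.md)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config file must be a YAML mapping")
    if "calendar" not in raw:
        raise ValueError("config missing required key 'calendar'")
    calraw = raw["calendar"]
    cal = core_io.Calendar(
        start=dt.date.fromisoformat(str(calraw["start"])),
        end=dt.date.fromisoformat(str(calraw["end"])),
        holidays=tuple(
            (dt.date.fromisoformat(str(a)), dt.date.fromisoformat(str(b)))
            for a, b in calraw.get("holidays", [])
        ),
    )
    seed = int(raw.get("seed", 0))
    panel = None
    if "panel" in raw:
        blocks = []
        for b in raw["panel"]:
            spec = synthetic.PATTERN_PRESETS[str(b["pattern"])]
            blocks.append((spec, int(b["n_series"])))
        panel = synthetic.PanelSpec(blocks=tuple(blocks), calendar=cal, seed=seed)
    strategies = []
    for s in raw.get("strategies", []):
        if s.get("next_day"):
            strat = service.FixedStrategy(next_day=True)
        else:
            days = tuple(sorted(_STRATEGY_DAYS[d.lower()] for d in s["service_days"]))
            strat = service.FixedStrategy(
                services_per_week=len(days), service_days=days
            )
        strategies.append((str(s.get("name", f"strategy{len(strategies)}")), strat))
    return RunConfig(
        calendar=cal,
        panel=panel,
        event_log_path=raw.get("event_log_path"),
        min_total=int(raw.get("min_total", 51)),
        linkages=tuple(raw.get("linkages", cns.DEFAULT_LINKAGES)),
        k_hier=int(raw.get("k_hier", 4)),
        k_sim=int(raw.get("k_sim", 3)),
        prune=cns.PruneConfig(enabled=bool(raw.get("prune", True))),
        max_small=int(raw.get("max_small", 2)),
        alphas=tuple(float(a) for a in raw.get("alphas", forecasting.DEFAULT_ALPHAS)),
        split=float(raw.get("split", 0.75)),
        strategies=tuple(strategies),
        seed=seed,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


_STAGE_ORDER = ("simulate", "features", "cluster", "classify", "forecast", "service")


def run_pipeline(config: RunConfig, out_dir, until: str = "all") -> dict:
    """Run the pipeline up to stage ``until`` and write artifacts to ``out_dir``.

    Stages in order: simulate (or ingest), features, cluster, classify,
    forecast, service; ``until='all'`` runs everything.  Returns a manifest
    dict (also written to ``manifest.json``) listing the stages run, their
    parameters, and every written file with its SHA-256 checksum.
    """
    if until != "all" and until not in _STAGE_ORDER:
        raise ValueError(f"unknown stage {until!r}")
    last = len(_STAGE_ORDER) - 1 if until == "all" else _STAGE_ORDER.index(until)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {"seed": config.seed, "stages": []}

    def note(stage: str, **params):
        manifest["stages"].append({"stage": stage, **params})

    def finish() -> dict:
        manifest["files"] = {
            p.name: _sha256(p) for p in sorted(written, key=lambda q: q.name)
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        return manifest

    cal = config.calendar

    # -- ingest / simulate
    if config.panel is not None:
        logs, planted = synthetic.generate_panel(config.panel)
        pd.DataFrame(
            {"series_id": [lg.series_id for lg in logs], "planted": planted}
        ).to_csv(out / "planted_labels.csv", index=False)
        written.append(out / "planted_labels.csv")
        note("simulate", n_series=len(logs), seed=config.seed)
    else:
        logs = core_io.read_event_log(config.event_log_path)
        note("ingest", path=str(config.event_log_path), n_series=len(logs))
    core_io.write_event_log(logs, out / "event_log.csv")
    written.append(out / "event_log.csv")

    series = [core_io.aggregate_daily(lg, cal) for lg in logs]
    kept, removed = core_io.filter_by_total_demand(series, config.min_total)
    core_io.write_daily_matrix(kept, out / "daily_matrix.csv")
    written.append(out / "daily_matrix.csv")
    note("filter", min_total=config.min_total, kept=len(kept), removed=len(removed))
    if last < 1:
        return finish()

    # -- features
    fm = features.extract_features(kept, features.default_registry())
    for group, df in fm.standardized.items():
        p = out / f"features_{group}.csv"
        df.to_csv(p, index_label="series_id")
        written.append(p)
    note("features", groups=fm.group_names)
    if last < 2:
        return finish()

    # -- battery + consensus
    lm = cns.run_battery(fm, linkages=config.linkages, k=config.k_hier)
    pd.DataFrame(
        lm.labels,
        index=list(lm.series_ids),
        columns=[f"{g}|{m}" for g, m in lm.runs],
    ).to_csv(out / "label_matrix.csv", index_label="series_id")
    written.append(out / "label_matrix.csv")

    sim = cns.cosine_similarity(cns.one_hot_encode(lm))
    sp = cns.partition_similarity(sim, lm.series_ids, k=config.k_sim, seed=config.seed)
    pd.DataFrame(sim, index=list(lm.series_ids), columns=list(lm.series_ids)).to_csv(
        out / "similarity.csv", index_label="series_id"
    )
    written.append(out / "similarity.csv")

    cr = cns.build_consensus(sp, prune=config.prune)
    cr = cns.reassign_small_groups(cr, sp, max_small=config.max_small)

    edges = [
        {
            "u": u,
            "v": v,
            "similarity": d["similarity"],
            "level": "high",
        }
        for u, v, d in cr.high_graph.edges(data=True)
    ]
    pd.DataFrame(edges, columns=["u", "v", "similarity", "level"]).to_csv(
        out / "high_graph_edges.csv", index=False
    )
    nx.write_graphml(cr.high_graph, out / "high_graph.graphml")
    written += [out / "high_graph_edges.csv", out / "high_graph.graphml"]
    note(
        "consensus",
        linkages=list(config.linkages),
        k_hier=config.k_hier,
        k_sim=config.k_sim,
        centroids=list(sp.centroids),
        n_fine_groups=len(cr.fine_groups),
        n_pattern_groups=len(cr.pattern_groups),
        pruned_edges=[list(e) for e in cr.pruned_edges],
    )
    if last < 3:
        return finish()

    # -- pattern labels
    stats = {
        s.series_id: (features.compute_cv2(s), features.compute_aii(s)) for s in kept
    }
    report = patterns.classification_report(cr, stats)
    report.to_csv(out / "pattern_report.csv", index=False)
    written.append(out / "pattern_report.csv")
    note("classify", n_groups=len(cr.pattern_groups))
    if last < 4:
        return finish()

    # -- forecasting comparison
    fc = forecasting.compare_methods(kept, alphas=config.alphas, split=config.split)
    fc = fc.merge(report[["series_id", "group_label"]], on="series_id", how="left")
    fc.to_csv(out / "forecast_comparison.csv", index=False)
    written.append(out / "forecast_comparison.csv")
    note("forecast", alphas=list(config.alphas), split=config.split)
    if last < 5:
        return finish()

    # -- service analysis under fixed strategies
    if config.strategies:
        rows = []
        kept_ids = {s.series_id for s in kept}
        for lg in logs:
            if lg.series_id not in kept_ids or not lg.arrivals:
                continue
            for name, strat in config.strategies:
                svc = service.schedule_services(strat, cal, demand_log=lg)
                rep = service.actual_metrics(lg, svc, cal)
                rows.append(
                    {
                        "series_id": lg.series_id,
                        "strategy": name,
                        "demand_days": rep.demand_days,
                        "service_days": rep.service_days,
                        "ratio": rep.ratio,
                        "mean_wait_h": rep.mean_wait_h,
                        "intervals_per_week": rep.intervals_per_week,
                        "mean_interval_len_d": rep.mean_interval_len_d,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "service_report.csv", index=False)
        written.append(out / "service_report.csv")
        note("service", strategies=[n for n, _ in config.strategies])

    return finish()
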