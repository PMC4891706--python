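"""End-to-end screen pipeline: simulate, analyse, classify, compare, plot.

``pipeline_run`` drives a complete synthetic screen from one configuration
mapping: ring-assay experiments per line, per-line summaries and six-way
classification against population boundaries, a control cross, plus
single-gap sessions with per-width box statistics and rank-sum comparisons
against control. It writes CSVs, a JSON report, a run manifest, a
screen scatter (line medians with category colours and the control cross)
and per-width box summaries.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import io as rio
from .geometry import ArenaGeometry, CatwalkSetup
from .ring_analysis import analyze_ring_experiment
from .screen import (
    Category,
    category_census,
    classify_line,
    compute_boundaries,
    control_summary,
    summarize_line,
)
from .simulate import SimConfig, simulate_catwalk_session, simulate_ring_experiment
from .single_gap import box_stats, compare_to_control, per_fly_fractions

CATEGORY_COLORS = {
    Category.NORMAL: "tab:green",
    Category.OVERCAUTIOUS: "tab:brown",
    Category.VERY_CLUMSY: "tab:red",
    Category.CLUMSY: "tab:purple",
    Category.OVEREAGER: "tab:blue",
    Category.SUPER_CLIMBER: "gold",
}

#: packaged demonstration screen: a small population dominated by
#: control-like lines with a few phenotypic ones mixed in
DEMO_CONFIG = {
    "screen": {
        "lines": (
            [{"line_id": f"ctrl_like_{i:02d}", "profile": "control"} for i in range(9)]
            + [
                {"line_id": "oc_1", "profile": "overcautious"},
                {"line_id": "cl_1", "profile": "clumsy"},
                {"line_id": "oe_1", "profile": "overeager"},
                {"line_id": "sc_1", "profile": "super_climber"},
            ]
        ),
        "n_replicates": 3,
        "control_profile": "control",
        "control_experiments": 8,
        "duration": 600,
    },
    "catwalk": {
        "lines": ["overeager", "super_climber", "tarsi_clumsy"],
        "control_profile": "control",
        "widths": [2.5, 3.5, 5.0],
        "n_flies": 12,
    },
}


def _screen_stage(cfg: dict, seed: int, out: Path) -> dict:
    geometry = ArenaGeometry(**cfg.get("geometry", {}))
    duration = int(cfg.get("duration", 600))
    summaries, all_metrics = [], []
    for li, line in enumerate(cfg["lines"]):
        metrics = []
        for rep in range(1, int(cfg["n_replicates"]) + 1):
            record = simulate_ring_experiment(
                SimConfig(
                    seed=seed + 1000 * li, profile=line["profile"],
                    duration=duration, line_id=line["line_id"], replicate=rep,
                ),
                geometry,
            )
            m = analyze_ring_experiment(record)
            metrics.append(m)
            all_metrics.append(m)
        summaries.append(summarize_line(metrics))
    boundaries = compute_boundaries(summaries)
    categories = {s.line_id: classify_line(s, boundaries) for s in summaries}
    census = category_census(list(categories.values()))

    ctrl_metrics = [
        analyze_ring_experiment(
            simulate_ring_experiment(
                SimConfig(
                    seed=seed + 900_000, profile=cfg["control_profile"],
                    duration=duration, line_id="control", replicate=rep,
                ),
                geometry,
            )
        )
        for rep in range(1, int(cfg["control_experiments"]) + 1)
    ]
    ctrl = control_summary(ctrl_metrics)

    pd.DataFrame(
        [
            {
                "line_id": s.line_id,
                "x": s.median_max_mean_distance,
                "y": s.median_pct_dead,
                "category": categories[s.line_id].value,
            }
            for s in summaries
        ]
    ).to_csv(out / "classification.csv", index=False)
    (out / "boundaries.json").write_text(json.dumps(vars(boundaries), indent=2))

    fig, ax = plt.subplots(figsize=(5, 4))
    for s in summaries:
        cat = categories[s.line_id]
        ax.scatter(s.median_max_mean_distance, s.median_pct_dead,
                   color=CATEGORY_COLORS[cat], s=18)
    ax.errorbar(ctrl.x_median, ctrl.y_median,
                xerr=[[ctrl.x_median - ctrl.x_q25], [ctrl.x_q75 - ctrl.x_median]],
                yerr=[[ctrl.y_median - ctrl.y_q25], [ctrl.y_q75 - ctrl.y_median]],
                color="darkgreen", lw=2.5, capsize=3)
    ax.axvline(boundaries.x_low, ls=":", color="grey")
    ax.axvline(boundaries.x_high, ls=":", color="grey")
    ax.axhline(boundaries.y_high, ls=":", color="grey")
    ax.set_xlabel("median max mean distance (rel. units)")
    ax.set_ylabel("median dead flies (%)")
    fig.tight_layout()
    fig.savefig(out / "screen_scatter.png", dpi=120)
    plt.close(fig)

    return {
        "boundaries": vars(boundaries),
        "categories": {k: v.value for k, v in categories.items()},
        "census_pct": {c.value: census[c] for c in census},
        "control_cross": vars(ctrl),
    }


def _catwalk_stage(cfg: dict, seed: int, out: Path) -> dict:
    widths = [float(w) for w in cfg["widths"]]
    n_flies = int(cfg["n_flies"])
    sessions: dict[str, list] = {}
    for name in list(cfg["lines"]) + [cfg["control_profile"]]:
        sessions[name] = [
            simulate_catwalk_session(
                name, CatwalkSetup(gap_width=w), n_flies,
                seed=seed + 17 * wi + zlib.crc32(name.encode()) % 10_000,
            )
            for wi, w in enumerate(widths)
        ]
    rows, comp_rows = [], []
    for name, logs in sessions.items():
        for log in logs:
            flies = per_fly_fractions(log)
            for metric in ("frac_attempt", "frac_cross", "frac_fall_given_attempt"):
                bs = box_stats([getattr(f, metric) for f in flies])
                rows.append({"line_id": name, "gap_mm": log.setup.gap_width,
                             "metric": metric, **vars(bs)})
        if name != cfg["control_profile"]:
            for c in compare_to_control(logs, sessions[cfg["control_profile"]]):
                comp_rows.append(
                    {"line_id": name, "gap_mm": c.gap_width, "metric": c.metric,
                     "rank_sum": c.statistic, "p_value": c.p_value,
                     "stars": c.stars.value}
                )
    stats_df = pd.DataFrame(rows)
    stats_df.to_csv(out / "gap_stats.csv", index=False)
    comp_df = pd.DataFrame(comp_rows)
    comp_df.to_csv(out / "gap_comparisons.csv", index=False)

    fig, axes = plt.subplots(1, len(sessions), figsize=(3 * len(sessions), 3),
                             sharey=True, squeeze=False)
    for ax, (name, logs) in zip(axes[0], sessions.items()):
        data = [[f.frac_attempt for f in per_fly_fractions(log)] for log in logs]
        ax.boxplot(data, tick_labels=[str(w) for w in widths], whis=(10, 90))
        ax.set_title(name, fontsize=8)
        ax.set_xlabel("gap (mm)")
    axes[0][0].set_ylabel("attempt fraction")
    fig.tight_layout()
    fig.savefig(out / "gap_boxes.png", dpi=120)
    plt.close(fig)

    return {
        "n_sessions": sum(len(v) for v in sessions.values()),
        "comparisons": comp_rows,
    }


def pipeline_run(config: dict | None = None, out_dir: str | Path = "ringgap_report",
                 seed: int = 0) -> dict:
    """Run the full synthetic screen and analysis; returns the JSON report."""
    config = config or DEMO_CONFIG
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": seed}
    if "screen" in config:
        report["screen"] = _screen_stage(config["screen"], seed, out)
    if "catwalk" in config:
        report["catwalk"] = _catwalk_stage(config["catwalk"], seed, out)
    manifest = rio.run_manifest(
        "report", seed, [], [str(p) for p in sorted(out.iterdir())], config
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
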