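"""End-to-end run: plan → sequence → simulate → calibrate → compare.

Chains the package's stages exactly the way a method-development run
would: schedule the dilution series, expand it into a timed sequence,
generate synthetic replicate electropherograms for the automated series
and for a manual-pipetting counterpart (same true concentrations,
independent noise), calibrate both, and compare them by Deming
regression of level-wise back-calculated concentrations.  All outputs are
written as CSV/JSON so they round-trip through the package's own readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import CalibrationCurve, integrate_peaks, tcpa_signal
from .compare import compare_modes, deming_lambda
from .config import RunConfig
from .mixture import Solution, schedule_to_composition
from .profiles import IS_LABEL, working_solution, diluent
from .scheduler import DilutionSchedule, plan_series
from .sequence import build_sequence, reagent_budget, vial_volumes
from .simulate import Electropherogram, simulate_series

__all__ = [
    "plan_frame",
    "sequence_frame",
    "calibrate_series",
    "run_end_to_end",
]


def plan_frame(schedules: list[DilutionSchedule]) -> pd.DataFrame:
    """Schedules as a tidy table, one row per transfer step."""
    rows = []
    for level, s in enumerate(schedules):
        for step in (s.ws_step, s.dbge_step):
            if step is None:
                continue
            rows.append(
                {
                    "level": level,
                    "target_conc": s.target_concentration,
                    "solution": step.solution,
                    "t_min": step.duration_min,
                    "p_psi": step.pressure_psi,
                    "p_kpa": round(step.pressure_kpa, 2),
                    "product": step.product,
                    "achieved_conc": s.achieved_concentration,
                    "rel_error": s.relative_dilution_error,
                }
            )
        if s.undiluted:
            rows.append(
                {
                    "level": level,
                    "target_conc": s.target_concentration,
                    "solution": "WS (undiluted)",
                    "t_min": 0.0,
                    "p_psi": 0.0,
                    "p_kpa": 0.0,
                    "product": 0.0,
                    "achieved_conc": s.achieved_concentration,
                    "rel_error": 0.0,
                }
            )
    return pd.DataFrame(rows)


def sequence_frame(seq) -> pd.DataFrame:
    rows = [
        {
            "index": i,
            "kind": e.kind,
            "liquid": e.liquid,
            "duration_min": e.duration_min,
            "pressure_psi": e.pressure_psi,
            "source_tray": e.source_tray,
            "dest_tray": e.dest_tray,
            "vial": e.vial,
        }
        for i, e in enumerate(seq.events)
    ]
    return pd.DataFrame(rows)


def calibrate_series(
    traces: list[Electropherogram],
    config: RunConfig,
    x_values: list[float],
) -> dict:
    """Integrate traces, form IS-ratio signals and fit each analyte.

    ``x_values`` are the per-level calibration concentrations (one per
    level, level-major order matching the traces).  Returns per-analyte
    fits, replicate signals and per-replicate back-calculations.
    """
    analyte_names = [a.name for a in config.analytes if a.name != IS_LABEL]
    points: dict[str, list[tuple[float, float, int]]] = {n: [] for n in analyte_names}
    for trace in traces:
        level = trace.metadata["level"]
        rep = trace.metadata["replicate"]
        peaks = integrate_peaks(trace, config.analytes)
        signals = tcpa_signal(peaks, is_label=IS_LABEL)
        for name in analyte_names:
            points[name].append((x_values[level], signals[name], rep))

    result: dict = {}
    for name in analyte_names:
        x = np.array([p[0] for p in points[name]])
        y = np.array([p[1] for p in points[name]])
        curve = CalibrationCurve().fit(x, y)
        back = curve.inverse_predict(y)
        result[name] = {
            "curve": curve,
            "x": x,
            "y": y,
            "replicate": np.array([p[2] for p in points[name]]),
            "back_calculated": back,
        }
    return result


def _level_stats(x: np.ndarray, back: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame({"x_true": x, "x_hat": back})
    g = df.groupby("x_true", sort=True)["x_hat"]
    out = g.agg(["mean", "std"]).reset_index()
    out["rel_error_pct"] = 100.0 * (out["mean"] - out["x_true"]) / out["x_true"]
    return out


def run_end_to_end(config: RunConfig, outdir: "str | Path") -> dict:
    """Execute a full preparation-and-evaluation run; write all artefacts.

    Returns the report dictionary that is also written to ``report.json``.
    Deterministic for a fixed config (seeded generator throughout).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- plan ---------------------------------------------------------
    targets = list(config.targets)
    if config.include_undiluted and config.stock not in targets:
        targets.append(config.stock)
    schedules = plan_series(
        targets, config.stock, config.budget, config.effective_constraints
    )
    pf = plan_frame(schedules)
    pf.to_csv(outdir / "plan.csv", index=False)
    (outdir / "plan.json").write_text(pf.to_json(orient="records", indent=2))

    # --- sequence -----------------------------------------------------
    seq = build_sequence(schedules, mode=config.mode)
    sequence_frame(seq).to_csv(outdir / "sequence.csv", index=False)
    budgets = reagent_budget(seq, config.geometry, config.fluid)
    summary = {
        "mode": seq.mode,
        "total_duration_min": seq.total_duration_min,
        "reagent_budget_ul": budgets,
        "vial_volumes_ul": vial_volumes(seq, config.geometry, config.fluid),
    }
    (outdir / "sequence.json").write_text(json.dumps(summary, indent=2))

    # --- simulate: automated series uses the scheduled compositions,
    # the manual series the exact nominal targets -----------------------
    ws = working_solution(config.stock)
    dbge = diluent()
    comps_auto = [
        schedule_to_composition(s, config.geometry, config.fluid, ws, dbge)
        for s in schedules
    ]
    comps_manual = [
        Solution(
            f"manual-{t:g}",
            {"prilocaine": t, "bupivacaine": t, IS_LABEL: 100.0},
            internal_standard=IS_LABEL,
        )
        for t in targets
    ]
    rng = np.random.default_rng(config.seed)
    seed_auto, seed_manual = (int(s) for s in rng.integers(0, 2**31 - 1, 2))
    traces_auto = simulate_series(
        comps_auto, config.analytes, config.noise, config.replicates, seed=seed_auto
    )
    traces_manual = simulate_series(
        comps_manual, config.analytes, config.noise, config.replicates,
        seed=seed_manual,
    )
    tdir = outdir / "traces"
    tdir.mkdir(exist_ok=True)
    manifest = []
    for label, traces in (("auto", traces_auto), ("manual", traces_manual)):
        for tr in traces:
            fname = f"{label}_L{tr.metadata['level']}_r{tr.metadata['replicate']}.csv"
            tr.to_csv(tdir / fname)
            manifest.append({"file": fname, "series": label, **tr.metadata})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))

    # --- calibrate both series -----------------------------------------
    cal_auto = calibrate_series(traces_auto, config, targets)
    cal_manual = calibrate_series(traces_manual, config, targets)
    fits = {}
    back_rows = []
    for name, res in cal_auto.items():
        c = res["curve"]
        fits[name] = {
            "slope": c.slope_,
            "intercept": c.intercept_,
            "r_squared": c.r_squared_,
            "n_used": c.n_used_,
            "n_rejected": c.n_rejected_,
        }
        stats = _level_stats(res["x"], res["back_calculated"])
        stats.insert(0, "analyte", name)
        back_rows.append(stats)
    (outdir / "calibration.json").write_text(json.dumps(fits, indent=2))
    pd.concat(back_rows).to_csv(outdir / "back_calculation.csv", index=False)

    # --- compare automated vs manual ------------------------------------
    comparison = {}
    for name in fits:
        sa = _level_stats(cal_auto[name]["x"], cal_auto[name]["back_calculated"])
        sm_ = _level_stats(cal_manual[name]["x"], cal_manual[name]["back_calculated"])
        sd_auto = float(sa["std"].mean())
        sd_manual = float(sm_["std"].mean())
        delta = deming_lambda(sd_manual, sd_auto)
        fit = compare_modes(sa["mean"].to_numpy(), sm_["mean"].to_numpy(), delta=delta)
        comparison[name] = {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "se_slope": fit.se_slope,
            "se_intercept": fit.se_intercept,
            "delta": fit.delta,
            "n": fit.n,
        }
    (outdir / "comparison.json").write_text(json.dumps(comparison, indent=2))

    report = {
        "n_levels": len(targets),
        "targets": targets,
        "vial": config.vial,
        "mode": config.mode,
        "total_duration_min": seq.total_duration_min,
        "vial_volumes_ul": summary["vial_volumes_ul"],
        "calibration": fits,
        "comparison": comparison,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))

    lines = [
        f"Calibration series: {len(targets)} levels in {config.vial} vials, mode {config.mode}",
        f"Preparation time: {seq.total_duration_min:.1f} min",
    ]
    for name, f in fits.items():
        lines.append(
            f"{name}: slope {f['slope']:.4f}, intercept {f['intercept']:.4f}, "
            f"r^2 {f['r_squared']:.4f} ({f['n_rejected']} outlier(s) rejected)"
        )
    for name, c in comparison.items():
        lines.append(
            f"{name} auto vs manual: slope {c['slope']:.3f} +/- {c['se_slope']:.3f}, "
            f"intercept {c['intercept']:.3f} +/- {c['se_intercept']:.3f}"
        )
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return report
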