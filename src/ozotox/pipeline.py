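"""End-to-end study analysis.

Composes the assay modules into the analysis loop the study runs per
cell line: summarise viability and compare treated vs control; compute
the CBMN indices (RI, CBPI, MN frequency) and micronucleus comparisons;
summarise comet damage with Mann-Whitney comparisons; fit the logistic
growth model to the control viability means; convert the measured
Replication-Index deficits into a piecewise exposure schedule; and
simulate the treated trajectory from the fitted control parameters.  The
simulation schedule is always derived from the CBMN input, never
hand-entered.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .growth import (
    FitResult,
    GrowthTrajectory,
    LogisticParams,
    RISchedule,
    fit_lgm,
    simulate_treated,
    solve_lgm,
)
from .indices import (
    CometCellRecord,
    MNScoreRecord,
    aggregate_mn,
    cbpi,
    mn_frequency,
    olive_tail_moment,
    replication_index,
)
from .io import read_cbmn, read_comet, read_viability, write_report
from .stats import compare_groups, percent_change, summarize_group

__all__ = ["PipelineConfig", "StudyReport", "run_pipeline", "analyze_tables"]

log = logging.getLogger("ozotox.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and options for one pipeline run."""

    viability_path: str | Path | None = None
    cbmn_path: str | Path | None = None
    comet_path: str | Path | None = None
    cell_line: str = "A549"
    scenario: Literal["constant", "time_varying"] = "time_varying"
    bounds: dict[str, tuple[float, float]] | None = None
    thresholds: tuple[float, float, float] = (0.05, 0.005, 0.0005)
    seed: int = 0
    fit_growth_model: bool = True
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        t = self.thresholds
        if not (t[0] > t[1] > t[2] > 0):
            raise ValueError("significance thresholds must be strictly decreasing")


@dataclass
class StudyReport:
    """Machine-readable result of a pipeline run."""

    cell_line: str
    viability: dict = field(default_factory=dict)
    cbmn: dict = field(default_factory=dict)
    comet: dict = field(default_factory=dict)
    growth_fit: FitResult | None = None
    ri_schedule: RISchedule | None = None
    control_trajectory: GrowthTrajectory | None = None
    treated_trajectory: GrowthTrajectory | None = None
    sections_absent: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def partial(self) -> bool:
        return bool(self.sections_absent)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(
        {
            "viability": str(config.viability_path),
            "cbmn": str(config.cbmn_path),
            "comet": str(config.comet_path),
            "cell_line": config.cell_line,
            "scenario": config.scenario,
            "bounds": config.bounds,
            "thresholds": config.thresholds,
            "seed": config.seed,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _analyze_viability(df: pd.DataFrame, cell_line: str) -> dict:
    """Per-time summaries, treated-vs-control t-tests, and the printed
    percent-change conventions (treated deficit per time, 72-vs-48 drop
    per condition)."""
    sub = df[df["cell_line"] == cell_line]
    if sub.empty:
        raise ValueError(f"viability table has no rows for cell line {cell_line!r}")
    out: dict = {"per_time": {}, "drops_72_vs_48": {}}
    times = sorted(sub["time_h"].unique())
    for t in times:
        at_t = sub[sub["time_h"] == t]
        ctrl = at_t[at_t["condition"] == "control"]["rlu"].to_numpy()
        trt = at_t[at_t["condition"] != "control"]["rlu"].to_numpy()
        if len(ctrl) == 0:
            raise ValueError(f"no control viability series at {t} h")
        entry = {"control": summarize_group(ctrl)}
        if len(trt):
            entry["treated"] = summarize_group(trt)
            entry["percent_change"] = percent_change(
                entry["treated"], entry["control"]
            )
            if len(trt) >= 2 and len(ctrl) >= 2:
                entry["comparison"] = compare_groups(trt, ctrl, test="t_test")
        out["per_time"][f"{t:g}"] = entry
    if 48.0 in times and 72.0 in times:
        for cond_label, cond_mask in (
            ("control", sub["condition"] == "control"),
            ("treated", sub["condition"] != "control"),
        ):
            g48 = sub[cond_mask & (sub["time_h"] == 48.0)]["rlu"]
            g72 = sub[cond_mask & (sub["time_h"] == 72.0)]["rlu"]
            if len(g48) and len(g72):
                out["drops_72_vs_48"][cond_label] = -percent_change(
                    float(g72.mean()), float(g48.mean())
                )
    # control means for growth-model fitting (normalised to the 0 h mean)
    ctrl_means = (
        sub[sub["condition"] == "control"].groupby("time_h")["rlu"].mean().sort_index()
    )
    out["_control_means"] = ctrl_means
    return out


def _analyze_cbmn(records: Sequence[MNScoreRecord], cell_line: str) -> dict:
    """RI, CBPI and MN frequency per time point, with replicate-level
    micronucleus comparisons.

    MN induction is reported both as the ratio of pooled frequencies and
    as the mean of per-replicate ratios (replicates paired by order).
    """
    recs = [r for r in records if r.cell_line == cell_line]
    if not recs:
        raise ValueError(f"CBMN table has no rows for cell line {cell_line!r}")
    out: dict = {"per_time": {}}
    times = sorted({r.time_h for r in recs})
    for t in times:
        ctrl = [r for r in recs if r.time_h == t and r.condition == "control"]
        trt = [r for r in recs if r.time_h == t and r.condition != "control"]
        if not ctrl:
            raise ValueError(f"no control CBMN records at {t} h")
        ctrl_pool = aggregate_mn(ctrl)
        entry = {
            "control": {
                "cbpi": cbpi(ctrl_pool),
                "mn_per_1000bn": mn_frequency(ctrl_pool),
            }
        }
        if trt:
            trt_pool = aggregate_mn(trt)
            ri = replication_index(trt_pool, ctrl_pool)
            entry["treated"] = {
                "cbpi": cbpi(trt_pool),
                "mn_per_1000bn": mn_frequency(trt_pool),
            }
            entry["ri"] = ri
            entry["ri_deficit"] = max(0.0, 1.0 - ri / 100.0)
            if ri > 100.0:
                log.warning(
                    "RI %.1f > 100 at %g h (treated proliferating faster); "
                    "schedule reduction clamped at 0",
                    ri, t,
                )
            freq_t = [mn_frequency(r) for r in trt]
            freq_c = [mn_frequency(r) for r in ctrl]
            entry["mn_fold_pooled"] = (
                mn_frequency(trt_pool) / mn_frequency(ctrl_pool)
                if mn_frequency(ctrl_pool) > 0
                else None
            )
            ratios = [
                ft / fc for ft, fc in zip(freq_t, freq_c) if fc > 0
            ]
            entry["mn_fold_replicate_mean"] = (
                float(np.mean(ratios)) if ratios else None
            )
            if len(freq_t) >= 2 and len(freq_c) >= 2:
                entry["mn_comparison"] = compare_groups(freq_t, freq_c, "t_test")
        out["per_time"][f"{t:g}"] = entry
    return out


def _analyze_comet(records: Sequence[CometCellRecord], cell_line: str) -> dict:
    """Group means +/- SE of tail DNA % and OTM (per-slide means averaged
    across replicate slides) with per-cell Mann-Whitney comparisons."""
    recs = [r for r in records if r.cell_line == cell_line]
    if not recs:
        raise ValueError(f"comet table has no rows for cell line {cell_line!r}")
    df = pd.DataFrame(
        {
            "slide_id": [r.slide_id for r in recs],
            "condition": [r.condition for r in recs],
            "time_h": [r.time_h for r in recs],
            "tail_dna_pct": [r.tail_dna_pct for r in recs],
            "otm": [olive_tail_moment(r) for r in recs],
        }
    )
    out: dict = {"per_time": {}}
    for t in sorted(df["time_h"].unique()):
        at_t = df[df["time_h"] == t]
        entry = {}
        for label, mask in (
            ("control", at_t["condition"] == "control"),
            ("treated", at_t["condition"] != "control"),
        ):
            grp = at_t[mask]
            if grp.empty:
                continue
            slide_means = grp.groupby("slide_id")[["tail_dna_pct", "otm"]].mean()
            entry[label] = {
                "tail_dna_pct": summarize_group(slide_means["tail_dna_pct"]),
                "otm": summarize_group(slide_means["otm"]),
            }
        if "control" in entry and "treated" in entry:
            ctrl = at_t[at_t["condition"] == "control"]
            trt = at_t[at_t["condition"] != "control"]
            entry["tail_dna_comparison"] = compare_groups(
                trt["tail_dna_pct"], ctrl["tail_dna_pct"], "mann_whitney"
            )
            entry["otm_comparison"] = compare_groups(
                trt["otm"], ctrl["otm"], "mann_whitney"
            )
        out["per_time"][f"{t:g}"] = entry
    return out


def derive_schedule(cbmn_summary: dict, t_final: float = 72.0) -> RISchedule:
    """Turn measured RI deficits into a piecewise exposure schedule.

    The window (0, t1] takes the first time point's deficit, each
    subsequent window (t_i, t_{i+1}] the next; deficits are rounded to 3
    decimals and clamped to [0, 1].
    """
    per_time = cbmn_summary["per_time"]
    times = sorted(float(t) for t in per_time if "ri_deficit" in per_time[f"{float(t):g}"])
    if not times:
        return RISchedule.null(t_final)
    segments = []
    prev = 0.0
    for t in times:
        d = per_time[f"{t:g}"]["ri_deficit"]
        d = min(1.0, max(0.0, round(d, 3)))
        segments.append((prev, t, d))
        prev = t
    if prev < t_final:
        segments.append((prev, t_final, segments[-1][2]))
    return RISchedule(segments)


def analyze_tables(
    viability: pd.DataFrame | None,
    cbmn: Sequence[MNScoreRecord] | None,
    comet: Sequence[CometCellRecord] | None,
    config: PipelineConfig,
) -> StudyReport:
    """Run the analysis on in-memory tables (the library-level pipeline)."""
    report = StudyReport(cell_line=config.cell_line)
    control_means = None

    if viability is not None:
        via = _analyze_viability(viability, config.cell_line)
        control_means = via.pop("_control_means")
        report.viability = via
        log.info("viability: %d rows analysed", len(viability))
    else:
        report.sections_absent.append("viability")

    if cbmn is not None:
        report.cbmn = _analyze_cbmn(cbmn, config.cell_line)
        log.info("cbmn: %d records analysed", len(cbmn))
    else:
        report.sections_absent.append("cbmn")

    if comet is not None:
        report.comet = _analyze_comet(comet, config.cell_line)
        log.info("comet: %d cells analysed", len(comet))
    else:
        report.sections_absent.append("comet")

    if config.fit_growth_model and control_means is not None:
        t0_mean = control_means.iloc[0]
        norm = control_means / t0_mean
        obs = GrowthTrajectory(
            norm.index.to_numpy(dtype=float), norm.to_numpy(dtype=float)
        )
        t_final = float(obs.times[-1])
        fit = fit_lgm(
            obs,
            scenario=config.scenario,
            bounds=config.bounds,
            seed=config.seed,
        )
        report.growth_fit = fit
        grid = np.linspace(0.0, t_final, int(t_final) + 1)
        report.control_trajectory = solve_lgm(fit.params, grid)
        schedule = (
            derive_schedule(report.cbmn, t_final)
            if report.cbmn
            else RISchedule.null(t_final)
        )
        report.ri_schedule = schedule
        report.treated_trajectory = simulate_treated(fit.params, schedule, grid)
        log.info(
            "growth model fitted (scenario=%s, rss=%.3g); schedule %s",
            config.scenario, fit.residual_sum_of_squares, schedule.segments,
        )
    elif config.fit_growth_model:
        report.sections_absent.append("growth_fit")

    report.provenance = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "software_version": __version__,
    }
    return report


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Run the full analysis from files on disk.

    Missing optional inputs produce a partial report with the section
    marked absent; a missing control viability series aborts.  Outputs
    (report JSON and trajectory CSVs) are written to ``config.out_dir``
    when given.
    """
    viability = (
        read_viability(config.viability_path) if config.viability_path else None
    )
    cbmn = read_cbmn(config.cbmn_path) if config.cbmn_path else None
    comet = read_comet(config.comet_path) if config.comet_path else None
    report = analyze_tables(viability, cbmn, comet, config)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.json")
        from .io import write_trajectory_csv

        if report.control_trajectory is not None:
            write_trajectory_csv(
                report.control_trajectory, out / "control_trajectory.csv"
            )
        if report.treated_trajectory is not None:
            write_trajectory_csv(
                report.treated_trajectory, out / "treated_trajectory.csv"
            )
    return report
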