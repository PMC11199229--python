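"""End-to-end orchestration: simulate -> preprocess -> cluster -> backfit ->
behave -> stats, as a configured, logged, reproducible run.

A run is described by a :class:`RunConfig` (constructible from a YAML
document with per-stage sections), executed by :func:`run_analysis` into a
run directory containing metric tables, correlation matrices, a power
report, and a provenance log (package version, config hash, per-stage
timings and row counts). :func:`make_report` renders the directory into a
human-readable markdown summary with the commonality table and banded
correlation matrices.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .backfit import backfit, metrics_table, segment_stats, widen_metrics
from .behave import load_trials_csv, summarize_cohort
from .cluster import (
    MicrostateSet,
    commonality,
    grand_average,
    load_template_set,
    modified_kmeans,
    peak_topographies,
)
from .eegio import bandpass, read_recording, segment_conditions
from .simulate import SimulationConfig, generate_cohort
from .stats import correlation_matrix, correlation_power, r_squared, subgroup

__all__ = ["RunConfig", "run_analysis", "make_report", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one analysis run depends on."""

    # simulation (used when no input recordings are given)
    simulate: dict[str, Any] = field(
        default_factory=lambda: {"n_participants": 8, "planted_r": 0.4, "render": True}
    )
    # input mode: explicit paths override simulation
    recordings: list[str] = field(default_factory=list)
    behaviour_csv: str | None = None
    template_csv: str | None = None

    condition: str = "both"  # EC | EO | both
    bandpass_low: float = 2.0
    bandpass_high: float = 20.0
    trim: float = 2.0

    k: int = 7
    restarts: int = 5
    max_iter: int = 200
    tol: float = 1e-6
    backfit_source: str = "grand"  # subject | grand | template

    subgroup_max_age: float = 40.0
    power_cases: list[dict[str, Any]] = field(
        default_factory=lambda: [
            {"rho": 0.403, "n": 36, "alpha": 0.05, "tails": 2},
            {"rho": 0.403, "n": 36, "alpha": 0.05, "tails": 1},
            {"rho": 0.277, "n": 36, "alpha": 0.05, "tails": 2},
            {"rho": 0.277, "n": 36, "alpha": 0.05, "tails": 1},
        ]
    )

    seed: int = 0
    output_dir: str = "runs/run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def conditions(self) -> list[str]:
        if self.condition == "both":
            return ["EC", "EO"]
        if self.condition in ("EC", "EO"):
            return [self.condition]
        raise ValueError(f"condition must be EC, EO or both, not {self.condition!r}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(log: list[dict], name: str, started: float, **counts) -> None:
    log.append({"stage": name, "seconds": round(time.perf_counter() - started, 3), **counts})


def run_analysis(config: RunConfig) -> Path:
    """Execute the full pipeline and write the run directory.

    Deterministic given the config (which includes the seed). Any stage
    failure aborts with :class:`StageError`; a marker file flags the run
    directory as invalid so partial outputs are never mistaken for results.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    invalid_marker = out / "INVALID"
    invalid_marker.write_text("run in progress")
    log: list[dict] = []
    conditions = config.conditions()
    try:
        _run_stages(config, out, log, conditions)
    except Exception as exc:
        invalid_marker.write_text(f"run failed: {exc}")
        if isinstance(exc, StageError):
            raise
        raise StageError("unknown", str(exc)) from exc
    invalid_marker.unlink()
    make_report(out)
    return out


def _run_stages(config: RunConfig, out: Path, log: list[dict], conditions: list[str]) -> None:
    # ---- acquire data -----------------------------------------------------
    t0 = time.perf_counter()
    planted: MicrostateSet | None = None
    if config.recordings:
        recordings = [read_recording(p) for p in config.recordings]
        if config.behaviour_csv is None:
            raise StageError("input", "recordings given without a behaviour CSV")
        trials = load_trials_csv(config.behaviour_csv)
        behaviour = summarize_cohort(trials)
        pids = [f"P{i:03d}" for i in range(len(recordings))]
    else:
        sim = dict(config.simulate)
        n_participants = int(sim.pop("n_participants", 8))
        planted_r = float(sim.pop("planted_r", 0.0))
        render = bool(sim.pop("render", True))
        if not render:
            raise StageError("simulate", "the pipeline needs rendered EEG (render=true)")
        sim_config = SimulationConfig(**sim, seed=config.seed)
        cohort = generate_cohort(
            n_participants, planted_r, sim_config, seed=config.seed, render=True
        )
        recordings = cohort.recordings
        behaviour = cohort.behaviour_summary
        planted = cohort.maps
        pids = list(behaviour["participant"])
    _stage(log, "acquire", t0, participants=len(recordings))

    # ---- preprocess + segment --------------------------------------------
    t0 = time.perf_counter()
    datasets = []
    for rec in recordings:
        filtered = bandpass(rec, config.bandpass_low, config.bandpass_high)
        datasets.append(segment_conditions(filtered, trim=config.trim, conditions=conditions))
    n_blocks = sum(len(d[c].blocks) for d in datasets for c in conditions)
    _stage(log, "preprocess", t0, blocks=n_blocks)

    # ---- subject-level clustering + grand average -------------------------
    t0 = time.perf_counter()
    subject_sets: dict[str, list] = {c: [] for c in conditions}
    n_peaks = 0
    for i, per_cond in enumerate(datasets):
        for cond in conditions:
            peaks = peak_topographies(per_cond[cond])
            n_peaks += len(peaks)
            fit = modified_kmeans(
                peaks,
                config.k,
                restarts=config.restarts,
                max_iter=config.max_iter,
                tol=config.tol,
                seed=config.seed + 1000 + i,
            )
            subject_sets[cond].append(fit.set)
    grand = {c: grand_average(subject_sets[c]) for c in conditions}
    _stage(log, "cluster", t0, peaks=n_peaks)

    # ---- map source for backfitting ---------------------------------------
    if config.backfit_source == "template":
        template = (
            MicrostateSet.from_csv(config.template_csv)
            if config.template_csv
            else load_template_set()
        )
        fit_maps = {c: template for c in conditions}
    elif config.backfit_source == "grand":
        fit_maps = grand
    elif config.backfit_source == "subject":
        fit_maps = None  # per-subject below
    else:
        raise StageError("backfit", f"unknown backfit_source {config.backfit_source!r}")

    # commonality of every grand-averaged set against the reference maps
    reference = planted if planted is not None else load_template_set()
    commonality_rows = []
    for cond in conditions:
        try:
            values, mean, sd = commonality(grand[cond], reference)
        except ValueError:
            break  # montage mismatch with packaged template: skip table
        row = {"condition": cond, **{c: v for c, v in values.items()}}
        row["mean"], row["sd"] = mean, sd
        commonality_rows.append(row)

    # ---- backfit + metrics -------------------------------------------------
    t0 = time.perf_counter()
    cohort_labels: dict[str, dict] = {}
    for i, per_cond in enumerate(datasets):
        cohort_labels[pids[i]] = {}
        for cond in conditions:
            maps = subject_sets[cond][i] if fit_maps is None else fit_maps[cond]
            cohort_labels[pids[i]][cond] = backfit(per_cond[cond], maps)
    tidy = metrics_table(cohort_labels, conditions)
    _stage(log, "backfit", t0, rows=len(tidy))

    # ---- statistics --------------------------------------------------------
    t0 = time.perf_counter()
    corr_tables = {}
    sub_tables = {}
    for cond in conditions:
        wide = widen_metrics(tidy, cond)
        corr_tables[cond] = correlation_matrix(behaviour, wide)
        if "age" in behaviour.columns:
            sub_tables[cond], excluded = subgroup(
                behaviour, wide, max_age=config.subgroup_max_age
            )
            sub_tables[cond].attrs["excluded"] = excluded
    power_report = []
    for case in config.power_cases:
        res = correlation_power(**case)
        power_report.append(
            {
                **case,
                "power": round(res.power, 4),
                "rho_squared": round(r_squared(case["rho"]), 4),
                "r_critical": res.r_critical,
            }
        )
    _stage(log, "stats", t0, cells=sum(len(t) for t in corr_tables.values()))

    # ---- write artefacts ---------------------------------------------------
    behaviour.to_csv(out / "behaviour_summary.csv", index=False)
    tidy.to_csv(out / "metrics_tidy.csv", index=False)
    for cond in conditions:
        widen_metrics(tidy, cond).to_csv(out / f"metrics_wide_{cond}.csv")
        corr_tables[cond].to_csv(out / f"correlations_{cond}.csv", index=False)
        if cond in sub_tables:
            sub_tables[cond].to_csv(out / f"correlations_subgroup_{cond}.csv", index=False)
        grand[cond].to_csv(out / f"grand_average_maps_{cond}.csv")
    if commonality_rows:
        pd.DataFrame(commonality_rows).to_csv(out / "commonality.csv", index=False)
    (out / "power.json").write_text(json.dumps(power_report, indent=1))
    provenance = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "conditions": conditions,
        "stages": log,
        "config": asdict(config),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, default=str))


def make_report(run_dir: str | Path) -> Path:
    """Render a run directory into ``report.md``.

    Regeneration is idempotent: the report is a pure function of the run
    artefacts. An incomplete run yields a partial report with explicit gaps.
    """
    run_dir = Path(run_dir)
    lines = ["# Microstate analysis report", ""]
    prov_path = run_dir / "provenance.json"
    if prov_path.exists():
        prov = json.loads(prov_path.read_text())
        lines += [
            f"Package version {prov['package_version']}, config hash "
            f"`{prov['config_hash']}`, seed {prov['seed']}.",
            "",
        ]
    if (run_dir / "INVALID").exists():
        lines += ["**WARNING: this run is marked invalid (failed or in progress).**", ""]

    comm_path = run_dir / "commonality.csv"
    lines += ["## Commonality against reference maps", ""]
    if comm_path.exists():
        frame = pd.read_csv(comm_path)
        cols = [c for c in frame.columns if c not in ("condition", "mean", "sd")]
        header = "| condition | " + " | ".join(cols) + " | mu +/- sigma |"
        lines += [header, "|" + "---|" * (len(cols) + 2)]
        for row in frame.itertuples(index=False):
            vals = " | ".join(f"{getattr(row, f'_{i + 1}'):.3f}" for i in range(len(cols)))
            lines.append(
                f"| {row.condition} | {vals} | {row.mean:.2f} +/- {row.sd:.2f} |"
            )
        lines.append("")
    else:
        lines += ["_Not available for this run._", ""]

    for cond in ("EC", "EO"):
        path = run_dir / f"correlations_{cond}.csv"
        if not path.exists():
            continue
        frame = pd.read_csv(path)
        lines += [f"## Correlations ({cond})", ""]
        lines += ["| behaviour | metric | r | p | band |", "|---|---|---|---|---|"]
        for row in frame.itertuples(index=False):
            shown = "" if row.band == "blank" else f"{row.r:.3f}"
            box = {"p<=.05": "full", ".05<p<=.10": "dotted", "blank": ""}[row.band]
            lines.append(f"| {row.behaviour} | {row.metric} | {shown} | {row.p:.3f} | {box} |")
        lines.append("")

    power_path = run_dir / "power.json"
    lines += ["## Power appendix", ""]
    if power_path.exists():
        for case in json.loads(power_path.read_text()):
            lines.append(
                f"- rho = {case['rho']}, n = {case['n']}, alpha = {case['alpha']}, "
                f"{case['tails']}-tailed: power = {case['power']:.4f} "
                f"(rho^2 = {case['rho_squared']:.4f})"
            )
        lines.append("")
    else:
        lines += ["_No power cases configured._", ""]

    report = run_dir / "report.md"
    report.write_text("\n".join(lines))
    return report
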