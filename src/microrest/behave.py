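"""Behavioural metrics from joystick / boat logs.

Two metrics summarise performance in the steering task:

Completion Time (CT)
    elapsed seconds from task start to the finish event; lower is better.
Movement Variability (MV)
    standard deviation (sample, n-1) of the joystick vertical-axis rotation
    angle theta_z over the trial, in degrees; low variability indicates
    automatic, externally focused control.

Logs arrive as delimited tables at a nominal 50 Hz; timestamps are linearly
resampled onto an exact uniform grid before any statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BehaviourTrial",
    "resample_linear",
    "completion_time",
    "movement_variability",
    "summarize",
    "load_trials_csv",
]


@dataclass
class BehaviourTrial:
    """One run of the motor task for one participant."""

    t: np.ndarray  # seconds, strictly increasing
    theta_z: np.ndarray  # joystick rotation, degrees
    pos: np.ndarray | None = None  # optional (n, 2) boat position
    finish_time: float | None = None  # absolute time of the finish event
    run: int = 1
    participant: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.theta_z = np.asarray(self.theta_z, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.theta_z.shape:
            raise ValueError("t and theta_z must be equal-length vectors")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.theta_z)):
            raise ValueError("theta_z contains non-finite values")
        if self.finish_time is not None and self.finish_time > self.t[-1] + 1e-9:
            raise ValueError("finish event lies beyond the recorded samples")


def resample_linear(trial: BehaviourTrial, rate: float = 50.0) -> BehaviourTrial:
    """Linearly resample a trial onto a uniform grid spanning [t0, t_end].

    The grid steps at exactly ``1/rate`` from the first timestamp; the final
    original timestamp is appended when the grid does not land on it, so
    both endpoints are preserved. Already-uniform input at the target rate
    is returned unchanged (idempotence).
    """
    if trial.t.size < 2:
        raise ValueError("resampling needs at least 2 samples")
    step = 1.0 / rate
    span = trial.t[-1] - trial.t[0]
    n_steps = int(np.floor(span / step + 1e-9))
    grid = trial.t[0] + step * np.arange(n_steps + 1)
    if grid[-1] < trial.t[-1] - 1e-9:
        grid = np.append(grid, trial.t[-1])
    if grid.size == trial.t.size and np.allclose(grid, trial.t, atol=1e-12):
        return trial
    theta = np.interp(grid, trial.t, trial.theta_z)
    pos = None
    if trial.pos is not None:
        pos = np.column_stack(
            [np.interp(grid, trial.t, trial.pos[:, j]) for j in range(trial.pos.shape[1])]
        )
    return replace(trial, t=grid, theta_z=theta, pos=pos)


def completion_time(trial: BehaviourTrial) -> float:
    """CT in seconds: finish event time minus task start time."""
    if trial.finish_time is None:
        raise ValueError(f"trial {trial.participant}/run {trial.run} has no finish event")
    return float(trial.finish_time - trial.t[0])


def movement_variability(trial: BehaviourTrial, rate: float = 50.0, ddof: int = 1) -> float:
    """MV in degrees: standard deviation of theta_z after resampling.

    Sample convention (n-1) by default; a constant signal yields 0.
    """
    resampled = resample_linear(trial, rate)
    if resampled.theta_z.size < 2:
        raise ValueError("movement variability needs at least 2 samples")
    return float(np.std(resampled.theta_z, ddof=ddof))


def summarize(
    trials: Sequence[BehaviourTrial], participant: str | None = None
) -> dict[str, float | str | int | None]:
    """Participant-level CT and MV, averaged over completed runs.

    Runs without a finish event are incomplete and are skipped; a
    participant with no completed run is flagged missing (NaN metrics)
    rather than raising, so cohort tables keep the row.
    """
    completed = [tr for tr in trials if tr.finish_time is not None]
    pid = participant if participant is not None else (trials[0].participant if trials else "")
    if not completed:
        return {"participant": pid, "CT": np.nan, "MV": np.nan, "n_runs": 0, "missing": True}
    cts = [completion_time(tr) for tr in completed]
    mvs = [movement_variability(tr) for tr in completed]
    return {
        "participant": pid,
        "CT": float(np.mean(cts)),
        "MV": float(np.mean(mvs)),
        "n_runs": len(completed),
        "missing": False,
    }


def load_trials_csv(path: str | Path | pd.DataFrame) -> list[BehaviourTrial]:
    """Parse the trial-log CSV dialect into BehaviourTrial objects.

    Expected columns: participant_id, run, t, theta_z, pos_x, pos_y,
    finished (0/1; the first rising edge marks the finish event).
    """
    frame = path if isinstance(path, pd.DataFrame) else pd.read_csv(path)
    trials = []
    for (pid, run), grp in frame.groupby(["participant_id", "run"], sort=True):
        grp = grp.sort_values("t")
        finished = grp["finished"].to_numpy()
        finish_time = None
        hits = np.flatnonzero(finished > 0)
        if hits.size:
            finish_time = float(grp["t"].to_numpy()[hits[0]])
        pos = None
        if {"pos_x", "pos_y"} <= set(grp.columns):
            pos = grp[["pos_x", "pos_y"]].to_numpy(dtype=float)
        trials.append(
            BehaviourTrial(
                grp["t"].to_numpy(dtype=float),
                grp["theta_z"].to_numpy(dtype=float),
                pos=pos,
                finish_time=finish_time,
                run=int(run),
                participant=str(pid),
            )
        )
    return trials


def summarize_cohort(trials: Sequence[BehaviourTrial]) -> pd.DataFrame:
    """Summaries for every participant present in a list of trials."""
    by_pid: dict[str, list[BehaviourTrial]] = {}
    for tr in trials:
        by_pid.setdefault(tr.participant, []).append(tr)
    return pd.DataFrame([summarize(v, k) for k, v in sorted(by_pid.items())])
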