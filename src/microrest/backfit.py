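"""Backfitting template maps onto EEG and temporal microstate metrics.

Backfitting assigns every sample of a condition dataset to the template map
with the largest absolute spatial correlation (winner-takes-all, polarity
invariant), independently within each block. From the resulting label
sequence three metrics are computed per class and condition:

Duration
    mean length of the class's segments, in seconds; a segment is a maximal
    run of one class within one block (runs never span block boundaries).
Occurrence
    number of segments of the class in the condition (a raw count, not a
    rate).
Contribution
    percentage of the condition's samples labelled with the class, a.k.a.
    coverage. Contributions sum to 100% and satisfy
    ``Contribution = 100 * Occurrence * Duration / T`` with T the effective
    condition length.

With the canonical seven classes this yields the 21-metric feature vector
per participant and condition used by the correlational analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import MicrostateSet
from .eegio import ConditionDataset, average_reference

__all__ = ["LabelSequence", "backfit", "segment_stats", "metrics_table", "widen_metrics"]

METRICS = ("duration", "occurrence", "contribution")


@dataclass
class LabelSequence:
    """Per-sample class assignment of one condition, block by block."""

    blocks: list[np.ndarray]  # int arrays, one per block
    sampling_rate: float
    n_classes: int
    condition: str = ""

    def __post_init__(self) -> None:
        self.blocks = [np.asarray(b, dtype=int) for b in self.blocks]
        if not self.blocks or any(b.size == 0 for b in self.blocks):
            raise ValueError("label sequence needs at least one non-empty block")
        hi = max(int(b.max()) for b in self.blocks)
        lo = min(int(b.min()) for b in self.blocks)
        if lo < 0 or hi >= self.n_classes:
            raise ValueError("label outside [0, n_classes)")

    @property
    def n_samples(self) -> int:
        return sum(b.size for b in self.blocks)

    @property
    def total_duration(self) -> float:
        return self.n_samples / self.sampling_rate

    # -- run-length-encoded JSON -------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "sampling_rate": self.sampling_rate,
            "n_classes": self.n_classes,
            "condition": self.condition,
            "blocks": [
                [[int(c), int(n)] for c, n in zip(*_rle(b))] for b in self.blocks
            ],
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "LabelSequence":
        payload = json.loads(Path(path).read_text())
        blocks = [
            np.repeat([c for c, _ in runs], [n for _, n in runs]) for runs in payload["blocks"]
        ]
        return cls(blocks, payload["sampling_rate"], payload["n_classes"], payload["condition"])


def _rle(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode: (values, lengths)."""
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return labels[starts], ends - starts


# ---------------------------------------------------------------------------
# backfitting
# ---------------------------------------------------------------------------

def backfit(dataset: ConditionDataset, microstates: MicrostateSet) -> LabelSequence:
    """Label every sample with its best-correlating template map.

    Each sample topography is average-referenced and assigned to the class
    maximising the absolute spatial correlation with the template; ties
    break to the lowest class index (argmax convention). Flat (zero
    variance) samples carry no topography and inherit the label of the
    nearest non-flat sample within the same block; an entirely flat block is
    an error.
    """
    if dataset.n_channels != microstates.n_channels:
        raise ValueError("montage mismatch between dataset and template maps")
    labelled: list[np.ndarray] = []
    for bi, block in enumerate(dataset.blocks):
        x = average_reference(block)  # channels x samples
        norms = np.linalg.norm(x, axis=0)
        # |corr| proportional to |m . v| / ||v||; the norm is constant per
        # sample, so argmax over classes needs only |m . v|
        scores = np.abs(microstates.maps @ x)
        labels = np.argmax(scores, axis=0)
        flat = norms == 0
        if flat.all():
            raise ValueError(f"block {bi}: every sample is flat, cannot backfit")
        if flat.any():
            idx = np.arange(labels.size)
            good = idx[~flat]
            nearest = good[np.argmin(np.abs(idx[:, None] - good[None, :]), axis=1)]
            labels = labels[nearest]
        labelled.append(labels)
    return LabelSequence(labelled, dataset.sampling_rate, microstates.k, dataset.condition)


# ---------------------------------------------------------------------------
# temporal metrics
# ---------------------------------------------------------------------------

def segment_stats(label_sequence: LabelSequence) -> pd.DataFrame:
    """Per-class Duration, Occurrence and Contribution of one condition.

    Returns a DataFrame indexed by class (0..k-1) with columns
    ``duration`` (s), ``occurrence`` (count), ``contribution`` (%), and
    ``absent`` (True when the class never appears; its duration is then
    reported as 0 rather than NaN). The effective condition length and
    condition label are stored in ``DataFrame.attrs``.
    """
    k = label_sequence.n_classes
    fs = label_sequence.sampling_rate
    seg_count = np.zeros(k, dtype=int)
    seg_samples = np.zeros(k, dtype=float)
    for block in label_sequence.blocks:
        values, lengths = _rle(block)
        np.add.at(seg_count, values, 1)
        np.add.at(seg_samples, values, lengths)
    total = float(sum(b.size for b in label_sequence.blocks))
    present = seg_count > 0
    duration = np.zeros(k)
    duration[present] = seg_samples[present] / seg_count[present] / fs
    stats = pd.DataFrame(
        {
            "duration": duration,
            "occurrence": seg_count,
            "contribution": 100.0 * seg_samples / total,
            "absent": ~present,
        },
        index=pd.RangeIndex(k, name="class"),
    )
    stats.attrs["condition"] = label_sequence.condition
    stats.attrs["T"] = total / fs
    return stats


def metrics_table(
    cohort_labels: Mapping[str, Mapping[str, LabelSequence]],
    conditions: Sequence[str] = ("EC", "EO"),
) -> pd.DataFrame:
    """Tidy per-participant metric table across conditions.

    ``cohort_labels`` maps participant id -> condition -> label sequence.
    Output columns: participant, condition, class, metric, value, absent.
    A participant missing a condition contributes rows with ``absent=True``
    and NaN values for that condition rather than being dropped silently.
    """
    rows = []
    for pid, per_cond in cohort_labels.items():
        k = max(ls.n_classes for ls in per_cond.values())
        for cond in conditions:
            if cond not in per_cond:
                for cls in range(k):
                    for metric in METRICS:
                        rows.append(
                            {
                                "participant": pid,
                                "condition": cond,
                                "class": cls,
                                "metric": metric,
                                "value": np.nan,
                                "absent": True,
                            }
                        )
                continue
            stats = segment_stats(per_cond[cond])
            for cls in range(len(stats)):
                for metric in METRICS:
                    rows.append(
                        {
                            "participant": pid,
                            "condition": cond,
                            "class": cls,
                            "metric": metric,
                            "value": float(stats.loc[cls, metric]),
                            "absent": bool(stats.loc[cls, "absent"]),
                        }
                    )
    return pd.DataFrame(rows)


def widen_metrics(tidy: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Wide export of one condition: participants x (metric, class) columns.

    With seven classes this is the participants x 21 feature matrix used by
    the correlation analyses; columns are named ``metric_class`` such as
    ``contribution_3``.
    """
    sub = tidy[tidy.condition == condition]
    wide = sub.pivot_table(
        index="participant", columns=["metric", "class"], values="value", dropna=False
    )
    wide.columns = [f"{metric}_{cls}" for metric, cls in wide.columns]
    return wide
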