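"""EEG containers, I/O, filtering, condition segmentation, and global field power.

The central object is :class:`EEGRecording`: a channels x samples matrix in
microvolts with a sampling rate, channel labels, and a list of condition
events marking the onsets of eyes-closed (EC) / eyes-open (EO) resting blocks.
Recordings round-trip losslessly through HDF5 or a delimited matrix with a
JSON sidecar.

Processing follows the conventional resting-state microstate front end:
zero-phase band-pass filtering (2-20 Hz by default), average referencing,
trimming 2 s from both edges of every 30 s block, and per-block computation
of global field power (GFP) and its peaks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "EEGRecording",
    "ConditionDataset",
    "read_recording",
    "write_recording",
    "bandpass",
    "downsample",
    "average_reference",
    "segment_conditions",
    "gfp",
    "gfp_peaks",
]

CONDITIONS = ("EC", "EO")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EEGRecording:
    """Multichannel EEG with events.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    sampling_rate : float
        Samples per second, > 0.
    channel_labels : list of str
        One label per channel.
    events : list of (int, str)
        ``(onset_sample, condition_label)`` pairs, onsets strictly
        increasing and inside the record; labels are ``"EC"`` or ``"EO"``.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if self.data.shape[0] < 2:
            raise ValueError("a recording needs at least 2 channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length does not match data rows")
        self.events = [(int(s), str(lab)) for s, lab in self.events]
        onsets = [s for s, _ in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        if onsets and (onsets[0] < 0 or onsets[-1] >= self.n_samples):
            raise ValueError("event onset outside the record")
        for _, lab in self.events:
            if lab not in CONDITIONS:
                raise ValueError(f"unknown event label {lab!r} (expected EC/EO)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class ConditionDataset:
    """Trimmed, concatenated blocks of one resting condition.

    Block boundaries are preserved: every per-block array is stored
    separately so that no temporal statistic ever spans the discontinuity
    between two blocks.
    """

    condition: str
    blocks: list[np.ndarray]
    sampling_rate: float

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"condition {self.condition}: no blocks")
        n_ch = {b.shape[0] for b in self.blocks}
        if len(n_ch) != 1:
            raise ValueError("blocks disagree on channel count")

    @property
    def n_channels(self) -> int:
        return self.blocks[0].shape[0]

    @property
    def n_samples(self) -> int:
        return sum(b.shape[1] for b in self.blocks)

    @property
    def total_duration(self) -> float:
        """Effective condition length T in seconds (sum of block lengths)."""
        return self.n_samples / self.sampling_rate

    @property
    def block_lengths(self) -> list[int]:
        return [b.shape[1] for b in self.blocks]

    def concatenated(self) -> np.ndarray:
        """All blocks side by side; use block_lengths to recover boundaries."""
        return np.concatenate(self.blocks, axis=1)


# ---------------------------------------------------------------------------
# I/O: HDF5 or delimited matrix + JSON sidecar
# ---------------------------------------------------------------------------

def write_recording(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording to ``.h5``/``.hdf5`` or ``.csv`` (+ ``.json`` sidecar).

    The delimited form stores the channels x samples matrix with one row per
    channel; sampling rate, labels, and events go to ``<stem>.json``.
    Round trips are lossless (float64 end to end).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            dset = f.create_dataset("data", data=rec.data)
            dset.attrs["sampling_rate"] = rec.sampling_rate
            dset.attrs["channel_labels"] = [str(c) for c in rec.channel_labels]
            if rec.events:
                f.create_dataset(
                    "event_onsets", data=np.array([s for s, _ in rec.events], dtype=np.int64)
                )
                f.create_dataset(
                    "event_labels",
                    data=np.array([lab for _, lab in rec.events], dtype="S8"),
                )
    elif suffix == ".csv":
        pd.DataFrame(rec.data, index=rec.channel_labels).to_csv(path, header=False, float_format="%.17g")
        sidecar = {
            "sampling_rate": rec.sampling_rate,
            "channel_labels": list(rec.channel_labels),
            "events": [[s, lab] for s, lab in rec.events],
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValueError(f"unknown recording format {suffix!r} (use .h5 or .csv)")
    return path


def read_recording(path: str | Path) -> EEGRecording:
    """Read a recording written by :func:`write_recording`.

    ``.edf`` and EEGLAB ``.set`` files are imported best-effort through
    :mod:`mne` when it is installed; events are not recovered from those
    formats and must be supplied separately.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            dset = f["data"]
            data = dset[()]
            rate = float(dset.attrs["sampling_rate"])
            labels = [str(c) for c in dset.attrs["channel_labels"]]
            events: list[tuple[int, str]] = []
            if "event_onsets" in f:
                onsets = f["event_onsets"][()]
                labs = [b.decode() for b in f["event_labels"][()]]
                events = list(zip((int(s) for s in onsets), labs))
        return EEGRecording(data, rate, labels, events)
    if suffix == ".csv":
        frame = pd.read_csv(path, header=None, index_col=0, float_precision="round_trip")
        sidecar = json.loads(path.with_suffix(".json").read_text())
        events = [(int(s), str(lab)) for s, lab in sidecar.get("events", [])]
        return EEGRecording(
            frame.to_numpy(dtype=float),
            float(sidecar["sampling_rate"]),
            [str(c) for c in sidecar["channel_labels"]],
            events,
        )
    if suffix in (".edf", ".set"):
        return _read_interchange(path, suffix)
    raise ValueError(f"unknown recording format {suffix!r}")


def _read_interchange(path: Path, suffix: str) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF/SET import requires the optional mne dependency") from exc
    if suffix == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_eeglab(path, preload=True, verbose="error")
    return EEGRecording(
        raw.get_data() * 1e6,  # mne returns volts
        float(raw.info["sfreq"]),
        list(raw.ch_names),
        [],
    )


def read_events_csv(path: str | Path) -> list[tuple[int, str]]:
    """Read events from a two-column CSV ``onset_sample,label``."""
    frame = pd.read_csv(path)
    return [(int(r.onset_sample), str(r.label)) for r in frame.itertuples()]


# ---------------------------------------------------------------------------
# filtering / referencing
# ---------------------------------------------------------------------------

def bandpass(rec: EEGRecording, low: float = 2.0, high: float = 20.0, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass.

    Forward-backward second-order sections, so the effective attenuation is
    twice the design order and the phase response is exactly zero. Defaults
    follow the conventional microstate band of 2-20 Hz.
    """
    nyquist = rec.sampling_rate / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyquist:
        raise ValueError(f"high cut-off {high} Hz >= Nyquist {nyquist} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered)


def downsample(rec: EEGRecording, factor: int) -> EEGRecording:
    """Integer decimation after an anti-alias (order-8 Chebyshev) filter.

    Event onsets are mapped to the nearest surviving sample. Used to bring
    e.g. 1000 Hz acquisitions down to the 250 Hz analysis rate.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("decimation factor must be a positive integer")
    if factor == 1:
        return rec
    data = sps.decimate(rec.data, int(factor), axis=1, zero_phase=True)
    events = [(int(round(s / factor)), lab) for s, lab in rec.events]
    return EEGRecording(data, rec.sampling_rate / factor, list(rec.channel_labels), events)


def average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean across channels (common average)."""
    data = np.asarray(data, dtype=float)
    return data - data.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# condition segmentation
# ---------------------------------------------------------------------------

def segment_conditions(
    rec: EEGRecording, trim: float = 2.0, conditions: Sequence[str] = CONDITIONS
) -> dict[str, ConditionDataset]:
    """Split a recording into per-condition datasets with edge trimming.

    Events partition the record: each block runs from its onset to the next
    onset (or the end of the record). The first and last ``trim`` seconds of
    every block are dropped to keep only steady-state activity, so the
    default 30 s blocks each contribute 26 s. Under the default protocol of
    4 blocks per condition this yields T = 104 s effective per condition.
    """
    if not rec.events:
        raise ValueError("recording has no condition events")
    trim_samples = int(round(trim * rec.sampling_rate))
    onsets = [s for s, _ in rec.events] + [rec.n_samples]
    blocks: dict[str, list[np.ndarray]] = {c: [] for c in conditions}
    for i, (onset, label) in enumerate(rec.events):
        end = onsets[i + 1]
        if end - onset <= 2 * trim_samples:
            raise ValueError(
                f"block {i} ({label}, samples {onset}:{end}) shorter than twice the "
                f"{trim} s trim"
            )
        if label in blocks:
            blocks[label].append(rec.data[:, onset + trim_samples : end - trim_samples])
    out: dict[str, ConditionDataset] = {}
    for cond in conditions:
        if not blocks[cond]:
            raise ValueError(f"no {cond} events in recording")
        out[cond] = ConditionDataset(cond, blocks[cond], rec.sampling_rate)
    return out


# ---------------------------------------------------------------------------
# global field power
# ---------------------------------------------------------------------------

def gfp(data: np.ndarray | ConditionDataset, ddof: int = 0) -> np.ndarray | list[np.ndarray]:
    """Global field power: spatial standard deviation across channels.

    GFP(t) = std over channels of the instantaneous topography, computed
    after average referencing. The population convention (``ddof=0``) is the
    default in the microstate literature; data are re-referenced internally
    so an offset common to all channels never contributes.

    For a :class:`ConditionDataset` a list of per-block GFP series is
    returned; for an array (channels x samples, or a single channels vector)
    the GFP series or scalar.
    """
    if isinstance(data, ConditionDataset):
        return [gfp(b, ddof=ddof) for b in data.blocks]
    arr = np.asarray(data, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    if arr.shape[0] < 2:
        raise ValueError("GFP needs at least 2 channels")
    out = arr.std(axis=0, ddof=ddof)
    return float(out[0]) if squeeze else out


def gfp_peaks(gfp_series: np.ndarray | list[np.ndarray]) -> np.ndarray | list[np.ndarray]:
    """Strict local maxima of a GFP series.

    A peak is a sample strictly greater than both neighbours; block
    boundaries never hold peaks. Given a list of per-block series (the
    output of :func:`gfp` on a :class:`ConditionDataset`) each block is
    searched independently and a list of per-block index arrays is returned.
    """
    if isinstance(gfp_series, list):
        return [gfp_peaks(b) for b in gfp_series]
    series = np.asarray(gfp_series, dtype=float)
    peaks, _ = sps.find_peaks(series)
    return peaks
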