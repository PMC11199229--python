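"""Synthetic resting-state EEG cohorts with known microstate ground truth.

The generator emulates the structure a microstate analysis relies on without
any forward head model:

* a set of k planted template maps (zero-mean, unit-norm, mutually
  orthogonal topographies);
* a semi-Markov class sequence: segment durations drawn from a truncated
  Gamma distribution (mean 90 ms, sd 30 ms by default, matching the
  conventional 60-120 ms microstate duration range and 2-4 segments/s),
  successive segments always differing in class;
* per-sample topography equal to the active map scaled by a rectified
  sinusoidal envelope (10 Hz carrier) plus i.i.d. Gaussian sensor noise at a
  configurable signal-to-noise ratio, so global field power peaks occur
  twice per carrier cycle;
* an alternating eyes-open / eyes-closed protocol (default four 30 s blocks
  per condition).

At the cohort level, each participant receives individual class prevalences
(Dirichlet-distributed transition weights) and a behavioural record whose
completion time is a linear function of one designated class's realized
eyes-closed Contribution plus Gaussian noise calibrated to a planted
population correlation; movement variability is coupled analogously to a
second class. Ground-truth metrics are always computed by enumerating the
realized label sequence, never from the generating distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .backfit import LabelSequence, segment_stats
from .cluster import MicrostateSet
from .eegio import EEGRecording

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CohortResult",
    "make_templates",
    "sample_label_sequence",
    "render_eeg",
    "generate_cohort",
    "DEFAULT_BLOCK_PLAN",
]

#: alternating protocol: four (EO + EC) pairs of 30 s blocks
DEFAULT_BLOCK_PLAN: tuple[tuple[str, float], ...] = tuple(
    (cond, 30.0) for _ in range(4) for cond in ("EO", "EC")
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic EEG generator.

    ``snr`` is the ratio of signal RMS to noise RMS over the whole record;
    ``numpy.inf`` disables sensor noise entirely.
    """

    n_channels: int = 32
    sampling_rate: float = 250.0
    k_classes: int = 7
    block_plan: Sequence[tuple[str, float]] = DEFAULT_BLOCK_PLAN
    duration_mean_ms: float = 90.0
    duration_sd_ms: float = 30.0
    carrier_freq: float = 10.0
    carrier_phase: float = 0.3  # radians; keeps envelope zeros off the sample grid
    snr: float = np.inf
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.k_classes < 1:
            raise ValueError("k_classes must be >= 1")
        if not (self.snr > 0):  # also rejects NaN
            raise ValueError("snr must be positive (inf allowed)")
        mean_samples = self.duration_mean_ms / 1000.0 * self.sampling_rate
        if mean_samples <= 1:
            raise ValueError("mean segment duration must exceed one sample")
        shortest = min(d for _, d in self.block_plan)
        if self.duration_mean_ms / 1000.0 >= shortest:
            raise ValueError("mean segment duration must be below the block length")
        if self.duration_sd_ms <= 0:
            raise ValueError("duration_sd_ms must be positive")


@dataclass
class GroundTruth:
    """What the generator actually planted, per participant.

    ``stats`` holds per-condition DataFrames in the exact format of
    :func:`microrest.backfit.segment_stats`, computed from the realized
    label sequence so the metric identities hold by construction.
    """

    planted_maps: MicrostateSet
    label_sequences: dict[str, LabelSequence]
    stats: dict[str, pd.DataFrame]
    planted_behaviour_r: float = 0.0
    seed: int | None = None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "planted_maps": self.planted_maps.maps.tolist(),
            "planted_behaviour_r": self.planted_behaviour_r,
            "seed": self.seed,
            "stats": {
                cond: frame.reset_index().to_dict(orient="list")
                for cond, frame in self.stats.items()
            },
        }
        path.write_text(json.dumps(payload))
        return path


# ---------------------------------------------------------------------------
# planted template maps
# ---------------------------------------------------------------------------

def make_templates(n_channels: int, k: int, seed: int | None = None) -> MicrostateSet:
    """Draw k mutually orthogonal zero-mean unit-norm topographies.

    A random Gaussian basis is projected onto the average-reference subspace
    and orthonormalised, so pairwise spatial correlations are exactly zero
    (well within the near-orthogonality contract). Deterministic given the
    seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_channels - 1:
        raise ValueError(
            f"cannot fit {k} orthogonal average-referenced maps on {n_channels} channels "
            f"(the zero-mean subspace has dimension {n_channels - 1})"
        )
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_channels, k))
    raw -= raw.mean(axis=0, keepdims=True)  # project into zero-mean subspace
    q, r = np.linalg.qr(raw)
    q *= np.sign(np.diag(r))[None, :]  # deterministic orientation
    return MicrostateSet(q.T)


# ---------------------------------------------------------------------------
# semi-Markov label sequence
# ---------------------------------------------------------------------------

def _duration_batch(config: SimulationConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    """Segment durations in samples from the truncated Gamma family."""
    mean = config.duration_mean_ms / 1000.0
    sd = config.duration_sd_ms / 1000.0
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    dur = rng.gamma(shape, scale, size=size)
    return np.maximum(1, np.round(dur * config.sampling_rate)).astype(int)


def sample_label_sequence(
    config: SimulationConfig,
    class_weights: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[list[tuple[str, np.ndarray]], dict[str, LabelSequence]]:
    """Sample the piecewise-constant class sequence for the whole protocol.

    Returns ``(blocks, per_condition)`` where ``blocks`` lists
    ``(condition, labels)`` in protocol order and ``per_condition`` gathers
    the same label arrays into one :class:`LabelSequence` per condition.
    Successive segments always change class; the class entered at each
    transition is drawn from ``class_weights`` (uniform by default)
    renormalised over the k-1 other classes. Each block starts a fresh
    segment.
    """
    k = config.k_classes
    if class_weights is None:
        class_weights = np.full(k, 1.0 / k)
    class_weights = np.asarray(class_weights, dtype=float)
    if class_weights.shape != (k,) or np.any(class_weights < 0) or class_weights.sum() == 0:
        raise ValueError("class_weights must be k non-negative values, not all zero")
    class_weights = class_weights / class_weights.sum()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    # precompute, for every possible previous class (k = no previous), the
    # candidate classes and their cumulative weights, so each transition is a
    # single searchsorted on a pre-drawn uniform
    candidates, cumweights = [], []
    if k > 1:
        for prev in range(k + 1):
            cand = np.array([c for c in range(k) if c != prev], dtype=int)
            w = class_weights[cand]
            if w.sum() == 0:
                w = np.full(cand.size, 1.0)
            candidates.append(cand)
            cumweights.append(np.cumsum(w) / w.sum())

    mean_samples = config.duration_mean_ms / 1000.0 * config.sampling_rate

    blocks: list[tuple[str, np.ndarray]] = []
    for cond, block_s in config.block_plan:
        n = int(round(block_s * config.sampling_rate))
        if k == 1:
            blocks.append((cond, np.zeros(n, dtype=int)))  # one segment per block
            continue
        budget = int(n / mean_samples * 1.5) + 16
        durations = _duration_batch(config, rng, budget)
        uniforms = rng.random(budget)
        labels = np.empty(n, dtype=int)
        pos, i, current = 0, 0, k  # k = sentinel "no previous class"
        while pos < n:
            if i >= budget:
                durations = _duration_batch(config, rng, budget)
                uniforms = rng.random(budget)
                i = 0
            nxt = int(candidates[current][np.searchsorted(cumweights[current], uniforms[i])])
            end = min(pos + durations[i], n)
            labels[pos:end] = nxt
            current = nxt
            pos = end
            i += 1
        blocks.append((cond, labels))

    per_condition: dict[str, LabelSequence] = {}
    for cond in dict.fromkeys(c for c, _ in blocks):
        per_condition[cond] = LabelSequence(
            [lab for c, lab in blocks if c == cond], config.sampling_rate, k, cond
        )
    return blocks, per_condition


# ---------------------------------------------------------------------------
# EEG rendering
# ---------------------------------------------------------------------------

def render_eeg(
    blocks: Sequence[tuple[str, np.ndarray]],
    maps: MicrostateSet,
    config: SimulationConfig,
    seed: int | None = None,
) -> EEGRecording:
    """Render a label plan into a multichannel recording.

    At sample t with class c the topography is ``a(t) * map_c + noise``,
    with ``a(t)`` a rectified sinusoid at the carrier frequency (phase
    offset keeps its zeros between samples) and i.i.d. Gaussian noise scaled
    so that signal RMS / noise RMS equals ``config.snr``. Events mark each
    block onset.
    """
    k = max(int(lab.max()) for _, lab in blocks) + 1
    if k > maps.k:
        raise ValueError("label plan references more classes than the map set holds")
    fs = config.sampling_rate
    all_labels = np.concatenate([lab for _, lab in blocks])
    n = all_labels.size
    t = np.arange(n) / fs
    envelope = np.abs(np.sin(2 * np.pi * config.carrier_freq * t + config.carrier_phase))
    signal = maps.maps[all_labels].T * envelope[None, :]  # channels x samples

    rng = np.random.default_rng(seed if seed is not None else config.seed)
    if np.isfinite(config.snr):
        signal_rms = float(np.sqrt(np.mean(signal**2)))
        noise = rng.standard_normal(signal.shape) * (signal_rms / config.snr)
        signal = signal + noise

    events: list[tuple[int, str]] = []
    onset = 0
    for cond, lab in blocks:
        events.append((onset, cond))
        onset += lab.size
    return EEGRecording(signal, fs, events=events)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    """Everything :func:`generate_cohort` produced for one synthetic cohort."""

    maps: MicrostateSet
    recordings: list[EEGRecording | None]
    behaviour_trials: pd.DataFrame
    behaviour_summary: pd.DataFrame
    ground_truths: list[GroundTruth]
    config: SimulationConfig
    ct_class: int
    mv_class: int


def _couple(
    x: np.ndarray,
    r: float,
    base: float,
    slope: float,
    rng: np.random.Generator,
    population_sd: float | None = None,
) -> np.ndarray:
    """Linear response ``base + slope*(x - mean) + noise`` with population
    correlation ``r`` against x.

    The noise sd is calibrated against ``population_sd`` of x when given
    (estimated from an independent calibration draw, so the attained
    correlation is unbiased); the realized sample sd is the fallback.
    """
    x = np.asarray(x, dtype=float)
    sx = float(x.std(ddof=1)) if population_sd is None else float(population_sd)
    centred = x - x.mean()
    if r == 0.0:
        return base + rng.standard_normal(x.size) * abs(slope) * max(sx, 1e-12)
    if sx == 0 or float(x.std(ddof=1)) == 0:
        raise ValueError("degenerate design: zero variance in the coupled contribution")
    signed_slope = slope * np.sign(r)
    if abs(r) >= 1.0:
        return base + signed_slope * centred
    noise_sd = abs(slope) * sx * np.sqrt(1.0 / r**2 - 1.0)
    return base + signed_slope * centred + rng.standard_normal(x.size) * noise_sd


def generate_cohort(
    n_participants: int,
    planted_behaviour_r: float,
    config: SimulationConfig | None = None,
    seed: int | None = None,
    render: bool = True,
    trials: bool = True,
    ct_class: int = 2,
    mv_class: int = 3,
    mv_r: float | None = None,
    prevalence_concentration: float = 5.0,
) -> CohortResult:
    """Generate a full synthetic cohort with a planted brain-behaviour link.

    Completion time is coupled to the eyes-closed Contribution of
    ``ct_class`` (default class index 2, the "3/C" slot) at population
    correlation ``planted_behaviour_r``; movement variability is coupled to
    ``mv_class`` (default "4/D") at ``mv_r`` (defaults to the same planted
    value). Per-participant class prevalences are Dirichlet draws, so the
    coupled contributions vary across the cohort. With ``render=False`` the
    EEG matrices are skipped (entries are None) while label sequences,
    ground truth and behaviour stay identical — cohort-level statistics do
    not depend on the rendering stage.

    Behavioural logs are emitted both as a participant-level summary (CT,
    MV, age and experience covariates) and as 50 Hz joystick trial traces
    (two runs per participant, both realising the planted values exactly)
    from which the behavioural metrics can be recomputed.
    """
    if abs(planted_behaviour_r) > 1:
        raise ValueError("|planted_behaviour_r| must be <= 1")
    if n_participants < 3:
        raise ValueError("need at least 3 participants")
    config = config if config is not None else SimulationConfig()
    if mv_r is None:
        mv_r = planted_behaviour_r
    # keep the designated classes inside [0, k); defaults target the 3/C and
    # 4/D slots of a 7-class set but must degrade for smaller k
    k = config.k_classes
    ct_class = min(ct_class, k - 1)
    mv_class = min(mv_class, k - 1)
    if mv_class == ct_class and k > 1:
        mv_class = (ct_class - 1) % k
    root = np.random.SeedSequence(seed if seed is not None else config.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_participants + 3)]
    cohort_rng = np.random.default_rng(child_seeds[-1])
    calibration_rng = np.random.default_rng(child_seeds[-3])
    maps = make_templates(config.n_channels, config.k_classes, child_seeds[-2])

    recordings: list[EEGRecording | None] = []
    ground_truths: list[GroundTruth] = []
    for i in range(n_participants):
        prng = np.random.default_rng(child_seeds[i])
        weights = prng.dirichlet(np.full(config.k_classes, prevalence_concentration))
        blocks, per_cond = sample_label_sequence(config, weights, seed=child_seeds[i] + 1)
        stats = {cond: segment_stats(ls) for cond, ls in per_cond.items()}
        ground_truths.append(
            GroundTruth(maps, per_cond, stats, planted_behaviour_r, child_seeds[i])
        )
        recordings.append(
            render_eeg(blocks, maps, config, seed=child_seeds[i] + 2) if render else None
        )

    ec = "EC" if "EC" in ground_truths[0].stats else next(iter(ground_truths[0].stats))
    contrib_ct = np.array([g.stats[ec].loc[ct_class, "contribution"] for g in ground_truths])
    contrib_mv = np.array([g.stats[ec].loc[mv_class, "contribution"] for g in ground_truths])

    # population sd of the coupled contributions, estimated from an
    # independent calibration draw so the planted correlation is unbiased
    sd_ct = sd_mv = None
    if 0.0 < abs(planted_behaviour_r) < 1.0 or 0.0 < abs(mv_r) < 1.0:
        calib_ct, calib_mv = [], []
        for _ in range(max(n_participants, 100)):
            w = calibration_rng.dirichlet(np.full(config.k_classes, prevalence_concentration))
            _, per_cond = sample_label_sequence(
                config, w, seed=int(calibration_rng.integers(2**31))
            )
            stats = segment_stats(per_cond[ec])
            calib_ct.append(stats.loc[ct_class, "contribution"])
            calib_mv.append(stats.loc[mv_class, "contribution"])
        sd_ct = float(np.std(calib_ct, ddof=1))
        sd_mv = float(np.std(calib_mv, ddof=1))

    # positive planted r: higher coupled-class contribution -> longer CT / higher MV
    ct = _couple(
        contrib_ct, planted_behaviour_r, base=270.0, slope=8.0, rng=cohort_rng,
        population_sd=sd_ct,
    )
    # snap to the 50 Hz behavioural grid so trial logs realise CT exactly
    ct = np.round(np.clip(ct, 30.0, None) * 50.0) / 50.0
    mv = _couple(contrib_mv, mv_r, base=12.0, slope=0.5, rng=cohort_rng, population_sd=sd_mv)
    mv = np.clip(mv, 0.1, None)

    age = np.clip(np.round(cohort_rng.normal(29.0, 6.0, n_participants)), 18, 55).astype(int)
    gaming = cohort_rng.random(n_participants) < 0.4
    sailing = cohort_rng.random(n_participants) < 0.2

    summary = pd.DataFrame(
        {
            "participant": [f"P{i:03d}" for i in range(n_participants)],
            "CT": ct,
            "MV": mv,
            "age": age,
            "gaming_experience": gaming,
            "sailing_experience": sailing,
        }
    )
    trial_logs = _behaviour_trials(summary, cohort_rng) if trials else pd.DataFrame()
    return CohortResult(
        maps, recordings, trial_logs, summary, ground_truths, config, ct_class, mv_class
    )


def _behaviour_trials(summary: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """50 Hz joystick logs, two runs each, realising CT and MV exactly.

    theta_z is white noise rescaled to the planted sample standard
    deviation; the finish flag rises at the planted completion time.
    """
    frames = []
    for row in summary.itertuples():
        n = max(int(round(row.CT * 50.0)) + 1, 4)
        t = np.arange(n) / 50.0
        for run in (1, 2):
            z = rng.standard_normal(n)
            z = (z - z.mean()) / z.std(ddof=1) * row.MV
            finished = (t >= row.CT).astype(int)
            finished[-1] = 1
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": row.participant,
                        "run": run,
                        "t": t,
                        "theta_z": z,
                        "pos_x": t * 0.8,  # nominal straight-line course
                        "pos_y": np.zeros(n),
                        "finished": finished,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
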