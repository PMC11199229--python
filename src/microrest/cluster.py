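"""Polarity-invariant microstate clustering and template comparison.

Microstate maps are average-referenced, unit-norm scalp topographies. Because
an oscillating dipolar field reverses polarity twice per cycle, a map and its
negation represent the same state: every distance in this module is based on
the squared or absolute spatial correlation.

The extraction algorithm is the modified k-means of the microstate
literature, run on the topographies at global field power (GFP) peaks:

1. assign each peak topography to the map with the largest squared spatial
   correlation;
2. update each map as the dominant eigenvector of the outer-product sum of
   its assigned topographies (the polarity-invariant centroid), then
   re-reference and renormalise;
3. repeat until the global explained variance (GEV) changes by less than
   ``tol``; keep the best of ``restarts`` seeded initialisations.

GEV weighs each sample's fit by its GFP:

    GEV = sum_t (GFP_t * corr(v_t, map_label(t)))^2 / sum_t GFP_t^2

Also here: Hungarian matching of two map sets up to permutation and sign,
grand averaging across participants, the explained-variance-vs-k selection
table, and the commonality statistic against a normative template set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .eegio import ConditionDataset, average_reference

__all__ = [
    "MicrostateSet",
    "ClusterFit",
    "spatial_correlation",
    "modified_kmeans",
    "gev",
    "select_k",
    "match_sets",
    "grand_average",
    "commonality",
    "load_template_set",
    "CLASS_LABELS",
]

#: conventional names of the seven canonical classes (1/A ... 7/G)
CLASS_LABELS = ["1/A", "2/B", "3/C", "4/D", "5/E", "6/F", "7/G"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Average-reference and unit-normalise each row (map)."""
    maps = np.asarray(maps, dtype=float)
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-variance map cannot be normalised")
    return maps / norms


@dataclass
class MicrostateSet:
    """k microstate template maps.

    ``maps`` is k x channels; each row is forced to zero channel mean and
    unit Euclidean norm at construction.
    """

    maps: np.ndarray
    class_labels: list[str] = field(default_factory=list)
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, dtype=float)
        if maps.ndim != 2 or maps.shape[0] < 1:
            raise ValueError("maps must be a k x channels matrix with k >= 1")
        self.maps = _normalize_maps(maps)
        if not self.class_labels:
            self.class_labels = (
                CLASS_LABELS[: self.k] if self.k <= 7 else [str(i + 1) for i in range(self.k)]
            )
        if len(self.class_labels) != self.k:
            raise ValueError("class_labels length does not match k")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length does not match channel count")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    # -- I/O: CSV (rows = classes, columns = channels) + JSON metadata ------
    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(self.maps, index=self.class_labels, columns=self.channel_labels).to_csv(
            path, float_format="%.17g"
        )
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "MicrostateSet":
        frame = pd.read_csv(path, index_col=0)
        return cls(
            frame.to_numpy(dtype=float),
            [str(i) for i in frame.index],
            [str(c) for c in frame.columns],
        )


@dataclass
class ClusterFit:
    """Result of one modified k-means extraction."""

    set: MicrostateSet
    assignments: np.ndarray  # per-peak class index
    explained_variance: float  # GEV over the clustered peaks
    n_restarts: int
    n_iter: int
    seed: int | None = None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "maps": self.set.maps.tolist(),
            "class_labels": self.set.class_labels,
            "channel_labels": self.set.channel_labels,
            "assignments": self.assignments.tolist(),
            "explained_variance": self.explained_variance,
            "n_restarts": self.n_restarts,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }
        path.write_text(json.dumps(payload))
        return path


# ---------------------------------------------------------------------------
# spatial correlation
# ---------------------------------------------------------------------------

def spatial_correlation(
    map_a: np.ndarray, map_b: np.ndarray, polarity_invariant: bool = False
) -> float:
    """Pearson correlation of two topographies across channels.

    Both maps are average-referenced first, so this is the cosine of the
    angle between the re-referenced vectors. With ``polarity_invariant`` the
    absolute value is returned, treating a map and its negation as equal.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("maps must be equal-length vectors of >= 2 channels")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance map: spatial correlation undefined")
    r = float(np.dot(a, b) / (na * nb))
    r = max(-1.0, min(1.0, r))
    return abs(r) if polarity_invariant else r


# ---------------------------------------------------------------------------
# peak extraction helper
# ---------------------------------------------------------------------------

def peak_topographies(dataset: ConditionDataset) -> np.ndarray:
    """Average-referenced topographies at per-block GFP peaks, peaks x channels."""
    from .eegio import gfp, gfp_peaks

    rows = []
    for block in dataset.blocks:
        ref = average_reference(block)
        idx = gfp_peaks(gfp(ref))
        rows.append(ref[:, idx].T)
    return np.concatenate(rows, axis=0)


# ---------------------------------------------------------------------------
# modified k-means
# ---------------------------------------------------------------------------

def _gev_peaks(x: np.ndarray, maps: np.ndarray, labels: np.ndarray) -> float:
    """GEV of average-referenced topographies x (n x channels) under maps/labels.

    For zero-mean rows and unit-norm zero-mean maps, GFP_t * corr(v_t, m) =
    (v_t . m) / sqrt(C), so the GFP weighting cancels into plain squared
    projections over squared norms.
    """
    proj = np.einsum("ij,ij->i", x, maps[labels])
    denom = float(np.einsum("ij,ij->i", x, x).sum())
    if denom == 0:
        raise ValueError("all-zero GFP: explained variance undefined")
    return float((proj**2).sum() / denom)


def _assign(x: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """Argmax of squared projection; ties break to the lowest class index."""
    scores = (x @ maps.T) ** 2
    return np.argmax(scores, axis=1)


def _dominant_eigvec(x: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of x^T x for the rows in x (polarity-invariant mean)."""
    cov = x.T @ x
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, -1]
    # deterministic sign: largest-magnitude entry positive
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        v = -v
    return v


def modified_kmeans(
    peaks: np.ndarray,
    k: int,
    restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = None,
    channel_labels: Sequence[str] | None = None,
) -> ClusterFit:
    """Polarity-invariant modified k-means over GFP-peak topographies.

    Parameters
    ----------
    peaks : ndarray, n_peaks x n_channels
        Topographies at GFP peaks (any reference; re-referenced internally).
    k : int
        Number of classes; seven is the convention for resting-state maps.
    restarts : int
        Seeded initialisations; each draws k distinct peak topographies
        uniformly. The restart with the largest GEV wins.
    max_iter, tol : int, float
        Stop when the GEV improves by <= ``tol`` or after ``max_iter``
        assignment/update sweeps.
    """
    x = average_reference(np.asarray(peaks, dtype=float).T).T
    n = x.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} peaks, got {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray, int] | None = None
    for _ in range(max(1, restarts)):
        init_idx = rng.choice(n, size=k, replace=False)
        maps = _normalize_maps(x[init_idx])
        prev_gev = -np.inf
        labels = _assign(x, maps)
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            # update: polarity-invariant centroid per class
            for c in range(k):
                members = x[labels == c]
                if members.shape[0] == 0:
                    # reseed an empty class from the currently worst-fit peak
                    fit = (x @ maps.T) ** 2
                    worst = int(np.argmin(fit.max(axis=1) / np.einsum("ij,ij->i", x, x)))
                    members = x[worst : worst + 1]
                maps[c] = _dominant_eigvec(members)
            maps = _normalize_maps(maps)
            labels = _assign(x, maps)
            cur_gev = _gev_peaks(x, maps, labels)
            if cur_gev - prev_gev <= tol:
                prev_gev = max(prev_gev, cur_gev)
                break
            prev_gev = cur_gev
        if best is None or prev_gev > best[0]:
            best = (prev_gev, maps.copy(), labels.copy(), n_iter)

    assert best is not None
    gev_val, maps, labels, n_iter = best
    mset = MicrostateSet(
        maps,
        channel_labels=list(channel_labels) if channel_labels else [],
    )
    # normalisation in MicrostateSet cannot change assignments (sign/scale only)
    return ClusterFit(mset, labels, float(gev_val), max(1, restarts), n_iter, seed)


# ---------------------------------------------------------------------------
# explained variance of labelled data
# ---------------------------------------------------------------------------

def gev(
    data: np.ndarray | ConditionDataset,
    microstates: MicrostateSet | np.ndarray,
    labels: np.ndarray | list[np.ndarray],
) -> float:
    """Global explained variance of labelled samples.

    ``data`` may be a samples x channels topography array (e.g. the peaks
    passed to clustering) with one label per row, or a
    :class:`ConditionDataset` with per-block label arrays covering every
    sample (the backfit evaluation).
    """
    maps = microstates.maps if isinstance(microstates, MicrostateSet) else np.asarray(microstates)
    if isinstance(data, ConditionDataset):
        x = np.concatenate(
            [average_reference(b).T for b in data.blocks], axis=0
        )
        lab = np.concatenate([np.asarray(l) for l in labels])
    else:
        x = average_reference(np.asarray(data, dtype=float).T).T
        lab = np.asarray(labels)
    if lab.shape[0] != x.shape[0]:
        raise ValueError("one label per evaluated sample required")
    if lab.size and (lab.min() < 0 or lab.max() >= maps.shape[0]):
        raise ValueError("label out of range for the map set")
    return _gev_peaks(x, _normalize_maps(maps), lab)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def select_k(
    peaks: np.ndarray,
    k_range: Sequence[int],
    restarts: int = 5,
    seed: int | None = None,
    plateau_threshold: float = 0.005,
) -> tuple[pd.DataFrame, int]:
    """Explained variance per k and a plateau-based suggestion.

    Fits modified k-means for every k in ``k_range`` and tabulates the
    best-restart GEV. The suggested k is the smallest whose improvement to
    the next k falls below ``plateau_threshold`` (0.5 percentage points by
    default); if no increment is that small, the largest k is suggested.
    """
    ks = sorted(int(k) for k in k_range)
    if not ks:
        raise ValueError("k_range is empty")
    rows = []
    for i, k in enumerate(ks):
        fit = modified_kmeans(peaks, k, restarts=restarts, seed=None if seed is None else seed + i)
        rows.append({"k": k, "explained_variance": fit.explained_variance})
    table = pd.DataFrame(rows)
    suggestion = ks[-1]
    for i in range(len(ks) - 1):
        if table.explained_variance[i + 1] - table.explained_variance[i] < plateau_threshold:
            suggestion = ks[i]
            break
    return table, suggestion


# ---------------------------------------------------------------------------
# matching, averaging, commonality
# ---------------------------------------------------------------------------

def match_sets(set_a: MicrostateSet, set_b: MicrostateSet) -> tuple[np.ndarray, np.ndarray]:
    """Optimal class pairing of two map sets, up to polarity.

    Returns ``(perm, signs)`` such that ``set_b.maps[perm[i]] * signs[i]``
    is the best partner of ``set_a.maps[i]``: the Hungarian assignment on
    cost 1 - |spatial correlation|, signs giving the correlating polarity.
    Ties resolve deterministically (lowest index first).
    """
    if set_a.k != set_b.k:
        raise ValueError("map sets must have equal k")
    if set_a.n_channels != set_b.n_channels:
        raise ValueError("map sets must share the channel montage")
    corr = set_a.maps @ set_b.maps.T  # both zero-mean unit-norm rows
    row_ind, col_ind = linear_sum_assignment(1.0 - np.abs(corr))
    perm = np.empty(set_a.k, dtype=int)
    perm[row_ind] = col_ind
    signs = np.sign(corr[np.arange(set_a.k), perm])
    signs[signs == 0] = 1.0
    return perm, signs


def grand_average(
    sets: Sequence[MicrostateSet], reference: MicrostateSet | None = None
) -> MicrostateSet:
    """Average map sets across participants after permutation/sign alignment.

    Every set is aligned to ``reference`` (default: the first set) with
    :func:`match_sets`, the aligned maps are averaged channelwise, and the
    mean maps are re-referenced and renormalised.
    """
    if not sets:
        raise ValueError("no map sets to average")
    ref = reference if reference is not None else sets[0]
    total = np.zeros((ref.k, ref.n_channels))
    for s in sets:
        perm, signs = match_sets(ref, s)
        total += signs[:, None] * s.maps[perm]
    return MicrostateSet(total / len(sets), list(ref.class_labels), list(ref.channel_labels))


def commonality(
    set_a: MicrostateSet, template_set: MicrostateSet
) -> tuple[pd.Series, float, float]:
    """Per-class polarity-invariant similarity to a template set.

    After Hungarian alignment, the absolute spatial correlation of each
    matched pair is reported per template class, with the mean and sample
    standard deviation across classes as the summary (the mu +/- sigma of a
    commonality table). The maximum attainable value is 1.
    """
    if set_a.n_channels != template_set.n_channels:
        raise ValueError("montage mismatch between map set and template")
    perm, _ = match_sets(template_set, set_a)
    values = pd.Series(
        [
            spatial_correlation(template_set.maps[i], set_a.maps[perm[i]], polarity_invariant=True)
            for i in range(template_set.k)
        ],
        index=template_set.class_labels,
        name="commonality",
    )
    sd = float(values.std(ddof=1)) if template_set.k > 1 else 0.0
    return values, float(values.mean()), sd


# ---------------------------------------------------------------------------
# packaged template set
# ---------------------------------------------------------------------------

def load_template_set() -> MicrostateSet:
    """Load the packaged synthetic normative 7-map template set.

    The seven canonical resting-state maps are published by reference only;
    this packaged set is a synthetic stand-in on a 32-channel 10-20-style
    montage with the canonical class labels, suitable for exercising the
    commonality and backfitting machinery. Substitute any template CSV
    (rows = classes, columns = channels) via :meth:`MicrostateSet.from_csv`
    for real analyses.
    """
    with resources.as_file(
        resources.files("microrest.data") / "synthetic_custo_like_templates.csv"
    ) as path:
        return MicrostateSet.from_csv(path)
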