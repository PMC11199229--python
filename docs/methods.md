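# Methods

This note documents the models, conventions and numerical choices behind
`microrest`, and what the synthetic validation does and does not establish.

## Signal model and preprocessing

A recording is a channels × samples matrix (µV) with a sampling rate and a
list of block-onset events labelled EC (eyes closed) or EO (eyes open). The
default protocol alternates four EO + EC pairs of 30 s blocks (250 Hz). The
front end is deliberately thin: the package assumes artefact-cleaned input
(ICA-based cleaning is out of scope) and applies

* a zero-phase band-pass: order-4 Butterworth in second-order sections run
  forward–backward (`sosfiltfilt`), default 2–20 Hz. Forward–backward
  filtering doubles the effective attenuation (≈48 dB one octave outside the
  band) and has exactly zero phase, so microstate boundaries are not
  displaced;
* common-average referencing, applied instantaneously wherever a topography
  is consumed;
* block trimming: the first and last `trim` seconds (default 2 s) of every
  block are discarded, so a 30 s block contributes 26 s and the default
  protocol yields T = 104 s of effective data per condition. The effective T
  (not the nominal 2 min) is what all time-normalised metrics use, and it is
  recorded in the output metadata.

Block boundaries are preserved end to end: GFP peaks, backfit labels and
run statistics are always computed within blocks, never across the temporal
discontinuity between them.

GFP uses the population (divide-by-N) standard deviation across channels,
the dominant convention in the microstate literature; a `ddof` parameter
exposes the sample convention. GFP peaks are strict local maxima
(`scipy.signal.find_peaks`), so plateaus and block edges never count.

## Microstate extraction

The modified k-means treats a topography and its negation as the same state
(oscillatory fields reverse polarity): distance is squared spatial
correlation and the class centroid is the dominant eigenvector of the
outer-product sum of the assigned (average-referenced) topographies. For
zero-mean unit-norm maps the GFP weighting in the GEV objective cancels into
plain squared projections, which is how it is computed.

Numerical choices, all configurable:

* restarts 5 (each draws k distinct peak topographies uniformly, seeded);
  the restart with the highest GEV over peaks wins;
* convergence when GEV improves ≤ 1e-6, cap 200 sweeps;
* an emptied class is reseeded from the currently worst-fit peak;
* ties (assignment, matching) break to the lowest class index, making every
  path deterministic under a fixed seed;
* eigenvector signs are oriented by making the largest-magnitude channel
  positive — maps are equivalence classes under sign, this is display only.

GEV during clustering is evaluated on the peaks only; after backfitting it
can be evaluated on all samples. Both are exposed (`ClusterFit.
explained_variance` vs `gev` on a dataset) because toolboxes differ on this
point.

Model selection (`select_k`) tabulates best-restart GEV per k and suggests
the smallest k whose improvement to k+1 falls below 0.5 percentage points —
a plateau rule. GEV is non-decreasing in k only statistically (best of
finitely many restarts), which the tests check at a 1e-6 tolerance.

Template sets are matched with the Hungarian algorithm on cost
1 − |spatial correlation|; grand averages align every set to a reference by
permutation and sign before the channelwise mean. Commonality is the
per-class |correlation| after such matching, summarised as mean ± sd across
classes (sample sd, n−1). The packaged 7-map template set is a **synthetic**
stand-in on a 32-channel 10-20-style montage (the canonical normative maps
are published by reference only); any CSV of rows = classes × columns =
channels can be substituted.

## Backfitting and temporal metrics

Every sample is labelled winner-takes-all by maximal |spatial correlation|;
there is no temporal smoothing and no minimum-duration rejection by default
(none is part of the reference procedure; both would be sensitivity
options). A flat sample inherits the label of the nearest non-flat sample in
its block. Occurrence is a raw count per condition (not a rate); Duration is
the mean run length in seconds; Contribution is the percentage of labelled
samples. A class that never occurs reports Duration 0 with an explicit
`absent` flag rather than NaN, so correlation tables never silently shrink.
A run touching a trimmed block edge counts as one occurrence in that block;
runs never span blocks, so a class active across a block boundary counts
twice. These conventions make the identity
`Contribution = 100 · Occurrence · Duration / T` hold exactly by
construction, which the tests verify on arbitrary random sequences.

Without smoothing, backfitting noisy broadband data fragments runs: at
SNR 2 the recovered Contributions are accurate to well under a percentage
point while Durations shrink and Occurrences inflate. This is inherent to
framewise winner-takes-all labelling, not a defect, and is why Contribution
is the primary metric.

## Behavioural metrics

Joystick logs (nominally 50 Hz, jittered) are linearly resampled onto an
exact uniform grid preserving both endpoints. Completion Time is finish
minus start time (clock-offset invariant). Movement Variability is the
sample (n−1) standard deviation of the vertical-axis angle θz after
resampling; the population convention is an option. Participants performed
the task twice; the participant-level value is the mean over completed runs
(the aggregation is not dictated by the reference procedure — the mean is
this package's documented default, with per-run export available).

## Correlational statistics and exact power

Pearson correlations are tested with the t transform
`t = r·√(df/(1−r²))`, df = n − 2, two-sided, with pairwise-complete missing
data handling and the effective n reported per cell. No multiple-comparison
correction is applied by default, matching the reference analysis style; a
Benjamini–Hochberg flag exists for users. Display bands: p ≤ .05
(significant, full box), .05 < p ≤ .10 (trend, dotted box), blank otherwise.
Subgroup analysis repeats the computation excluding participants older than
40 years and reports the excluded count; an empty filter reproduces the full
analysis bit for bit.

Power uses the exact sampling density of the sample correlation under a
bivariate normal population (Hotelling's closed form with the Gauss
hypergeometric function ₂F₁, evaluated in log space), integrated by adaptive
quadrature over the rejection region |r| > r_crit, with r_crit from the null
t distribution. The Fisher-z normal approximation is used only as a test
oracle, alongside a seeded 10⁶-draw Monte-Carlo simulation of the sampling
distribution; the integration agrees with the Monte-Carlo oracle to < 0.003.
`required_n` brackets and bisects on the (strictly monotone) power curve.

## The synthetic-data generator

The generator emulates exactly the structure the analysis relies on:

* **Maps**: k mutually orthogonal average-referenced unit-norm random
  topographies (orthonormalised Gaussian draws in the zero-mean subspace).
  Orthogonality is stricter than real maps (pairwise |corr| up to ~0.3–0.5)
  and makes recovery easier; it pins down identifiability for testing.
* **Label process**: semi-Markov — truncated-Gamma segment durations, mean
  90 ms, sd 30 ms (consistent with the conventional 60–120 ms duration range
  and 2–4 segments/s), minimum one sample; the class entered at a transition
  is drawn from per-participant prevalence weights renormalised over the
  k − 1 other classes (uniform by default; the no-repeat law flattens
  realized prevalences relative to the weights). Each block starts a fresh
  segment.
* **Rendering**: sample topography = active map × rectified 10 Hz sinusoid
  (phase offset 0.3 rad keeps envelope zeros off the 250 Hz sample grid, so
  GFP peaks occur twice per cycle and no sample is flat) + i.i.d. Gaussian
  sensor noise scaled so signal RMS / noise RMS equals the configured SNR
  (∞ = noiseless). No volume conduction, no 1/f background, no artefacts.
* **Cohort**: per-participant prevalence weights ~ Dirichlet(5·1), giving a
  realized EC Contribution sd of ≈5 percentage points around the 14.3 % mean.
  Completion Time is `270 s + 8·(Contribution_C − mean) + noise`, with the
  noise sd calibrated so the population correlation equals the planted r.
  The calibration uses the contribution sd estimated from an *independent*
  calibration draw (max(n, 100) participants' label sequences) — calibrating
  against the analysis sample itself would bias the recovered correlation
  upward by ~0.03 at n = 36. Movement Variability couples analogously to a
  second class. Ages, gaming and sailing flags are independent covariates.
  CT values are snapped to the 50 Hz behavioural grid so the emitted trial
  logs (two runs, white-noise θz rescaled to the planted MV exactly) round-
  trip to the planted summary bit for bit.

Because the generator shares no code with the extraction path beyond the
metric definitions (ground-truth statistics are the enumeration of the
realized label sequence), passing round trips validate the clustering,
backfitting and statistics machinery. They do **not** validate performance
on real EEG, where maps are correlated, noise is spatially structured and
non-stationary, and the true k is unknown; the spatially-correlated-noise
mixing option and the commonality/plateau diagnostics are the entry points
for such sensitivity analyses.

## Validation problem sizes

The test suite runs single-participant designs of 4 × 26 s EC blocks at
250 Hz with 32 channels and k = 7 (≈2 000–3 500 GFP peaks per run):
noiseless recovery is exact; at SNR 2 over 10 seeds the mean per-class
commonality of recovered vs planted maps exceeds 0.90 and Contributions are
within 3 percentage points of ground truth. Cluster-vs-exhaustive-search
equivalence is checked on 100 random instances with ≤ 8 topographies and
k ≤ 3 (a generous 300-restart budget guarantees the global basin on these
tiny instances). Planted-correlation recovery uses one 500-participant
cohort (±0.08) and 200 cohorts of 36 (mean unbiased within its 95 % CI).
These sizes were chosen to exercise every code path at full fidelity while
keeping the whole suite to a few minutes on one core.

## Known limitations

* No ICA/artefact stage, no source imaging, no microstate syntax or
  transition analyses.
* Programmatic merging of split maps (as done by eye when inspecting k = 8
  solutions) is not implemented.
* The packaged template set is synthetic; commonality values against it
  characterise the machinery, not any empirical map family.
* Exact-power integration assumes bivariate normality of the underlying
  pair, as the corresponding power-analysis model does.
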