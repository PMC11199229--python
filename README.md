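# microrest

Resting-state EEG **microstate** analysis for studies linking pre-task brain
states to motor performance — with a first-class synthetic-cohort simulator,
so that every stage of the pipeline can be validated against known ground
truth without any recorded data.

Microstates are brief (~50–200 ms) periods during which the EEG scalp
topography stays quasi-stable. A resting recording alternating eyes-open
(EO) and eyes-closed (EC) 30 s blocks is band-pass filtered (2–20 Hz),
average-referenced, and trimmed (first and last 2 s of every block). At the
peaks of the global field power — GFP(t), the spatial standard deviation
across electrodes — topographies are clustered with the **polarity-invariant
modified k-means**: each peak map is assigned to the template maximising the
squared spatial correlation, and each template is updated as the dominant
eigenvector of its members' outer-product sum. The objective is the global
explained variance

    GEV = Σ_t (GFP_t · corr(v_t, a_{L(t)}))² / Σ_t GFP_t²,

with `v_t` the instantaneous topography and `a_{L(t)}` its labelled template.
Template sets are compared after Hungarian matching up to permutation and
polarity; the per-class |spatial correlation| is the **commonality**.
Backfitting labels every sample winner-takes-all and yields, per class and
condition, the **Duration** (mean segment length, s), **Occurrence**
(segment count) and **Contribution** (% of condition time), which satisfy
`Contribution = 100 · Occurrence · Duration / T`.

With seven classes this gives 21 metrics per participant and condition,
which are Pearson-correlated against two behavioural metrics from joystick
logs — Completion Time (CT) and Movement Variability (MV, the sd of the
joystick vertical-axis angle θz) — with significance banding (full box at
p ≤ .05, dotted at .05 < p ≤ .10, blank above). Statistical power for a
correlation test is computed **exactly** by integrating the bivariate-normal
sampling density of the sample correlation coefficient over the rejection
region (no Fisher-z approximation).

The simulator plants k orthogonal zero-mean unit-norm maps, a semi-Markov
label sequence (truncated-Gamma durations, mean 90 ms), a rectified 10 Hz
amplitude envelope with sensor noise at a configurable SNR, and a cohort
whose CT is linearly coupled to one class's EC Contribution at a planted
population correlation.

## Worked example

Extract microstates from a noiseless synthetic EC recording and recover the
planted ground truth:

```python
import numpy as np
from microrest import (SimulationConfig, make_templates, sample_label_sequence,
                       render_eeg, segment_conditions, modified_kmeans,
                       peak_topographies, commonality, backfit, segment_stats,
                       match_sets)

cfg = SimulationConfig(block_plan=[("EC", 26.0)] * 4, snr=np.inf, seed=0)
maps = make_templates(32, 7, seed=42)                 # planted templates
blocks, per_cond = sample_label_sequence(cfg, seed=1) # semi-Markov labels
rec = render_eeg(blocks, maps, cfg)                   # 32-ch EEG, 250 Hz
ds = segment_conditions(rec, trim=0.0, conditions=["EC"])["EC"]

fit = modified_kmeans(peak_topographies(ds), k=7, restarts=5, seed=3)
values, mean, sd = commonality(fit.set, maps)
print(f"GEV over peaks: {fit.explained_variance:.4f}")   # 1.0000
print(f"mean commonality: {mean:.4f}")                   # 1.0000

measured = segment_stats(backfit(ds, fit.set))
truth = segment_stats(per_cond["EC"])
perm, _ = match_sets(maps, fit.set)
print(truth.loc[2, "contribution"],                      # 14.4231...
      measured.loc[perm[2], "contribution"])             # identical
```

The run above prints `GEV over peaks: 1.0000`, `mean commonality: 1.0000`,
and identical planted vs recovered contributions (e.g. class 0: 13.581 %,
Duration 0.0948 s, Occurrence 149 over T = 104 s) — on noiseless data the
extraction-and-backfit round trip is exact.

Exact power of a correlation test at the 36-participant scale:

```python
from microrest import correlation_power, r_squared
res = correlation_power(rho=0.403, n=36, alpha=0.05, tails=2)
print(f"power {res.power:.4f}, rho^2 {r_squared(0.403):.4f}")
# power 0.7016, rho^2 0.1624
```

A full configured run (simulate → filter → cluster → backfit → correlate →
report) is available from the shell:

```
microrest run --seed 1 --out runs/demo
microrest stats --rho 0.277 --n 36       # {"power": 0.379, ...}
```

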