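# megcat

Time-resolved multivariate analysis of visual category learning in
simulated MEG recordings.

## The problem

When people learn — with trial-by-trial feedback — to tell apart two
highly similar, novel visual categories, category information appears in
the neural signal within a few hundred milliseconds of stimulus onset,
and the cortical sites carrying that information shift as learning
progresses: ventral visual regions become more category-predictive late
in learning, while prefrontal involvement fades. `megcat` implements the
complete statistical pipeline for studying this process, exercised
end-to-end on a synthetic MEG generator, so that every stage is testable
without access to human recordings:

1. **Stimulus space** (`megcat.stimuli`) — two categories of 20-edge
   "blob" polygons. Each category is a diagonal Gaussian around a
   prototype vector of edge proportions (uniform per edge on
   [0.3, 0.7]), with per-edge standard deviation
   `0.2 × |prototype_A − prototype_B|`. A session is 600 trials in five
   blocks, category-balanced within each block.
2. **Synthetic epochs** (`megcat.simulate`) — 102-channel sensor
   ensembles and 24 region-bounded dipole ensembles (12 ventral-visual,
   12 prefrontal), sampled at −120…400 ms around onset: band-limited
   Gaussian noise plus category-signed, raised-cosine evoked effects
   confined to latency windows, with amplitude following a logistic
   learning curve over trials.
3. **Preprocessing** (`megcat.preprocess`) — per-trial baseline removal
   over [−120, 0) ms; moving-window averaging (20 ms windows, 10 ms
   steps → 39 bins over [0, 400) ms); selection of the first/final 100
   trials as early/late learning phases.
4. **Discriminability** (`megcat.discriminability`) — per time bin, PCA
   to ≥ 99% variance, then the two-sample Hotelling statistic

   T² = (n_A n_B / (n_A + n_B)) · δ′ S⁻¹ δ,

   reported as a χ²_p statistic (p = retained dimensionality), plus
   100-fold label-shuffled null traces.
5. **Excursion inference** (`megcat.excursion`) — contiguous runs of
   ≥ 2 bins with χ² > 20 are proposed as temporal regions of interest;
   their maximum mass is ranked against the label-shuffled nulls,
   p = (1 + #{null ≥ observed}) / (n_perm + 1); subject-level p-values
   combine via Fisher's method, −2 Σ ln pᵢ ~ χ²(2k).
6. **Decoding** (`megcat.decoding`) — leave-one-trial-out logistic
   prediction of category from window-averaged dipole ensembles
   (baseline 0–50, M100 50–150, M200 150–250, M300 250–350 ms), per
   region and learning phase, with early-vs-late and
   ventral-visual-vs-prefrontal contrasts via two-proportion z-tests.
7. **Pipeline** (`megcat.pipeline`, `megcat` CLI) — orchestrates a
   multi-subject simulated cohort from one master seed and writes a
   reproducible result bundle.

## Worked example

```python
import numpy as np
from megcat import (
    NoiseParams, make_prototype_pair, generate_stimulus_set,
    default_layout, default_scenario_effects, simulate_region_ensembles,
    remove_baseline, decode_grid, compare_phases,
)

pair = make_prototype_pair(seed=0)
stimuli = generate_stimulus_set(pair, 300, np.random.default_rng(0))
layout = default_layout()
regions = simulate_region_ensembles(
    stimuli, layout, default_scenario_effects(layout),
    NoiseParams(), np.random.default_rng(0),
)
regions = {name: remove_baseline(ep) for name, ep in regions.items()}
table = decode_grid(regions, layout=layout)
contrast = compare_phases(table)
print(contrast.sort_values("difference", ascending=False).head(3)
      [["region", "window", "accuracy_early", "accuracy_late", "difference"]])
```

prints

```
                 region window  accuracy_early  accuracy_late  difference
34          fusiform-lh   M200            0.48           1.00        0.52
21  lateraloccipital-rh   M100            0.32           0.56        0.24
43  inferiortemporal-lh   M300            0.33           0.54        0.21
```

The canonical scenario injects a 150–250 ms effect into the left
fusiform region whose strength ramps up with learning, and a decaying
250–350 ms effect into the left pars orbitalis. The decoding grid
recovers exactly this structure: the largest early→late accuracy
increase (+0.52) lands on the fusiform M200 cell — early-phase decoding
is at chance (0.48) because the effect is still nearly absent in the
first 100 trials, and late-phase decoding is perfect (1.00) once the
learning curve saturates. The remaining cells fluctuate around chance.

The same analysis is available from the shell:

```sh
megcat run-all --seed 0 --out runs/demo      # full 7-subject cohort
megcat combine --pvalues 0.0099,0.0099       # Fisher combination
```

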