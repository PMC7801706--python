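# eegmicrostates

EEG microstate analysis of cognitive task performance: segmentation of
multichannel scalp EEG into the four archetype microstates (A–D), extraction
of 36 per-epoch temporal and syntactic features, nonparametric group
comparison, and a feature-selection + classification harness — together with
a synthetic EEG generator with known ground-truth microstate structure, so
that every stage of the pipeline can be validated by parameter recovery.

It is written for researchers analysing resting/task EEG cohorts (e.g.
mental-arithmetic performance groups) who want a tested, reproducible
microstate pipeline rather than a collection of toolbox scripts.

## The method

Spontaneous EEG topographies do not change continuously: the scalp field
stays quasi-stable for 60–120 ms and then switches abruptly.  These
*microstates* are recovered in four steps:

1. **Global field power.**  For potentials $V_i(t)$ on $N$ electrodes,

   $$\mathrm{GFP}(t) = \sqrt{\tfrac{1}{N}\sum_{i=1}^{N}\bigl(V_i(t) - \bar V(t)\bigr)^2},$$

   a reference-free measure of momentary field strength.  Topographies at
   local GFP maxima have the highest signal-to-noise ratio and form the
   clustering input.

2. **Polarity-invariant (modified) k-means.**  Peak maps are clustered into
   $k=4$ templates.  Both the assignment (maximal squared spatial
   correlation) and the template update (first principal direction of the
   assigned maps) ignore polarity, because spontaneous EEG fields flip sign.
   The objective is the global explained variance

   $$\mathrm{GEV} = \frac{\sum_t \mathrm{GFP}(t)^2\,
       \mathrm{corr}\bigl(V(t), a_{L(t)}\bigr)^2}{\sum_t \mathrm{GFP}(t)^2},$$

   maximised over 20 random re-runs (threshold $10^{-6}$, at most 1000
   iterations), with a greedy local-search polish of the winning partition.
   Templates are labelled A–D by optimal matching against canonical
   orientation maps (A/B: mirrored lateral orientations, C:
   anterior–posterior, D: fronto-central focus).

3. **Backfitting and features.**  Every sample of every 2-s epoch is
   assigned to the best-matching template, giving a label sequence whose
   runs yield 18 microstate features (per class: mean duration in ms,
   occurrence in Hz, coverage in %, mean GFP in µV; plus class-pooled mean
   duration and mean occurrence), 12 transition percentages (ordered class
   pairs), and 6 directional predominances $P(X{\to}Y) - P(Y{\to}X)$ with a
   permutation test of syntactic symmetry.

4. **Statistics and classification.**  State-group contrasts (rest vs task
   within group, group vs group within task) use two-sided Mann–Whitney
   tests with Bonferroni–Holm correction.  The classification harness
   balances the groups by downsampling (250 epochs/group), repeats
   recursive feature elimination over re-drawn subsamples, and reports
   accuracy/AUC/sensitivity/specificity from stratified five-fold
   cross-validation for eight classifiers (LR; linear/polynomial/RBF SVM;
   kNN with k = 2, 5, 10; random forest).

The synthetic generator renders a Markov sequence of four ground-truth
topographies (truncated-geometric dwell times, configurable transition
matrix), amplitude-modulated so the GFP rises and falls within each state,
with per-segment polarity flips and spatially correlated noise at a
configurable SNR — and builds two-group cohorts (26 good / 10 poor
performers, 3-min rest + 1-min task at 500 Hz on the 19-channel 10–20
montage) with configurable planted effects.

## Worked example

```python
import numpy as np
from eegmicrostates import (CohortSpec, default_ground_truth, generate_cohort,
                            run_study, compare_states)

truth = default_ground_truth(seed=3, snr=5.0)          # 4 maps, 80 ms dwell
spec = CohortSpec(truth=truth, n_good=3, n_poor=2,
                  rest_length_s=30.0, task_length_s=30.0,
                  effects={("good", "task"): {"dwell_scale": {"D": 1.2}}})
cohort = generate_cohort(spec, seed=7)
table, models, log = run_study([sr.recording for sr in cohort],
                               clustering="pooled", bandpass=False, seed=9)

model = next(iter(models.values()))
corr = np.abs(model.ordered_maps() @ truth.topographies.T)
print("GEV: %.3f" % model.gev)
print("map recovery |corr|:", np.round(np.diag(corr), 3))
print("mean dwell (ms):", np.round(
    table[[f"duration_{c}" for c in "ABCD"]].mean().to_numpy(), 1))
```

prints

```
GEV: 0.972
map recovery |corr|: [1. 1. 1. 1.]
mean dwell (ms): [77.5 80.2 83.5 80.4]
```

i.e. the four templates recovered from 150 noisy synthetic epochs are
essentially identical to the generating topographies (spatial correlation
1.00), the model explains 97 % of the GFP-weighted variance, and the
backfitted mean dwell times sit within a few percent of the generator's
80 ms.  Feeding `table` to `compare_states` then flags the planted class-D
dwell increase in the good-performer task contrast and nowhere else.

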