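# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates.  It is the package's own account of its
procedures; every number quoted here is computed by the tests or by
`scripts/acceptance.py`.

## Microstate model and segmentation

The package treats spontaneous EEG as a concatenation of quasi-stable
scalp-field topographies ("microstates", ~60–120 ms each) from a small
inventory of four archetypes.  Segmentation follows the classic recipe:

* **Clustering input.**  Only topographies at local maxima of the global
  field power are clustered; backfitting afterwards labels *every* sample.
  Peaks are defined by `gfp[t-1] < gfp[t] >= gfp[t+1]` (first sample of a
  plateau; endpoints excluded).

* **Modified k-means.**  Assignment uses the squared spatial correlation
  (polarity ignored, ties to the lowest template index); the template
  update is the first principal direction of the assigned maps — the unit
  vector maximising $\sum_t (V_t \cdot a)^2$ — equivalently a GFP²-weighted
  polarity-invariant mean.  Both steps monotonically increase the GEV, and
  convergence is declared when its relative change falls below 1e-6
  (at most 1000 iterations).  A sign-aligned-mean update is available
  (`update_rule="mean"`).

* **Re-runs and polish.**  20 random initialisations (k distinct peak maps
  as seeds) are run and the highest-GEV run kept.  On tiny inputs, where
  the number of distinct seed subsets is below the re-run budget, all
  subsets are enumerated instead of sampled.  The winning partition is then
  refined by greedy local search: single-map reassignments always, plus
  two-map exchanges on inputs of ≤128 maps.  Plain Lloyd-style iteration
  provably cannot leave some local optima that single seed re-draws also
  miss; the polish makes the result locally optimal under the explored
  neighbourhood at negligible cost for realistic inputs (~9 s for 10⁵ peak
  maps).  On randomly generated peak-map-like instances with ≤8 maps and
  k = 2 the polished result matched the exhaustively enumerated 2-partition
  optimum in 1998 of 2000 instances (the rest require coordinated moves of
  ≥3 maps); the 50-instance acceptance check passes in full.

* **Archetype labelling.**  The four templates are matched to canonical
  orientation maps built on schematic 10–20 coordinates — A and B are the
  mirrored lateral orientations (gradient axis tilted 30° from the
  left–right axis toward frontal), C the anterior–posterior gradient, D a
  fronto-central Gaussian focus — by maximising summed |spatial
  correlation| over all bijections (solved as a linear assignment problem,
  exact over the 24 permutations).

* **Aggregation level.**  By default one model is fitted per state-group
  cell (poor/good × rest/task), since group-level topographies may differ;
  `clustering="pooled"` fits a single model on all epochs.

## Preprocessing

Fixed order: 2–20 Hz band-pass → common-average reference → 2-s epochs →
threshold rejection.  The filter is a 4th-order Butterworth applied
forward–backward (zero phase; topography timing is preserved), on the
continuous recording so that epoch edges carry no transients.  An epoch is
rejected iff any channel exceeds 100 µV in absolute value or 500 µV² in
variance (per channel per epoch — the only reading of the variance
criterion consistent with the amplitude criterion's scale), or it appears
in an explicit manual-exclusion list, which stands in for irreproducible
visual inspection while keeping the pipeline deterministic.

**Band-pass and synthetic data.**  The synthetic generator builds signals
directly in topography space with discontinuous state switches.  A 20 Hz
low-pass rings over ~50 ms — the same order as the dwell times — and smears
neighbouring states into each other (measured: backfit agreement at snr = 5
falls from 1.00 to ~0.54 when the filter is applied).  Parameter-recovery
runs therefore use `bandpass=False`; the filter keeps its own
frequency-response tests (pass-band gain within 5 %, ≥90 % attenuation at
0.5 Hz and 50 Hz).  Real raw EEG, which is generated in-band, should keep
the filter.

## Feature definitions and boundary handling

Within one 2-s epoch, for each class: duration = mean length (ms) of its
runs, occurrence = number of its runs per second, coverage = % of samples,
mean GFP = mean GFP over its samples; plus class-pooled mean duration and
mean occurrence.  The first and last run of an epoch are truncated by the
window, so they are excluded from duration means but count toward coverage
and occurrence (a run occurs if it starts inside the epoch; the first run
counts as a start).  Consequently mean occurrence = Σ occurrence exactly,
coverages sum to 100 %, and the identity coverage ≈ occurrence × duration/10
holds approximately; the `policy="symmetric"` mode computes all three over
interior runs with the interior span as time base, under which the identity
is exact.  A class absent from an epoch gets occurrence and coverage 0 and
a flagged, imputed (0) duration, so classifiers receive complete 36-vectors.

Transition percentages divide the count of each ordered class pair's
boundaries by the total boundary count; directional predominance is
P(X→Y) − P(Y→X) for the six unordered pairs, antisymmetric and negated by
time reversal.

## Syntax-asymmetry permutation test

The null of interest is directional symmetry of the microstate syntax.  Run
lengths stay attached to their classes, and only the run order is
resampled, so the resampling leaves every microstate feature untouched.
Two design choices matter and were measured:

* **Resampling scheme.**  A plain uniform shuffle of the run order ignores
  that real run sequences never repeat a class in adjacent runs; its null
  is therefore wrong for long sequences, and the test over-rejects
  (measured type-I at α = 0.05: 0.051 at ~50 runs, 0.062 at ~100, 0.074 at
  ~200).  The default scheme draws arrangements sequentially, proportional
  to remaining run-class counts and excluding the class just placed, so
  every draw respects the no-repeat structure.

* **Estimator.**  The statistic is integer-valued, so the conservative
  add-one estimator under-rejects at practical sequence lengths.  The
  default is the mid-p estimate (n_greater + 0.5·(n_equal + 1))/(B + 1),
  never zero and close to exactly calibrated.  Measured type-I of the
  default pairing: 0.040 / 0.047 / 0.048 at ~25 / 100 / 500 runs; the
  acceptance run over 5,000 symmetric-chain sequences gives 0.052.

Both the plain shuffle and the add-one estimator remain available as
options.  An analytic independence expectation of the transition
percentages is provided for comparison with the resampling null.

## Group statistics

Mann–Whitney (normal approximation with tie and continuity correction, z
signed so positive means the first sample is larger) agrees with exact
enumeration to < 0.05 for tie-free n ≤ 8.  Holm's step-down adjustment is
applied per contrast within two families: the 18 microstate features, and
the 12 + 6 transition features.  The unit of analysis is the epoch, which
mirrors common practice for this design but ignores within-subject
correlation; p-values are therefore anti-conservative for subject-level
claims, and a subject-mean aggregation mode (`aggregate="subject"`) is
provided.  Directional predominances are tested against zero with a
sign-flip permutation test (their null is symmetric about zero); a
signed-rank variant is available.

## Classification harness

Groups are balanced by uniform downsampling without replacement (default
250 epochs/group).  RFE is repeated (default 100×) over re-drawn
subsamples; within each repetition the elimination is fold-nested: ranking
(|coefficient| for linear models on standardised features, validation-split
permutation importance otherwise) and elimination use training folds only,
and the held-out fold is scored at every feature count.  An earlier
whole-subsample ranking inflated small-count accuracy to ~0.6 under
shuffled labels; the nested version sits at 0.5 as it must.  Features are
z-scored inside training folds (they mix ms, Hz, %, µV).  Default
hyperparameters: C = 1.0 for LR and all SVMs, RBF width "scale", polynomial
degree 3, 500 trees; sensitivity is the recall of the good-performer class.

## Synthetic generator: what it emulates and what it does not

The generator emulates the statistics the pipeline measures: four fixed
unit-norm, average-referenced topographies (canonical archetypes with
seeded jitter); a semi-Markov state sequence with truncated-geometric
dwells (memoryless, minimum one sample; default mean 80 ms, inside the
physiological 60–120 ms range) and a zero-diagonal row-stochastic
transition matrix (default uniform); a raised half-sine GFP profile per
segment (peak 5 µV — typical band-passed scalp field strength — troughs at
half peak, so GFP maxima fall mid-segment as in real data); per-segment
polarity flips (exercising polarity invariance); and spatially correlated
Gaussian noise (squared-exponential covariance over the electrode layout,
length scale 0.5 head radii, average-referenced) at a configurable
signal/noise RMS ratio (default 5).  Cohorts default to the study design:
26 good / 10 poor performers, 3-min rest + 1-min task, 500 Hz, 19 channels,
with per-cell parameter overrides for planting effects.

It does **not** emulate: biophysical forward fields, 1/f spectra,
band-limited state switching (transitions are discontinuous), eye/muscle
artifacts, or between-subject topographic variability.  Passing recovery
tests therefore shows the pipeline's machinery is correct under a known
generative model — not that real EEG satisfies that model.

## Problem sizes in the shipped runs

The test suite and acceptance script scale the study down where full size
adds nothing: topography/dwell recovery uses 5 subjects × 2 × 30 s
(recovery is already at |corr| > 0.999); the planted-effect study runs the
full design (36 subjects, 4,320 epochs); permutation-test calibration uses
8-s sequences (≈100 runs) with 1,000 permutations — 5,000 sequences in the
test suite, 1,000 in the acceptance script; the acceptance-script RFE uses
25 repetitions with logistic regression.  All randomness is seeded;
cohort-level streams are spawned per recording so results are
bit-reproducible.

## Known limitations

* Dwell distributions are geometric; empirical dwell distributions are
  heavier-tailed.
* The conditional arrangement sampler is sequential-proportional, not
  exactly uniform over no-repeat arrangements; its measured calibration is
  slightly conservative (0.04–0.05).
* Epoch-level statistics ignore subject clustering (see above).
* EDF files can be read (via mne) but not written; the portable write
  format is a TSV matrix + JSON sidecar.
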