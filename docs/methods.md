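# Methods

`msdual` implements a dual-modality (resting-state + task-state) EEG
microstate analysis for graded disorders of consciousness (DOC), together
with a synthetic cohort generator that reproduces the statistical structure
the analysis assumes. This note records the models, the defaults and why
they were chosen, the numerical decisions, and what the synthetic tests do
and do not demonstrate.

## Microstate model

Scalp EEG is modeled as a sequence of quasi-stable topographies
("microstates"), conventionally four classes A-D. All topographic
quantities assume the common average reference:

* **GFP** (global field power): `GFP(t) = sqrt(mean_c v_c(t)^2)`, the
  spatial SD of the field at time `t`.
* **Spatial correlation** `r`: Pearson correlation of two maps across
  channels. Because the generating dipoles oscillate, a map and its
  negation are the same microstate; assignments always use `|r|`.
* **GMD** (global map dissimilarity): Euclidean distance of unit-GFP maps,
  `GMD^2 = 2 (1 - r)`.

### Modified k-means

Template extraction clusters topographies at GFP peaks (moments of maximal
topographic signal-to-noise). The clustering is a polarity-invariant
k-means: a map `x_t` is assigned to the class maximizing `(x_t . a_k)^2`,
and each prototype `a_k` is updated to the dominant eigenvector of the
class's cross-product matrix `sum x_t x_t^T` (the polarity-invariant
analogue of the cluster mean). An alternative mean-of-sign-aligned-maps
update is available via `update="mean"`; the eigenvector update is the
default because it is the exact maximizer of the within-class explained
variance. Defaults: 10 restarts, 500 iteration cap, convergence when the
relative change of explained variance falls below 1e-5. Raw (non-GFP-
normalized) peak maps are clustered, so stronger maps weigh more; returned
templates are rescaled to unit GFP.

Model order is chosen by the cross-validation criterion
`CV(K) = sigma^2 * ((C-1)/(C-1-K))^2`, where `sigma^2` is the residual
variance per channel and `C` the channel count; `K* = argmin CV`.

### Global templates and canonical labels

A single *global* template set is clustered from GFP-peak maps pooled
across subjects. Every subject contributes the same number of maps (seeded
random subsampling to the minimum per-subject count) so long recordings
cannot dominate. Maps are named A-D by exhaustively matching (over all
permutations, K <= 6) against built-in idealized archetypes — smooth
dipolar patterns on the 10-20 montage with the class-D archetype peaking
at Pz (posterior-parietal), the configuration relevant to DOC grading.
Matching scores are stored on the template set so the labeling can be
audited.

### Back-fitting and parameters

Every sample is assigned to the template with the highest `|r|` (ties to
the lowest class index, zero-GFP samples left unassigned). Interior
segments shorter than a minimum duration are then removed: walking in from
the segment edges, each sample joins whichever flanking class has the
higher `|r|` at that sample; first/last segments are exempt (no neighbor
on one side). Each pass strictly reduces the segment count, so the
procedure terminates; adjacent short segments are handled in separate
passes because processing them simultaneously from a stale snapshot can
cycle. The default threshold is 30 ms — below the 60-120 ms physiological
dwell range, so genuine states survive while noise-driven flicker is
removed.

Per class: coverage (% of assigned samples), mean segment duration (ms),
occurrence (segments per assigned second), and mean GFP (uV) over assigned
samples. Goodness of fit: global explained variance
`GEV = sum_t (GFP_t r_t)^2 / sum_t GFP_t^2` (reported as R^2) and the
residual SD of `v(t) - a(t) T_k(t)` with `a(t)` the least-squares scalar.

### TANOVA

Topographies of two groups are compared by the GMD between the two
group-mean maps, with group membership permuted for the null (default
5000 permutations, Monte-Carlo p never below `1/(n_perm+1)`). Members are
scaled to unit GFP, and polarity is aligned to the dominant eigenvector of
the pooled unit-GFP maps before averaging. An order-invariant common
reference is essential: aligning each group to "its first member" makes
the statistic depend on row order, which breaks exchangeability and
invalidates the permutation distribution (Monte-Carlo and exhaustive
enumeration then disagree). Group comparisons are run per class on
subject-level class-mean maps (each subject's assigned samples, unit-GFP
scaled and sign-aligned to the class template, averaged).

## Statistics

* Route gate: Shapiro-Wilk per group and Levene (mean-centered), all at
  alpha = 0.05; any failure, constant group, or n < 3 routes to the
  nonparametric branch. Note that with four groups the joint pass
  probability under exact normality is ~0.95^5 ~ 0.77, an inherent
  property of this gate.
* Parametric: one-way ANOVA (from raw data via `f_oneway`, or exactly from
  (n, mean, SD) summaries: `SSB = sum n_g (m_g - m)^2`,
  `SSW = sum (n_g - 1) s_g^2`), effect size partial eta squared
  `SSB/(SSB+SSW)`; Bonferroni-corrected pairwise t tests with Cohen's d.
* Nonparametric: Kruskal-Wallis H (tie-corrected) with epsilon squared
  `H (N+1)/(N^2-1)`, Dunn-Bonferroni post hocs (tie-corrected z tests).
* Cohen's d uses the equal-weight pooled SD `sqrt((s1^2+s2^2)/2)`; this
  convention reproduces seven of the nine reported dual-template effect
  sizes to +/-0.01 (the remaining two, 6.36 and 3.78, match no standard
  pooling of their reported cells — they evaluate to 6.26 and 3.63 — and
  are flagged rather than force-fit). The n-weighted pooled SD is
  available via `weighted=True`.
* Rank-biserial: `2U/(n1 n2) - 1` (independent), signed-rank ratio
  (paired).
* Task design: linear mixed model `value ~ condition * group` with subject
  random intercepts, REML (statsmodels `MixedLM`). The interaction Wald F
  uses the between-within denominator df `N - p - (S - G)`, which equals
  the Satterthwaite value `(S-G)(C-1)` in the balanced complete designs
  this pipeline produces; general-unbalanced Satterthwaite df are not
  implemented. Type-I error of the interaction test is verified by
  simulation (<= 10% at alpha 0.05).

## Synthetic cohort generator

The generator emulates the study conditions: four groups (HC 9, MCS+ 6,
MCS- 6, VS 6), 32-channel average-referenced EEG, and rest(120 s) /
task(80 s) / rest(120 s) sessions.

* **State sequence**: semi-Markov chain without self-transitions,
  gamma-distributed dwell times (shape 2 — right-skewed, positive) with
  per-class mean dwell targets. Class entry weights are calibrated by a
  fixed-point iteration on the embedded chain so that stationary coverage
  matches the per-class coverage targets exactly in expectation.
* **Group profiles** (the study conditions): Microstate-D resting coverage
  23.5 / 15.1 / 9.4 / 4.7 % and GFP 7.1 / 6.7 / 4.4 / 3.1 uV across
  HC / MCS+ / MCS- / VS; D dwell 50 / 29 / 30 / 24 ms. Classes A-C take
  the reported resting per-class dwell and GFP values and share the
  non-D coverage mass in proportion to their reported coverages. Task
  modulation adds to the D coverage target during the task window only
  (HC: +3.1 V, +2.7 O, +7.2 V-O percentage points; MCS+: +2.1 V-O;
  MCS-/VS: 0), with the other classes rescaled proportionally.
  Note the reported D dwell means put MCS+ (29 ms) *below* MCS- (30 ms);
  the simulator reproduces the reported values, so the recovered duration
  gradient is HC > MCS- > MCS+ > VS, not the strict severity ordering —
  an internal inconsistency of the reported group profile that the test
  suite documents rather than hides.
* **Forward model**: each segment contributes
  `sign x a(t) x template`, with a random +/-1 polarity sign per segment
  (exercising polarity invariance) and a strictly positive envelope
  `a(t) = GFP_k (1 + 0.3 sin(2 pi f t + phi))`, `f ~ U(8, 12) Hz` per
  segment (alpha-band amplitude modulation whose mean equals the class's
  GFP target). Noise is spatially correlated Gaussian (squared-exponential
  covariance over electrode positions, 3 cm length scale), band-passed to
  0.5-50 Hz, average-referenced, and scaled to `noise_level` times the
  signal RMS. At noise 0 every sample is an exact scalar multiple of its
  template, giving the exact-recovery regime the oracle tests rely on.
* **Sampling rate**: 250 Hz default (adequate for 0.5-50 Hz content),
  configurable; several Monte-Carlo suites run at 125 Hz to keep the
  default test run fast.
* **Problem sizes**: the cohort-recovery analysis uses 27 subjects x 300 s
  at noise 0.25; task-modulation recovery uses 9 HC subjects x 20 seeds of
  full 320-s sessions; null-calibration suites use 100 replicates of
  shortened (60/40/60 s) sessions.

What the generator does **not** emulate: biophysical dipole/forward-head
modeling, ocular or muscular artifacts (artifact removal is out of scope),
non-stationary vigilance drifts, inter-subject topographic variability
(all subjects share the archetype maps), and 1/f background spectra.
Passing recovery tests therefore demonstrate the correctness of the
*pipeline* under the stated generative model, not robustness to real
patient EEG.

## Numerical choices and edge cases

* Band-pass: Butterworth, zero-phase (`sosfiltfilt`), default order 5 per
  band edge — the lowest order whose zero-phase response attenuates 60 Hz
  by >20 dB at fs 250 (order 4 gives 19.1 dB).
* Average reference is enforced on entry to all topographic computation;
  `global_field_power` and clustering reject non-average-referenced input.
* Back-fit ties (equal `|r|` within 1e-12) go to the lowest class index;
  zero-GFP samples are unassigned and excluded from all denominators.
* Empty clusters during k-means are re-seeded from the worst-fit map.
* Parameter-recovery measurements use an 8 ms (2-sample) smoothing
  threshold: it removes single-sample noise flickers, which otherwise bias
  recovered dwell downward for low-GFP classes, while censoring almost no
  genuine segments (the shortest generated mean dwell is 24 ms). The 30 ms
  default stays in place for the study-replica analyses; it is not used
  for dwell recovery because it would censor the 24-30 ms patient-group
  D segments themselves.
* EDF+ output is written by a built-in 16-bit writer (1-s records, TAL
  annotation channel); reading goes through `mne.io.read_raw_edf`, with an
  explicit file-size check so truncated files fail loudly. Recordings
  should be whole seconds long (the final partial record is zero-padded).
* `summary_matched_sample` rescales a seeded normal draw affinely to the
  exact requested sample mean and SD, bridging summary-statistic and
  raw-data inference to ~1e-12.

## Known limitations

* Canonical labeling is exhaustive over permutations and limited to K <= 6.
* The LMM reports between-within df; strongly unbalanced designs would
  need a true Satterthwaite implementation.
* TANOVA permutes complete maps; no cluster-based spatio-temporal
  statistics.
* The archetype maps are idealized; canonical labels on real data should
  be audited via the stored matching scores.
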