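# msdual

Dual-modality (resting-state + task-state) EEG **microstate** analysis for
graded disorders of consciousness (DOC), with a synthetic cohort generator
that makes the whole pipeline testable end to end without patient data.

## The problem

Behavioral scales grade consciousness (healthy controls HC, minimally
conscious states MCS+ / MCS−, vegetative state VS) subjectively and miss
covert awareness. EEG microstates — quasi-stable scalp topographies lasting
tens of milliseconds, canonically labeled A–D — offer an objective,
millisecond-resolution readout. Microstate **D**, with a posterior-parietal
maximum, tracks default-mode-network integrity: its resting coverage, GFP,
and dwell time attenuate with DOC severity, and its task-evoked coverage
increase under combined visual–olfactory stimulation separates MCS+ from
deeper states. This package implements that analysis for anyone who wants
to run, audit, or stress-test it.

## The method

For average-referenced EEG `v(t)`:

* GFP(t) = √(mean_c v_c(t)²); topographies at GFP peaks are clustered with
  a polarity-invariant **modified k-means**: sample `x_t` joins the class
  maximizing `(x_tᵀ a_k)²`, and each prototype `a_k` is the dominant
  eigenvector of `Σ_{t∈k} x_t x_tᵀ` (10 restarts, 500 iterations,
  tolerance 1e-5).
* Model order by the CV criterion `σ̂²·((C−1)/(C−1−K))²`, minimized over K.
* A pooled **global template** (equal per-subject peak counts) is labeled
  A–D against idealized archetypes, then **back-fitted**: every sample goes
  to the template with the highest |spatial correlation|, segments shorter
  than a minimum duration are smoothed into their neighbors, and coverage
  (%), mean duration (ms), occurrence (/s), and mean GFP (μV) are computed
  per class, plus GEV = Σ(GFP_t·r_t)²/ΣGFP_t² and the residual SD.
* Templates are compared by |r| matrices and a permutation **TANOVA**
  (GMD between polarity-aligned group means); groups by assumption-gated
  ANOVA/ηp² or Kruskal–Wallis/ε² with Bonferroni/Dunn–Bonferroni post hocs,
  Cohen's d and rank-biserial effect sizes; the task design by a linear
  mixed model (condition × group, subject random intercepts, REML).

The synthetic generator (`msdual.simulate`) emulates the study conditions:
9/6/6/6 cohorts, 32-channel EEG, rest(120 s)/task(80 s)/rest(120 s)
sessions, semi-Markov state sequences with gamma dwell times hitting the
reported per-group coverage/dwell/GFP profiles, polarity-flipping
segments, spatially correlated band-limited noise, and task windows whose
Microstate-D coverage shifts by the reported modulation. See
`docs/methods.md` for every default and its rationale.

## Worked example

Run a scaled-down study replica (10 subjects, 60 s rest recordings,
40/30/40 s sessions, 125 Hz) and print the headline results:

```python
from msdual.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(group_sizes={"HC": 3, "MCS+": 2, "MCS-": 2, "VS": 2},
                     rest_duration_s=60.0, fs=125.0, rest_s=40.0,
                     task_s=30.0, post_rest_s=40.0, n_perm=199, seed=11)
report = run_pipeline(cfg, "out/")
print(report["microstate_D_coverage_group_means"])
print(report["task_modulation_means"]["V-O"])
print(report["template_match"]["rest"])
```

prints (values rounded):

```
{'HC': 22.26, 'MCS+': 11.72, 'MCS-': 7.18, 'VS': 3.45}
{'HC': 5.54, 'MCS+': 2.13, 'MCS-': 0.10, 'VS': -0.28}
{'A': 0.9999, 'B': 1.0000, 'C': 1.0000, 'D': 0.9999}
```

Reading: recovered resting Microstate-D coverage falls monotonically with
DOC severity (HC 22.3 % → VS 3.4 %, tracking the generating 23.5/15.1/
9.4/4.7 % profile); the task-minus-rest D-coverage increase under combined
visual–olfactory stimulation is large in HC, small in MCS+, and absent in
MCS−/VS; and the pooled resting global template matches the generating
topographies at |r| ≥ 0.999 per class. `out/` also receives the tidy
parameter table, CV curve, template CSVs, TANOVA report, and group
statistics (`statistics.json`), all stamped with the config hash and seed.

The same pipeline is scriptable from the shell:

```bash
msdual simulate --seed 1 --duration 300 --out cohort/   # EDF+ + sidecars
msdual cluster cohort/sub-*.edf --k 4 --out template/
msdual backfit cohort/sub-00_HC.edf --template template/template.csv --out fit/
msdual run-all --config config.yaml --seed 1 --out out/
```

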