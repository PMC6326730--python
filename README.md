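# dfcengage

Tracking short-term task engagement from whole-brain dynamic functional
network connectivity (dFC).

## The problem

During a continuous multi-task fMRI scan (rest, 2-back working memory,
mental math, visual search; 120-TR blocks, TR = 1.5 s), the correlation
structure among brain components fluctuates at the scale of tens of seconds.
Windowed connectivity patterns are known to identify *which* task a person
is doing; this package implements the next question: do they also track
*how engaged* the person is, window by window?

The analysis:

1. estimates dFC as windowed Pearson correlations of 61 IC time courses
   (non-overlapping 45-s windows, Fisher z, 61·60/2 = 1,830 links),
   after motion regression, a 0.0222–0.18 Hz zero-phase band-pass, and a
   4-TR hemodynamic shift;
2. clusters each subject's 32 window vectors with correlation-distance
   k-means (k = 4, k-means++, best of 100 restarts) and labels clusters by
   the optimal bijection onto the tasks — giving a high-engagement (HE)
   centroid per task and the rest centroid as the low-engagement (LE)
   pattern;
3. derives three per-window engagement markers:
   *dist*(dFC, HE) = 1 − r(window, HE centroid), *dist*(dFC, LE), and the
   mean participation coefficient
   **B_T = mean_i [1 − Σ_s (κ_is/κ_i)²]** over a Louvain + consensus
   partition of each window's graph (positive weights);
4. relates markers to windowed behavior (mean RT, response accuracy,
   missing rate) with a crossed random-intercept linear mixed model
   y = β₀ + β₁·marker + β₂·FD + u_subject + v_window + ε, fit by ML with
   likelihood-ratio p values, plus Spearman screens and link-wise HE−LE
   one-tailed t contrasts at BH q < 0.01.

The expected signature, which the synthetic experiments reproduce, is:
windows closer to the task's HE pattern (and farther from the rest
pattern), and more globally integrated windows, accompany better
performance — positive t for dist_HE vs RT, negative for dist_LE vs RT,
positive for B_T vs accuracy.

A synthetic-data module generates full cohorts (component time series,
behavioral events, motion) in which a latent engagement process — a
logistic-squashed Ornstein–Uhlenbeck level e(t) ∈ [0,1] — jointly drives
the connectivity state (a convex blend between task and rest covariance)
and behavior (slower RTs, more misses and errors as e falls), so every
stage of the pipeline is exercisable and testable without any scan data.

## Worked example

Simulate a small cohort and run the full pipeline:

```bash
dfcengage simulate --seed 3 --n-subjects 6 --out cohort/
dfcengage run-all --seed 3 --input cohort/ --out results/
```

which prints

```
wrote 6-subject cohort to cohort
mean clustering accuracy: 0.7969
results written to results
```

`results/` then contains `long_table.csv` (one row per subject × task
window with dist_he, dist_le, b_t, behavior, FD), `lme_results.csv` (one
row per task × marker × outcome with estimate, t, LRT p), the per-task
HE−LE contrast link lists, the Spearman screen, per-subject clustering
accuracies, and a `manifest.json` recording config and seeds.  A mean
clustering accuracy of ~0.80 says that for a typical simulated subject
about 25 of 32 windows are assigned to the correct task state purely from
connectivity — engaged windows cluster cleanly, disengaged windows drift
toward the rest state, which is exactly the gradient the markers exploit.

In Python, the same experiment is:

```python
from dfcengage import synthdata, pipeline
from dfcengage.config import RunConfig

cfg = RunConfig()                       # study defaults: WL=30 TRs, k=4, ...
states = synthdata.make_state_covariances(seed=1)
paradigm, records = synthdata.simulate_cohort(6, states=states, seed=3)
subjects = [{"subject_id": r.subject_id, "timeseries": r.timeseries,
             "events": r.events, "motion": r.motion} for r in records]
result = pipeline.run_cohort(paradigm, subjects, cfg)
print(result.lme_table.query("task == 'memory'")
      [["marker", "outcome", "t_value", "p_value"]])
```

## Layout

| Module | Contents |
| --- | --- |
| `dfcengage.paradigm` | block schedule, window segmentation, behavioral windowing |
| `dfcengage.synthdata` | covariance states, engagement process, cohort simulation |
| `dfcengage.signal_prep` | motion regression, band-pass, hemodynamic shift |
| `dfcengage.dfc` | windowed Fisher-z connectivity, link vectorization, QC |
| `dfcengage.clustering` | correlation-distance k-means, labeling, distance markers |
| `dfcengage.graph` | Louvain, consensus clustering, participation coefficients |
| `dfcengage.stats` | crossed random-intercept LME + LRT, Spearman, HE−LE contrasts |
| `dfcengage.config` / `io` / `pipeline` / `cli` | configuration, file formats, orchestration, CLI |

See `docs/methods.md` for the model details, parameter defaults and their
rationale, and known limitations.
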