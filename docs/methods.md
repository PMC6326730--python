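# Methods

`dfcengage` implements an engagement-tracking analysis of whole-brain dynamic
functional network connectivity (dFC), together with a synthetic cohort
generator that reproduces the statistical structure the analysis assumes.
This note records the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic experiments do and do not show.

## The experiment being modeled

A continuous multi-task scan: four conditions (rest, 2-back working memory,
mental arithmetic, visual search "video"), each presented twice as 120-TR
blocks (TR = 1.5 s, 180 s per block) in randomized order with the constraint
that no task directly follows itself, separated by 8-TR instruction periods.
Behavioral events arrive on task-specific grids (memory: one trial / 3 s,
60 per block; math: one / 5 s, 36 per block; video: one / 11.25 s, 16 per
block), each trial either answered (with a reaction time and a correctness
flag) or missed.  The analysis consumes component (IC) time courses — here
61 components by default — not voxel data; volume-level preprocessing and
the spatial ICA that produces the components are out of scope.

## Analysis pipeline

1. **Signal prep** (`signal_prep`): motion-parameter regression (6 rigid-body
   parameters plus first differences, with intercept; OLS residuals), then a
   zero-phase band-pass Butterworth filter, 0.0222–0.18 Hz of overall order 6
   (scipy `butter(3, ...)`), applied forward–backward with reflect padding
   (100 samples).  The low cut equals 1/WL = 1/45 s, the standard rule tying
   the slowest retained fluctuation to the analysis window; the high cut
   stays below task motor-response rates.  Zero-phase filtering was chosen
   because a causal pass would add a group delay on top of the explicit
   hemodynamic shift; the alternative (causal, as acquisition-time software
   sometimes does) would shift all bands by a few seconds and is not exposed.
2. **Windowing** (`paradigm`): non-overlapping 30-TR (45 s) windows anchored
   at block onset + 4 TRs (6 s hemodynamic shift), truncated to the block:
   floor(120/30) = 4 windows per block, 32 per subject, 8 per task.  TRs left
   at a block end (120 mod WL) are discarded.  Trials are assigned to windows
   by un-shifted stimulus-onset time — the shift aligns the *signal* to
   stimulus time; behavior is already in stimulus time.
3. **dFC estimation** (`dfc`): per window, Pearson correlation across the
   window's TRs for each component pair, clipped to ±(1 − 10⁻⁶), Fisher
   z-transformed, and vectorized to the C(C−1)/2 upper-triangle links
   (61 components → 1,830 links).  A component with zero variance inside a
   window contributes r = 0 for its pairs, keeping the link dimension fixed.
   A low-variability screen flags subjects whose mean pairwise correlation
   among window vectors exceeds 0.95 (config-exposed; the screen models the
   exclusion of subjects whose dFC carries no dynamic information).
4. **State extraction** (`clustering`): per-subject k-means with k = 4 and
   correlation distance d(x,c) = 1 − Pearson(x,c), k-means++ seeding, up to
   1,000 iterations, best of n_init = 100 restarts by total distance.
   Implementation: rows are centered and scaled to unit norm, after which
   the normalized cluster mean is the exact minimizer of the within-cluster
   distance sum (spherical k-means); inertia is asserted non-increasing
   across iterations, and an emptied cluster is re-seeded at the point
   farthest from its centroid.  Clusters are labeled by the
   agreement-maximizing bijection onto the four tasks (Hungarian assignment
   on the cluster × task confusion matrix).  A bijection — rather than
   per-cluster majority vote — guarantees every task owns exactly one
   centroid even for poorly clustered subjects, so the engagement markers
   below are always defined.  Clustering accuracy is the fraction of windows
   whose mapped cluster task matches the paradigm.
5. **Engagement markers**: for each task window, dist_HE = correlation
   distance to the centroid labeled with that window's task
   (the task's high-engagement pattern), dist_LE = distance to the
   rest-labeled centroid (the low-engagement pattern), and B_T, the mean
   participation coefficient (below).  Rest windows are not marker rows.
6. **Graph metrics** (`graph`): each window's z-matrix is a weighted graph;
   negative weights are zeroed (the participation coefficient is defined on
   positive strength, and modularity on signed graphs has several competing
   conventions).  Louvain community detection (python-igraph, resolution
   γ = 1) is repeated n_reps = 500 times per window; a consensus partition
   re-clusters the thresholded co-assignment matrix (τ = 0.5) until it is
   block-constant.  Per node i, B_i = 1 − Σ_s (κ_is/κ_i)², κ taken over
   positive weights; a node with zero positive strength gets B_i = 0.
   B_T is the node average.  Graphs are built in z-space (monotone in r, so
   detected modules agree; an r-space switch exists in config).  The window
   index is mixed into the Louvain seed stream so repetitions differ across
   windows while the whole run is reproducible.
7. **Group statistics** (`stats`): the long table (one row per subject ×
   task window) is analyzed per task with the linear mixed model
   y = β₀ + β₁·marker + β₂·FD + u_subject + v_window + ε, with crossed
   random intercepts (all subjects traverse the same block order, so window
   is a crossed factor), fit by maximum likelihood — not REML, because the
   p value is a likelihood-ratio test between fixed-effect specifications,
   which is valid only under ML.  The marginal likelihood is profiled over
   the fixed effects and the residual variance and optimized over the two
   log variance ratios; the Woodbury identity reduces each evaluation to the
   (n_subjects + n_windows)-dimensional space, so a fit costs milliseconds.
   Windowed framewise displacement (sum of absolute first differences of
   the six motion parameters) is a fixed effect in both the full and the
   reduced model.  Variables are z-scored before fitting (an unstandardized
   mode exists for parameter-recovery simulations).  The reported t is
   β̂₁/SE(β̂₁) from the full fit with residual degrees of freedom
   (rows − fixed effects).  Rows with no responded trials have no RT and are
   dropped listwise per outcome.  The implementation is cross-checked
   against R lme4 (ML) in the test suite and agrees to ~10⁻⁴.
   Two further analyses: Spearman correlation (mid-rank ties) of per-subject
   clustering accuracy with subject-mean behavior, Benjamini–Hochberg
   corrected across the full task × metric family (the family choice is
   config-exposed); and link-wise one-sample one-tailed t tests on
   per-subject HE − LE centroid differences, BH-corrected across the 1,830
   links within each direction and thresholded at q < 0.01.

## Synthetic cohorts

The generator (`synthdata`) is first-class, tested code; it defines the
study conditions under which every property of the pipeline is demonstrated.

**Covariance states.** One correlation matrix per task plus a rest matrix.
Each task state places the components into 4 modules by a task-specific
random partition with within-module correlation 0.6 and a between-module
background of 0.35; the rest state uses its own partition with within 0.6
and between 0.  Two things follow: tasks are mutually distinguishable
(different partitions), and task states are more globally integrated than
rest (positive between-module background versus none), so integration rises
with engagement.  Positive semidefiniteness holds by construction and is
additionally repaired, if ever needed, by eigenvalue clipping followed by
correlation rescaling.

**Engagement.** A latent per-TR engagement level e(t) ∈ [0,1], generated as
a logistic-squashed Ornstein–Uhlenbeck process (mean 0.95, reversion 0.05
per TR, innovation SD 0.31 on the latent scale), giving mean engagement
≈ 0.72, a marginal SD of ≈ 0.2, and an autocorrelation time of ≈ 20 TRs
(30 s) — fluctuations at the tens-of-seconds scale the windowed analysis
targets.  Each subject's set-point is offset by N(0, 0.5) on the latent
scale, creating between-subject variance for the random intercepts.  No
empirical estimate of engagement autocorrelation exists to calibrate
against; these values were chosen once so that (a) a typical subject's task
windows are separable from rest (clustering accuracy at the planted-state
check ≈ 0.9+) while (b) enough windows visit intermediate engagement for
the markers to have dynamic range.  Both are exposed in config.

**Observations.** During a task block the series at TR t is drawn from
N(0, Σ) with Σ = e·Σ_task + (1−e)·Σ_rest (a convex combination of PSD
matrices, hence PSD); rest blocks, instruction gaps and the end padding use
Σ_rest.  The generator applies a 4-TR hemodynamic delay (state at t drives
the signal at t + 4), which the pipeline's shift-anchored windows undo.
Optional AR(1) smoothing and white observation noise exist and default off.

**Behavior.** Trials follow each task's grid.  RT is lognormal noise
(σ = 0.15) around baseline_task + 0.5·(1−e); misses and errors are
Bernoulli with logit-linear dependence on (1−e) (slopes 3 and 6).
Baselines are set so that at typical engagement the per-task means
approximate the observed ones (RT ≈ 1.0/2.3/1.3 s, missing ≈ 13/2/30 %,
accuracy ≈ 93/94/67 % for memory/math/video).  Subjects get an RT offset of
N(0, 0.2 s).

**What the generator does not emulate:** hemodynamic forward modeling
(signals are Gaussian draws, not convolved neural events), scanner noise
spectra and drifts, spatial maps, trial-difficulty structure (the observed
math/video confounds), or any engagement–connectivity coupling beyond the
two-state convex blend.  Passing tests therefore demonstrate that the
pipeline recovers the modeled couplings at realistic sizes and noise — not
that real data contain them.

## Problem sizes in tests and the acceptance script

Full-default runs (61 components, 24 subjects, 100 k-means restarts, 500
Louvain repetitions) are what the CLI executes.  The test suite and
`scripts/acceptance.py` use scaled runs chosen as the smallest sizes at
which the demonstrated effects are stable: cohorts of 16 subjects at 61
components with 10 k-means restarts and 24 Louvain repetitions per window
for the directional-marker checks; 10 single-subject replicates for state
recoverability; 24 subjects × 8 windows with 50 recovery and 500 null
replicates for LME calibration.  Effect parameters are never changed from
the defaults above.

## Numerical conventions and edge cases

- 0-based TR indices; half-open [start, end) windows; events in seconds.
- Correlations clipped at |r| = 1 − 10⁻⁶ before atanh.
- k-means requires at least k distinct vectors; determinism comes from a
  single integer seed feeding k-means++ and the restart stream.
- Louvain seeds derive from Python's `random` module (igraph's RNG);
  consensus iterates at most 50 outer rounds and warns if not converged.
- LME variance components are parameterized on the log scale (hence ≥ 0);
  boundary fits appear as ratios ~e⁻³⁰.  Five optimizer starts cover
  subject-only, window-only, both-small and both-moderate regimes.
- The LRT statistic is floored at 0; nesting violations beyond tolerance
  are logged.
- Degenerate inputs (constant marker vectors, zero-variance links,
  all-missed windows, subjects failing QC) degrade to warnings and flagged
  missing values rather than errors wherever the group analysis can proceed.

## Known limitations

- The consensus-clustering threshold τ, resolution γ, QC threshold, and the
  FDR family for the Spearman screen have no empirical anchors; all are
  config-exposed defaults.
- Single-run Louvain can land in local optima on near-degenerate graphs;
  the pipeline always uses consensus over repetitions, but the raw
  `louvain` call makes no optimality guarantee.
- dist_HE is a distance to a centroid that itself averages windows of mixed
  engagement, so its coupling to behavior is intrinsically weaker than
  dist_LE's (the rest centroid sits at the low-engagement extreme); the
  synthetic experiments reproduce exactly this asymmetry.
- Reported t degrees of freedom are residual df, not Satterthwaite; with a
  few hundred rows the practical difference is negligible.
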