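# Methods

This note documents the models and procedures implemented in
`microstates`, the choices made where the design was genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## The microstate model

Resting-state EEG alternates between a small number of quasi-stable scalp
potential topographies ("microstates"), each persisting for roughly
60–120 ms before switching. Clinical work conventionally uses four
classes, labeled A–D: two with diagonal axis orientations (A, B), one with
an anterior–posterior orientation (C), and one with a fronto-central
extreme (D). The analysis treats a topography and its negation as the same
state — polarity carries no class information — so every comparison between
maps is made polarity-invariant, either through squared spatial
correlation or by taking absolute values.

Key quantities:

- **GFP** (global field power): the population (1/N) standard deviation of
  the potential across electrodes at one sample. For average-referenced
  data this equals the Euclidean norm of the sample divided by √N.
  Topographies at local GFP maxima have the best signal-to-noise ratio and
  are the ones clustered.
- **Spatial correlation**: Pearson correlation between two maps across
  electrodes.
- **GEV** (global explained variance): for maps x_t with weights GFP_t
  assigned to templates, GEV = Σ_t (GFP_t · corr_t)² / Σ_t GFP_t². This is
  the objective the clustering maximizes and the figure of merit reported
  with every fit.

## Modified k-means

Assignment labels each map with the template of maximal squared spatial
correlation (ties to the lowest class index); the update replaces each
template by the dominant spatial pattern of its assigned maps — the
leading eigenvector of X'X, which is polarity-blind. With unit-GFP
templates, both steps monotonically increase GEV, which the implementation
asserts per iteration (the `gev_trace` attribute). Defaults: 20 restarts,
convergence at 1e-6 relative GEV change, 100 iterations per restart. Empty
clusters are re-seeded from the currently worst-represented map. The
normalized sign-aligned mean update is a cheaper near-equivalent; the
eigenvector form is used because it is exactly sign-blind and makes the
monotonicity argument exact.

Two-level clustering mirrors the individual→group protocol: each subject's
GFP-peak maps (normalized to unit GFP, weighted by their original GFP) are
clustered with k = 4; each subject then contributes exactly its k unit-GFP
templates — ranked by per-class GEV contribution, all k contributed, so
every participant carries equal weight — to a second modified k-means that
yields the group template set. Per-subject seeds are spawned from the
master seed with `np.random.SeedSequence(seed).spawn(...)`, so individual
fits can be reproduced in isolation.

Template alignment solves the assignment problem maximizing summed
|spatial correlation| over all permutations (Hungarian algorithm), then
re-signs and relabels. A synthetic canonical template set (two diagonal
maps, one anterior–posterior, one fronto-central Gaussian bump, built on a
standard 64-electrode layout) ships for conventional A–D labelling; it is
an idealized geometric stand-in, not an empirical group map, and can be
overridden.

## Backfitting and smoothing

Competitive fitting labels every sample (not only peaks) by maximal
|spatial correlation|; zero-variance samples inherit their predecessor's
label and are counted in the diagnostics. Smoothing follows a Besag-style
penalty: iteratively relabel sample t to maximize
corr²(t, class) + λ·N_b(t, class), where N_b counts same-class labels
among the 2b neighbors (truncated at the boundaries) under the previous
sweep's labels. Sweeps are synchronous and deterministic; a fixed point or
a detected 2-cycle (a known artifact of synchronous updates) ends the
iteration, the latter with a non-convergence flag. Afterwards 1-sample
segments are merged into the temporal neighbor whose template correlates
better at that sample (ties to the earlier neighbor) until none remain.
Defaults mirror the protocol at 128 Hz: b = 5, λ = 10, rejection on. The
fit term is plain squared correlation (unweighted); a GFP-weighted variant
was considered and rejected because backfitting itself is
correlation-based.

Note that with λ = 10 the neighbor term dominates the fit term (which
lives in [0, 1]), so smoothing acts as an iterated local majority filter:
it removes segments much shorter than the window and, by design, shifts
the duration distribution upward. This is intended behavior — the
rejection of one-frame states is explicitly part of the protocol — but it
means smoothed durations are not unbiased estimates of the pre-smoothing
segment lengths (on clean synthetic data, smoothing inflates mean
durations by roughly 70–100% by absorbing the short-segment mass of the
geometric dwell-time law). Parameter-recovery experiments therefore score
the unsmoothed competitive fit, which at the simulated noise level agrees
with the planted labels essentially perfectly; the smoothing branch is
validated by its own contracts (segment-count reduction, absence of
1-frame runs, identity at λ = 0).

Temporal parameters per class: mean duration (ms) = mean maximal-run
length × 1000/fs; coverage (%) = class samples / total samples × 100;
occurrence (1/s) = run count / total seconds. Truncated first/last runs
are included. The three are linked by the exact identity
occurrence × mean duration / 1000 = coverage / 100, which holds for every
segmentation and is asserted property-style in the tests.

## Synthetic data

The generator plants a semi-Markov process: the class sequence is a Markov
chain with zero self-transitions (uniform off-diagonal by default — no
empirical transition probabilities are available to emulate), and each
visit draws a dwell time from a geometric law on {1, 2, ...} samples with
mean equal to the class's requested mean duration (the simplest law with a
controllable mean and a 1-sample floor). The signal at sample t is the
active class's unit-GFP template scaled by an amplitude profile —
sinusoidal with ~100 ms period and depth 0.5 by default, so the GFP
possesses peaks for the clustering stage; a constant profile is available
but peak-less. Sensor noise is spatially white Gaussian projected onto the
average-reference subspace (no temporal 1/f shaping by default) and scaled
so that mean-GFP(signal)/mean-GFP(noise) equals the requested SNR; the
GFP-based definition matches the pipeline's own geometry. The default SNR
of 2 corresponds to a GEV around 80%, the explained-variance regime
reported for real resting-state recordings.

What the simulation does *not* emulate: volume-conduction-realistic
topographies, eye/muscle artifacts, non-stationary amplitude dynamics,
temporally correlated noise, inter-subject topographic variability.
Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated generative model, not robustness to real-world
artifacts.

Default study-scale conditions used in the recovery experiments (and in
`scripts/acceptance.py`): 10 subjects, 64 electrodes, 128 Hz, 5 minutes,
planted durations 60/80/100/120 ms, SNR 2. Smaller fixtures (16
electrodes, 30 s) are used in unit tests.

## Preprocessing

Band-pass (default 1–40 Hz) via zero-phase FIR (firwin + filtfilt; ~3.3
cycles of the lower edge as filter length) after polyphase resampling to
the target rate (anti-alias filtering included); output length is
floor(n · target/fs). Average-referencing is idempotent. The artifact
pipeline of real studies (ICA, bad-channel interpolation) is out of scope
and represented only by the ability to pass through already-clean data.
GFP peaks are strict local maxima; a plateau flanked by smaller values
yields its first index, endpoints are never peaks, and no minimum
inter-peak distance is imposed.

## Group statistics

- Chi-square for 2×2 tables is Pearson's, without continuity correction
  (the convention that reproduces published demographic statistics); the
  Yates flag exists but is off.
- The mixed-design ANOVA is a two-stratum split-plot GLM with Type III
  sums of squares under sum-to-zero coding. Between-subject terms (all
  interactions among between factors, covariates as main effects) are
  tested on subject means against the subject error; the within factor and
  its interactions with every between term and covariate are tested on
  subject-centered data against the subject × within residual. For the
  reference layout (2 groups × gender, education covariate, 176 subjects,
  4 classes) this yields the df pattern (1, 171) between and (3, 513)
  within. No sphericity correction is applied. Both classical η²
  (SS/total SS) and partial η² are reported; the 90% CI inverts the
  noncentral-F distribution at the observed F.
- Holm correction is the step-down procedure with a running maximum and
  cap at 1, returning values in input order; the family size may exceed
  the list length.
- Effect sizes: Cohen's d (pooled-SD independent, and one-sample on
  difference scores) with normal-approximation CIs; η²→d via
  d = 2√(η²/(1−η²)); Bayes factors via the BIC approximation
  BF01 = exp((BIC_alt − BIC_null)/2) — the exact default-prior (JZS)
  integration is deliberately out of scope.

## Meta-analysis

Hedges' g = J·d with J = 1 − 3/(4df − 1),
var_g = J²((n1+n2)/(n1 n2) + d²/(2(n1+n2))). τ² is estimated by REML:
Fisher scoring on the analytic restricted-likelihood score with the
expected information, floored at 0, safeguarded by Brent root-finding on
the score; convergence tolerance 1e-10. Pooling uses inverse-variance
weights 1/(v_i + τ²), normal-quantile 95% CIs, and z-tests — no
Knapp–Hartung adjustment, matching the common meta-analysis software
default. p-values across the 12 parameter × class cells are Holm-corrected
jointly. Cells with a single study are pooled with τ² = 0 (the pooled row
reproduces the study row); cells absent from the input are absent from the
output rather than fabricated.

## Numerical choices and degenerate inputs

- Zero-variance maps are rejected by `spatial_correlation` and skipped
  (correlation 0) in the vectorized matrix path; zero-variance samples in
  backfitting inherit the predecessor label.
- Tie-breaks are everywhere "lowest class index" / "earlier neighbor",
  making every stage deterministic.
- Eigenvector sign in the k-means update is fixed by positive correlation
  with the previous template.
- All randomness flows from explicit seeds; per-subject and per-stage
  seeds derive from a master seed through `SeedSequence.spawn`.

## Known limitations

- The smoothing penalty follows one defensible reading of windowed
  Besag-style relabeling; other implementations normalize the penalty
  differently, so smoothed parameter values are comparable only within a
  fixed configuration.
- The split-plot engine requires complete, balanced within-factor data
  (no missing cells) and rejects rank-deficient designs instead of
  dropping aliased terms.
- The BIC Bayes factor is an approximation; it agrees with default-prior
  Bayes factors only in order of magnitude.
- EDF/BDF export is not implemented (reading is); the text matrix +
  sidecar format is the canonical interchange.
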