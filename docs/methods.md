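# Methods

`mazemvpa` implements a complete multi-voxel pattern analysis (MVPA)
pipeline for decoding three stimulus categories (faces, buildings, animals)
from fMRI time series, in two regimes: a *paced* session in which stimulus
timing is fully controlled, and a *self-paced* mental-imagery session in
which event number, order and duration are generated by the subject, with
class imbalance as the result. Because no raw scanner data accompany this
problem, the package ships a forward simulator whose outputs drive every
test; this note records the models, conventions and numerical choices, and
what the synthetic results do and do not establish.

## Synthetic sessions

**Exploration (paced).** Three blocks of 27 stimuli — 9 faces, 9 buildings,
9 animals, always in that order — each shown 3 s with no gap inside a
block, blocks separated by 15–18 s fixation (uniform), the whole traversal
repeated five times; TR = 2.04 s. The default design therefore has 15
blocks and 135 events per category. An optional inter-stimulus interval
(`isi`) produces a slow-event-related variant used as a *separable control
condition*: in the paced design the haemodynamic responses of adjacent
categories overlap at stretch boundaries, so roughly 15 % of event windows
intrinsically carry the next category's rising response and perfect
decoding is unattainable at any effect size. That overlap is a property of
the design, not a bug: the paced session is deliberately hard.

**Mental imagery (self-paced).** 54 recall paths, one category per path,
categories balanced across paths, path lengths cycling through 3–6 so the
planned image count per category is identical (mean 4.5). Each planned
image is recalled with a category-specific probability — default
(1.0, 0.65, 0.93) for (faces, buildings, animals) — which is the imbalance
mechanism; these defaults reproduce the observed behavioural proportions of
roughly 39/25/36 %, with buildings the minority class. Event durations are
drawn log-uniformly from 0.2–4 s (so most events last under 2 s), the key
press falls at the event end, consecutive events are separated by a 0–0.5 s
jitter, and paths group into blocks of 6 for cross-validation. Recall
failures consume no time.

**Forward model.** Per-category boxcars are convolved with a canonical
double-gamma haemodynamic response (gamma shapes 6 and 16, undershoot ratio
1/6, unit peak) on a 20x oversampled grid and sampled at scan midpoints.
Voxel amplitude maps assign `effect_size` (in units of the noise standard
deviation) to `n_informative` voxels per category, with optional pairwise
overlap. Noise is the sum of slow cosine drifts (removed by the high-pass),
six smoothed random-walk motion series coupled into voxels by random
loadings (the motion series are returned and play the role of realignment
parameters), and AR(1) Gaussian noise (default marginal SD 1, lag-one
coefficient 0.3 — the minimal temporally correlated model; the data this
emulates were not noise-characterized). A convolution of a 3 s boxcar with
this response peaks 6.6 s after onset, which is why a 6 s window delay is
the appropriate correction.

What the simulator does **not** emulate: spatial structure (no smoothness,
no anatomy, no scanner artifacts, no slice timing), non-stationary noise,
and any behaviour-signal coupling beyond the recall probabilities. Passing
tests therefore demonstrate correctness of the pipeline's statistics and
its qualitative robustness properties, not performance on real scanner
data.

## Signal extraction

The full-session series is first residualized on an intercept, the six
motion series (standardized) and a discrete-cosine high-pass basis with
cutoff 1/128 Hz (`floor(2*T*cutoff)` columns; 9 for a 612 s session), by
ordinary least squares; a rank-deficient confound matrix degrades to a
pseudo-inverse fit with a warning. Confound regression happens once, before
epoching.

Paced events average the scans whose acquisition *midpoints* (k·TR + TR/2)
fall in `[onset + 6 s, onset + 9 s)` — window length equals the 3 s
stimulus duration. Self-paced events average scans whose acquisition *span*
overlaps the delay-corrected interval between consecutive key presses,
truncated to the last 2 scans (4.08 s) before the delay-corrected key
press; a scan whose span overlaps two events' intervals is excluded from
both, so no TR ever mixes stimuli, and events left with no scans produce no
sample (drops are recorded so class counts stay auditable). The midpoint
vs. span distinction is deliberate: paced windows are half-open and
non-overlapping by construction, while self-paced intervals abut and the
span rule is what makes the two-stimuli-per-TR exclusion meaningful. All
window conventions are half-open, times in seconds, scan indices 0-based.

## Feature selection

**GLM filter.** An omnibus F statistic per voxel tests the joint effect of
the three categories. Two equivalent routes exist: on the time series
(HRF-convolved category regressors against a confound-plus-intercept null
model) and on extracted samples (one-way F across the class labels). The
pipeline uses the sample route inside cross-validation folds because it
restricts cleanly to training samples and stays consistent under label
permutation; the series route is provided and tested for session-level
maps. Two voxel sets are derived: *global* — every voxel with F strictly
above 0.5 — and *specific* — the k largest-F voxels (k = 1000 at brain
scale; scaled to half the simulated voxel count in the analyses here, which
preserves the filter's role of passing a superset of the informative
voxels). Boundary ties break toward the lowest index.

**Recursive Feature Addition (RFA).** A forward wrapper: for each binary
comparison a linear SVM (C = 1) is trained on the (inner-)training samples
and voxels are ranked by |weight|, the sign splitting them into the two
condition lists (zero weights rank with the positive list; ties break by
lowest index). For n in the grid 5, 30, 55, 80, 105, 130, 150 — increments
of 25 capped at 150, since the stated bounds are not commensurate — each
comparison's model uses the top-n positive plus top-n negative voxels, and
the *global accuracy* at n is the sum over the three comparisons of
held-out accuracy in an inner leave-one-block-out loop, averaged over all
inner folds (the lower-variance reading; a single inner fold is the other
defensible one). The grid stops as soon as the current value is strictly
below **both** of the two preceding values; the selected n is the argmax
over evaluated iterations, and the final voxel set re-ranks on the full
outer-training data at that n (union over comparisons). RFA requires at
least three blocks so the inner loop has a training side.

## Classifiers

**SVM.** Standard soft-margin C-SVC with a linear kernel and fixed C = 1,
solved by libsvm via scikit-learn; the model exposes the primal weights
(for RFA ranking), bias, support-vector indices and dual coefficients (for
the SV-proportion diagnostics). A decision value of exactly zero maps to
+1. An iteration cap of 2·10⁵ guards against SMO cycling on degenerate
inputs (for example zero-variance features under permuted labels); it never
binds on healthy fits. Tests verify the dual objective against a dense
quadratic program and the KKT conditions at 1e-6.

**Gaussian process with Expectation Propagation.** A zero-mean GP prior
with inhomogeneous linear covariance k(x, x′) = σ²⟨x, x′⟩ + σ₀², both terms
tied to the single hyperparameter σ (σ₀² = σ²), probit likelihood, and the
standard sequential EP approximation: per-site cavity/moment-matching
updates with rank-one posterior updates, a full Cholesky recomputation
after every sweep, convergence when the largest site-parameter change in a
sweep falls below 1e-4 (cap 100 sweeps, non-convergence recorded on the
model and warned at prediction). Site precisions are clamped nonnegative;
improper cavities are skipped for that sweep. The EP log marginal
likelihood uses the numerically robust cavity form, and log σ (initialized
at 1) is by default refined by bounded scalar maximization of that marginal
(12 iterations, tolerance 0.05 on log σ — the kernel enters only as σ²·K₀,
so the base kernel is computed once); a flag disables the refinement. On
three-point problems the EP marginal agrees with exact tensor-quadrature
integration to better than 0.005 nats.

**Kernel centering.** Training kernels are double-centered (H K H).
Test-vs-train blocks are, by default, centered *independently* with their
own row/column means — an unusual convention kept deliberately, with one
documented consequence: a single-row test block centers to zero, so a lone
test point always receives probability 0.5. The pipeline always predicts a
whole held-out block at once, where the convention behaves sensibly; the
conventional train-statistics centering is available as `centering="train"`
and used in robustness tests.

## Multiclass assembly (ECOC)

Three binary comparisons (F-B, F-A, B-A; first-named class positive) vote
for each test point. With SVM votes, the class codewords are
faces (1, 1, 0), buildings (−1, 0, 1), animals (0, −1, −1) and the decision
is minimal Hamming distance, where *any* mismatch counts — including a ±1
vote against a 0 entry (the plain reading, and the one that recovers the
winner on consistent votes). With GP probabilities — oriented as
P(first-named class) — the codewords are faces (1, 1, 0.5),
buildings (0, 0.5, 1), animals (0.5, 0, 0) and the distance is the sum of
absolute differences. For hard votes mapped to probabilities, the
probability distance decomposes as 1 per opposite-sign mismatch plus 0.5
per zero-entry mismatch, so the two schemes agree on consistent votes but
weight inconsistencies differently. Exact distance ties are broken
uniformly at random from a seeded generator and flagged, keeping
permutation nulls unbiased.

## Evaluation and inference

Five procedures combine the pieces: P1 specific+SVM, P2 specific+GP, P3
global+RFA+GP, P4 specific+RFA+GP, P5 specific+RFA+SVM. Cross-validation is
leave-one-block-out (a block is 27 consecutive paced stimuli, or the events
of 6 consecutive recall paths — 15 and 9 folds for the default designs),
with the same fold sequence for every procedure; RFA procedures nest the
inner loop strictly inside the outer-training set. A training set missing a
class skips that fold with a logged warning.

The headline statistic is **balanced accuracy** — the unweighted mean of
per-class accuracies, chance 1/3 — computed from the confusion matrix
pooled over folds (robust when small imagery folds miss a class; per-fold
values are also stored). Significance comes from within-block label
permutation: each of 100 replicates draws one independent permutation per
block (preserving per-block class frequencies, hence respecting the
temporal correlation structure), reruns the entire procedure *including
feature selection* with permuted training labels (test labels untouched),
and pools fold confusions into one subject-level null value; replicates are
paired across folds rather than pooled fold-wise, because the observed
statistic is subject-level. p = (1 + #{null ≥ observed}) / (1 + 100) — the
finite-sample correction keeps p positive. The default designs perform
100 x 15 = 1500 (exploration) and 100 x 9 = 900 (imagery) label shufflings.

Group-level comparisons are rank-based throughout: Friedman tests
(tie-corrected chi-square; a table whose rows are all internally constant
returns the null result (0, 1)), paired Wilcoxon signed-rank tests with
zeros dropped, exact null for n ≤ 25 without ties and the normal
approximation otherwise, Bonferroni families of 3 (category post-hocs) or
10 (procedure pairs), and Spearman correlations (mid-ranks,
t-approximation). The SV-proportion analysis reports the full 3 x 3
Spearman grid between per-comparison support-vector class shares and class
accuracies, with signs for consistency inspection.

## Problem sizes and calibrated study conditions

Tests and the acceptance script scale the simulations to a single CPU:

* separable control: 2 traversals (6 blocks, 162 events), 150 voxels,
  12 informative per category, effect 2, zero noise, isi 9 s;
* chance-level runs: 2 traversals, 150 voxels, labels globally shuffled,
  20 seeds;
* RFA recovery: 2 traversals, 800 voxels, exactly 30 informative per
  category, effect 0.05 — a regime where accuracy rises up to n = 30 and
  the dilution penalty is measurable; the selected n per condition lands in
  {30, 55} in roughly 85–95 % of seeded replicates (31/35 across the seed
  sets measured during development);
* imbalanced imagery: 54 paths, 300 voxels, 20 informative per category,
  effect 0.04 — calibrated once so the SVM reference procedure reaches a
  balanced accuracy near 0.7, the intended moderate-separability regime —
  where the GP-based two-level procedure (P4) beats the SVM reference (P1)
  on minority-class (buildings) accuracy in about 85 % of replicates.

The specific filter's k scales with the simulated voxel count (150 of 300)
to preserve its superset-passing role; C, the F-threshold, the RFA grid,
the HRF delay, the high-pass cutoff and n_perm keep their full-scale
values.

## Known limitations

* The EP σ-refinement uses a coarse bounded search; marginal-likelihood
  plateaus can leave σ a few percent from the optimum (immaterial for
  classification).
* Independent test-kernel centering makes single-point predictions
  uninformative (see above); this is faithful to the stated convention, not
  a recommendation.
* The sample-route F map assumes confounds were removed before epoching; if
  extraction is run on raw series the filter absorbs drift variance.
* Under heavy label permutation the libsvm iteration cap can truncate
  degenerate fits; the affected fits are chance-level either way.
* The imagery extraction discards a substantial fraction of very short
  events through the shared-TR exclusion rule (as the averaging-window
  design implies); recall-probability defaults were set at the design
  level, so extracted-sample imbalance is slightly noisier than the
  behavioural table it emulates.
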