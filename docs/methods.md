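# Methods

## Signal model and synthetic cohorts

A recording is modelled as `y(t) = s(t) + (h ∗ q)(t) + ε(t)`: a tonic skin
conductance level `s`, a phasic part equal to a biexponential kernel `h`
convolved with a sparse nonnegative sudomotor driver `q`, and white
Gaussian noise `ε`. The generator builds each synthetic subject from this
model over the five-phase protocol (REST, MAT, REC1, RLX, REC2; 300 s per
phase; 256 Hz native rate, both configurable):

- **Tonic**: group mean level plus an integrated Gaussian random walk
  (`tonic_drift_sd` µS per √s, smoothed with a 2-s Gaussian kernel so the
  curve is slow by construction) plus a stress envelope that rises
  exponentially during MAT (15-s time constant) and relaxes from REC1
  onward (60-s constant). The envelope amplitude is
  `(reactivity_gain − 1) × 1 µS`, tying tonic reactivity and SCR-rate
  reactivity to one knob.
- **Phasic**: homogeneous Poisson SCR arrivals per phase
  (`scr_rate_per_min`, multiplied by `reactivity_gain` during MAT) with
  log-normal amplitudes parameterised by their mean and SD in µS. The
  kernel `h(t) = e^(−t/τd) − e^(−t/τr)` (rise 0.7 s, decay 2 s) is
  normalised to unit peak, so a planted amplitude is the peak height of its
  SCR.
- Conductance is clipped at 0 µS from below; subject `i` uses seed
  `master + i`.

Default group contrasts follow the depression-psychophysiology literature
qualitatively — lower tonic level (4 vs 6 µS), sparser non-specific SCRs
(1.5 vs 3 per min), blunted stress reactivity (gain 1.25 vs 2.0) — but the
magnitudes are calibration choices, not estimates from any clinical
dataset: no quantitative effect sizes are publicly available for this
protocol. Amplitudes (0.35–0.4 µS mean, 0.2 µS SD) and noise (0.02 µS SD)
sit in the usual ranges for dry-electrode finger recordings.

What the generator deliberately omits: inter-subject baseline heterogeneity
beyond the random walk, habituation of SCR rates within phases, motion
artifacts (except spikes injected explicitly in tests), electrode drift and
temperature effects. Passing tests on these cohorts therefore demonstrate
that the *pipeline machinery* is correct and leak-free — not that the
classifier's accuracy on synthetic cohorts predicts accuracy on patients.

## Preprocessing

Fixed order: artifact repair → zero-phase Butterworth → moving average →
decimation. Filters are applied forward–backward (`sosfiltfilt`) so SCR
latencies are not shifted; the price is that the effective magnitude
response is the square of the designed one, which the tests account for.
The moving-average window defaults to 0.25 s — short enough not to blunt a
0.7-s SCR rise. Artifact repair interpolates linearly across masked spans;
when no mask is supplied, samples neighbouring a >1 µS one-sample jump and
samples deviating >1 µS from a 1-s rolling median are flagged (the jump
rule alone cannot catch the interior of short plateau spikes). A recording
with more than half of any phase masked is excluded as unusable.

The default analysis rate is 8 Hz: the signal is band-limited to 1 Hz by
the filter, so 8 Hz retains 4× oversampling while keeping the decomposition
problem small; any divisor of the native rate down to 2 Hz is accepted.
Feature values at 4 and 8 Hz agree within a fraction of a percent on
noiseless signals (tested), so cohort-scale simulations in the test suite
and acceptance script run at 4 Hz where runtime matters.

## Convex decomposition

The decomposition solves

    min_{q ≥ 0, c, d}  ½‖y − h∗q − Bc − Dd‖² + α·1ᵀq + (γ/2)‖c‖²

with `B` a clamped cubic B-spline basis (10-s knot spacing) and `D` an
unpenalised intercept-plus-slope block that absorbs linear drift so the
ridge on `c` does not fight it. α = 0.008 and γ = 0.01; the two kernel time
constants are sorted so the smaller always acts as the rise constant.
The objective is smooth and convex on the feasible set, so it is solved
with bound-constrained L-BFGS-B using analytic gradients; convolutions use
FFTs, the spline basis is sparse, and the solver is warm-started from the
ridge fit of the tonic basis alone. Convergence is declared at a
projected-gradient sup-norm of `solver_tolerance` (default 1e-7; 1e-5
leaves the objective unchanged to six decimals on realistic signals and is
used for cohort-scale runs). The residual is defined as
`y − tonic − phasic`, making the reconstruction identity exact by
construction; optimality is verified in the tests against an independent
oracle that reduces the same quadratic program to an exact Lawson–Hanson
NNLS solve on dense matrices (≤200-sample instances, 1e-5 relative
objective agreement).

SCR detection runs on the phasic component: local maxima with ≥0.05 µS
rise from the preceding trough and ≥1 s separation — the conventional
psychophysiology criterion, exposed in `ScrParams`. Detected times are
phasic *peak* times; recovery checks against planted ground truth shift
onsets by the kernel peak lag `τr·τd/(τd−τr)·ln(τd/τr) ≈ 1.13 s`.

## Features

Per phase, a 150-s window (25% of the phase): first 150 s for MAT (to
capture activation before habituation), final 150 s for all other phases
(settled baseline / recovered activity). MSCL, SDSCL and SKSCL are the
mean, n−1 sample SD and uncorrected Fisher–Pearson g₁ skewness of the
*tonic* component in the window (g₁ is defined as 0 on a zero-variance
window); NSSCR counts detected SCR peaks inside the window. Differential
sets: D1 = MAT−REST, D2 = REC1−REST, D3 = REC1−RLX, D4 = REC1−REC2,
applied to all four base features. Column order is fixed (P1..P5 ×
features, then D1..D4) and the on-disk CSV carries a header checksum.

## Statistics

- Mann–Whitney U: exact null enumeration for tie-free samples with ≤12
  observations total, otherwise the normal approximation with tie and
  continuity corrections. At the branch point the two disagree by up to
  ~0.015 in p on worst-case draws — a property of the approximation.
- Chi-square: Pearson, no continuity correction by default (Yates optional).
- Group × task: rank-based ANOVA-type statistics for the design with one
  whole-plot factor (group) and one repeated factor (task). All N·t
  observations are mid-ranked jointly; cell rank means estimate relative
  effects; the quadratic form under each hypothesis projection is referred
  to F(f̂, ∞) for the within-subject hypotheses and to F(f̂, f̂₀) with a
  Box-type denominator df for the group effect, with f̂ from the Box
  approximation. Empirical type-I error at n = 8+8 over 2000 exchangeable
  null simulations is within 0.05 ± 0.02 for all three hypotheses.
- Benjamini–Hochberg step-up FDR at level 0.05 across the 36 features.

## Classification experiment

Stratified 5-fold cross-validation repeated 200 times (folds reshuffled
each repeat from the experiment seed). Inside every training fold: z-score
standardisation (training statistics only; constant columns scale 1), then
SVM-RFE — repeatedly fit a linear SVM (C = 1) and eliminate the feature
with the smallest squared weight, ties broken toward the lower column
index — giving a full ranking per fold; 5 × 200 = 1000 rankings are
averaged into the rank table. For each subset size the four classifiers
(linear SVM; CART with Gini impurity grown to purity, minimum leaf 1;
3-NN with Euclidean distance, k capped at the training-fold size on
degenerate tiny folds; Gaussian Naive Bayes) are trained on the top-ranked
features and evaluated on the held-out fold only. Rates are reported in
percent with the patient group as positive class; AUC uses the
rank (Mann–Whitney) formulation with mid-rank ties, computed per fold and
on predictions pooled across folds (train and test separately, for ROC
curves). Stratification, standardisation and the tree-growth controls are
deliberate choices where the protocol leaves them open; all are exposed in
`ModelConfig`.

## Null calibration and problem sizes

Cross-validated accuracy on a *single* small null cohort is a poor
diagnostic: because the 36 features share one dominant latent factor (the
subject's tonic level), an accidental group difference in that factor gives
one cohort genuinely learnable structure — per-cohort mean accuracy swings
by ±8 percentage points at 10+10 subjects, in both directions. The
leakage/null checks therefore estimate expected null accuracy by averaging
over exchangeable relabelings and replicate cohorts (8 permutations of the
strong-contrast cohort; 4 zero-contrast cohorts × 4 labelings), which
centres near 50% with ~2-point standard error. The strong-contrast
experiment and the scaled CV protocol (20 repeats, subset sizes 1/11/36,
10+10 subjects) run at the package's cohort-simulation sizes; the study-
scale defaults (37+30, 200 repeats, 8 subset sizes) remain the
configuration defaults.

## Known limitations

- The decomposition is dense in the driver; recordings much longer than an
  hour at high analysis rates would benefit from a state-space
  reformulation that is not implemented.
- The ANOVA-type test supports exactly the two-group × five-task complete
  design used here; unbalanced or incomplete panels are rejected rather
  than handled.
- No motion-artifact model beyond step/plateau spikes; no non-integer
  resampling; no alternative decomposition back-ends.
- Synthetic-cohort accuracy says nothing quantitative about clinical
  performance (see the generator's omissions above).
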