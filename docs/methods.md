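# Methods

## The data model

The unit of observation is a subject-week of free-living behavior,
represented as a stream of fixed-length epochs, each labeled lying
(LIE), sitting (SIT), standing (STAND), light physical activity (LPA),
moderate-to-vigorous physical activity (MVPA), or NONWEAR. Epochs are
0-based with half-open extents; each day is a separate observation
window, so runs and bouts never cross day boundaries. The default epoch
length is 1 s and is configurable everywhere — posture classifiers emit
epochs anywhere from 1 to 60 s, and none of the downstream mathematics
depends on the choice beyond duration rounding.

Wear-time validity follows the usual accelerometry convention: a day is
invalid when its non-NONWEAR time is strictly below 10 h, a subject when
strictly fewer than 4 valid days remain. Both thresholds are
configuration fields.

## Sequence metrics

**Runs** are maximal same-label (or same class-set) sequences. The three
behavior class-sets — sedentary SB = {LIE, SIT}, non-sedentary NSB =
{STAND, LPA, MVPA}, and MVPA alone — are analyzed by collapsing labels to
in/out of the set before run-length encoding, so the indices are
invariant to relabeling within a set.

**Bouts** are detected by a deterministic greedy scan: a candidate opens
at an in-target epoch and extends epoch by epoch while the window's
cumulative target fraction stays ≥ the purity threshold (default 0.8);
at the first violation or day boundary the window is trimmed back to its
last in-target epoch and emitted if its trimmed length is ≥ the minimum
bout duration (default 60 s). The scan resumes after an emitted bout, or
one epoch past a failed candidate's start. This makes bouts
non-overlapping windows that begin and end in-target — the occupancy
convention used by event-based posture processing. NONWEAR counts as
off-target inside a candidate window. The whole procedure is verified in
the test suite against an independent window-enumeration oracle.

**Partitioning indices** per subject and class-set:

- *median bout length* (minutes), pooled over all valid days; undefined
  (NaN) when a subject has no bout, in which case model fits drop the
  subject and report the count;
- *Gini index* of the durations of **all** class-set runs — bouts and
  sporadic sequences alike — computed as G = Σᵢⱼ|dᵢ−dⱼ| / (2n²d̄) via the
  equivalent sorted O(n log n) form. Every run weights equally; the
  corresponding Lorenz curve has cumulative sequence share on x and
  cumulative time share on y. G is scale-invariant and bounded by
  (n−1)/n;
- *bout/total ratio*: class-set time inside bouts over total class-set
  time (bout windows can contain off-target epochs; only in-target time
  counts in the numerator). Zero when there is no bout.

## Compositional core

Compositions are strictly positive vectors closed to sum 1. Zero parts —
common for lying in short observation windows — are handled by
multiplicative replacement: zeros become δ = half the smallest nonzero
proportion observed in the dataset (a dataset-level δ, so all subjects
are treated alike), other parts rescale. Application is logged.

All log-ratio machinery uses the natural logarithm. The default ilr
basis is the pivot (sequential binary partition) basis in the given part
order; since every model output is proven basis-invariant in the tests,
the choice is cosmetic. `clr_inv` requires its argument to sum to zero
within 1e-8; `closed_geometric_mean` is computed part-wise and equals
the clr-mean route to 1e-12.

## The three model families

All three are ordinary least squares with individuals as units,
covariates z entering linearly. Confidence intervals are t-based at the
residual degrees of freedom, significance markers † <0.1, * <0.05,
** <0.01, *** <0.001, and no multiple-testing correction is applied.

1. **Iso-temporal substitution.** The outcome is regressed on the D−1
   time-share proportions with one behavior (the displaced one) omitted,
   plus covariates. Each included coefficient is the outcome change per
   unit of time share moved from the displaced behavior to it. Looping
   the displaced behavior yields the full pairwise grid, which is exactly
   antisymmetric and transitive (all D fits are reparametrizations of one
   linear model); the tests assert both to 1e-8.

2. **Compositional linear model.** Y = α + ⟨β̂, x⟩_A + γ̂·z + ε, fitted
   as OLS on [ilr(x) | z]. The ilr coefficient vector b maps to clr space
   as Bᵀb; its Euclidean norm is |β̂| and its clr_inv (after
   normalization) the unit direction composition. The model p-value is
   the partial F-test of the whole ilr block. Predictions and
   hypothetical-profile contrasts (Δ = ⟨β̂, profile ⊖ reference⟩_A,
   exponentiated to a ratio when the outcome is log-transformed) are
   computed in clr space. Outcome transforms: natural log for BMI and
   triglycerides-type outcomes; the natural log is what reproduces the
   published profile ratios from the printed coefficient magnitudes.

3. **Partitioning-index regression.** OLS of the outcome on the index,
   optionally its square, the ilr time budget (so associations are
   interpreted at a fixed budget) and covariates. In `auto` mode the
   quadratic enters iff its partial F-test has p < 0.05; under a linear
   truth this admits the quadratic at the nominal 5 % rate (verified at
   1000 replicates). Helpers evaluate index shifts
   (b₁Δx + b₂Δ(x²)) and the parabola vertex −b₁/(2b₂).

BMI enters as a covariate in every model except those whose outcome is
BMI or waist circumference (the `bmi_covariate` / `adiposity_outcomes`
config fields).

## Synthetic cohorts

The generator produces data with exactly the structure the models
assume, which is what makes full-pipeline recovery tests meaningful.

- **Compositions** are logistic-normal: clr of the cohort center plus
  zero-sum-projected Gaussian noise with a configurable 5×5 clr
  dispersion (default 0.25·I). The default center (5.64, 54.72, 27.94,
  3.64, 8.01) % is a realistic adult closed geometric mean dominated by
  sitting.
- **Streams** alternate a behavior draw and a duration draw. The class
  probability is proportional to the class's remaining time deficit
  (target share × total time − realized), which makes realized shares
  converge to the target (L1 < 0.02 by 10⁵ epochs, tested); a sampled
  run is capped at the class's remaining deficit and truncated at day
  boundaries; durations are lognormal per class, rounded to whole epochs
  (minimum one). Per-class (μ, σ) defaults in log-seconds — LIE (5.8,
  1.7), SIT (5.2, 1.8), STAND (4.8, 1.5), LPA (3.8, 1.0), MVPA (3.5,
  1.1) — were chosen once so that default streams land inside the ranges
  observed for adult cohorts on every partitioning index: class-set Gini
  ≈ 0.72/0.77/0.59 for SB/NSB/MVPA, median bout lengths of a few
  minutes.
- **Covariates** are deliberately simple: sex ~ Bernoulli(0.64), age ~
  Normal(50.6, 9.6) clipped at 18, income/education/two nutritional
  indices standard Normal. They exist to give the design matrix
  realistic scales, nothing more.
- **Outcomes** follow Y = α + |β̂|·⟨direction, x⟩_A + γ·z + ε with
  Gaussian noise, exactly linear in clr space (doubling |β̂| doubles the
  compositional term, tested to 1e-12).
- **Seeding**: one global seed builds a `numpy.random.SeedSequence`,
  spawned into independent children — one each for compositions,
  covariates, outcome noise, and one per subject stream — so any
  component can be regenerated independently and byte-identically.

What the generator does **not** emulate: circadian structure (no
sleep/wake placement, behaviors are exchangeable across the day),
transition-matrix dependence between adjacent behaviors, covariate–
behavior correlation (time budgets are independent of age, sex, etc.),
and measurement error in the labels themselves. Duration capping at the
class deficit censors the longest runs slightly. Consequently, passing
recovery tests show the estimators are correct under the assumed model;
they do not certify performance under classifier noise or confounded
real-world budgets. The simulated MVPA bout/total ratio (~0.93) sits
above typically observed values (~0.5): real MVPA is more sporadic than
a lognormal single-scale duration law allows.

## Numerical choices and scale of the shipped checks

Compositions must sum to 1 within 1e-9; clr round-trips are exact to
1e-10; basis invariance is asserted to 1e-10 and grid antisymmetry/
transitivity to 1e-8. Rank-deficient designs, constant indices,
all-NONWEAR streams, non-PSD dispersions and unclosed proportion tables
are rejected with messages rather than propagated.

The shipped simulation checks use cohorts of n = 500 (100 replicates)
for compositional-model recovery, 1000 replicates of n = 150 for the
quadratic selection rate, and 1000 random streams of ≤ 200 epochs for
the bout-detector oracle — sizes at which the medians and rates under
test are stable while the whole suite stays quick on one CPU.

## Known limitations

- Bout detection is one fixed greedy convention; published event-based
  processors differ in tie-break details, and no single convention is
  canonical. Ours is deterministic and oracle-tested, but numbers are
  only comparable across datasets processed with the same convention.
- The median bout length uses bouts only (not all runs); with no bouts it
  is missing, and subjects drop from that model with a logged count.
- Models are cross-sectional OLS: no day-level repeated measures, no
  causal interpretation.
- The pipeline assumes the five-class taxonomy; other alphabets require
  remapping before ingestion.
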