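# Methods

This note describes the model and procedures `mongoosenet` implements,
the defaults it chooses where the method leaves parameters open, and
what the synthetic benchmark does and does not demonstrate.

## Problem and pipeline

The package detects heart disease from a tabular clinical cohort: k
patients × n mixed numeric/categorical attributes with scattered missing
entries, and a binary outcome (normal vs abnormal; graded 0–4 clinical
labels are collapsed 0 → normal, ≥1 → abnormal, configurable). The
pipeline has four stages, each refit on training data only:

1. **Quantile normalization** of the numeric columns.
2. **Imputation** — column mean (numeric) / modal category (categorical).
3. **Similarity-cascade feature selection** — congruence coefficient,
   then Kumar–Hassebrook similarity.
4. **Classification** — a 1-D fire-module convolutional network whose
   flat weight vector is trained by the dwarf mongoose optimization
   algorithm (DMOA) under a mean-squared-error fitness.

## Quantile normalization

Each numeric column is ranked; the reference distribution is the mean of
the rank-sorted columns; every value is replaced by the reference value
at its within-column rank; the original row order is restored. Choices
the bare procedure leaves open:

- **Scope.** Normalization applies to numeric columns only; rank
  arithmetic on category codes is meaningless.
- **Missing entries.** Normalization precedes imputation, so ranks are
  computed over observed values only and missing entries pass through
  untouched. A column with m < k observed values contributes its
  quantile function (linearly interpolated at k evenly spaced
  probabilities) to the reference, and its observed values map to the
  reference at the interpolated position of their rank. For complete
  columns this reduces exactly to the classic sort/mean/reassign
  algorithm.
- **Ties.** Tied values receive the mean of the reference values over
  the tied rank block, so output is deterministic. Note that averaging
  necessarily perturbs the "all columns share one multiset" property at
  tied entries; the property is exact on tie-free data.
- **Train/test.** The reference and per-column quantile maps are learned
  on the training matrix; held-out values are mapped onto the training
  reference by interpolated rank against the training column. This keeps
  the transform leak-free inside cross-validation.

## Feature-selection cascade

Stage 1 scores every column P against the binary label vector R with the
congruence coefficient (Tucker's uncentered correlation)

    J = ΣPR / √(ΣP² · ΣR²)  ∈ [−1, 1]

and keeps the top o. Stage 2 re-scores the survivors T against the
labels V with the Kumar–Hassebrook (continuous Tanimoto) similarity

    M = ΣTV / (ΣT² + ΣV² − ΣTV)

and keeps the top z. Decisions:

- The cascade is sometimes written with the congruence denominator
  unsquare-rooted; that form is not scale-invariant and is not the
  congruence coefficient by its standard definition. The square-rooted
  Tucker form is the default; the unscaled variant is available as
  `congruence_form="unscaled"` for fidelity experiments.
- Stage 1 ranks by |J| by default: a feature perfectly anti-aligned with
  the outcome is maximally informative. Configurable to raw J.
- Both stages score against the label vector — the only target vector
  defined for the task. Categorical features enter as their numeric
  codes post-imputation; no one-hot expansion.
- o and z have no canonical values; defaults are o = ⌈0.6·n⌉ and
  z = ⌈0.5·o⌉, both overridable, recorded in the run log.
- Ties in ranking break toward the lower column index; columns with zero
  norm score 0 (they cannot carry signal and the similarity is undefined
  on them).

**A property worth knowing:** both scores are *uncentered*. On
nonnegative data (category codes, the 0/1 label) the score of a pure
noise column is systematically positive, while a zero-mean numeric noise
column scores near 0. Mixed-type noise columns are therefore *not*
exchangeable under the null: categorical noise outranks numeric noise.
This is faithful to the similarity measures themselves; the null
(no-signal) calibration check is consequently run on all-numeric
matrices, where columns are exchangeable and the number of designated
columns surviving selection is exactly hypergeometric.

## Network

The selected z features form a single-channel 1-D signal. The default
"micro" architecture is: initial conv (4 filters, width 3, stride 1) →
2 fire modules (squeeze 2; expand 2+2) → max-pool (width 2, stride 2)
→ final conv (2 filters, width 1) → global average pool → softmax.
A fire module is a width-1 squeeze convolution feeding concatenated
width-1 and width-3 expand convolutions, rectifiers throughout; squeeze
must compress (s < e1 + e3). The classical eight-fire-module layout is
constructible (`NetworkSpec.full8`) but is far larger than small tabular
inputs warrant for population-based training. "Same" zero padding
preserves length at widths 1 and 3; there is no dropout or batch norm;
exact probability ties predict class 0 (normal). With all-zero
parameters every logit is 0 and the output is exactly (0.5, 0.5).

The parameter vector is the concatenation of each conv's weights
(c_out × c_in × w) and biases in layer order; `flatten`/`unflatten` are
mutually inverse bit-exactly, and saved parameter files carry a spec
hash so weights cannot silently be loaded into a different architecture.

## Optimizer

DMOA minimizes the training MSE between the network's abnormal-class
probability and the 0/1 labels, over box bounds [−1, 1] per weight
(configurable). Per iteration:

- **Alpha phase** (exploitation): each solution proposes
  s + α·Q, with α ~ U(−1,1) per dimension and Q the "peep" vocalization
  scale (default 2, the source convention); the alpha female is drawn by
  fitness-proportional likelihoods. Acceptance is greedy.
- **Sleeping-mound bookkeeping:** L_r = Δfitness / max|Δfitness|
  (zero vector when nothing changed), ω its population mean.
- **Babysitter exchange:** every ⌈0.1·HU⌉ iterations the n_babysitters
  worst solutions are re-randomized within bounds.
- **Scout phase** (exploration): every iteration, each solution moves
  by ∓ D·α·z·(s − S), toward the movement vector S when ω improved and
  away otherwise; z ~ U(0,1) per solution and D = (1 − U/HU)^(2U/HU)
  decays from 1 to 0, so late-run moves refine rather than explore.
  Components of S where a solution coordinate is exactly 0 contribute 0,
  keeping the vector finite.

Further conventions: bound handling is clamping; the raw
fitness-proportional alpha likelihoods are kept verbatim (they weight
worse solutions more under minimization — convergence rests on greedy
acceptance, not on this draw; an "inverted" weighting is available);
runs stall-terminate after 50 improvement-free iterations by default.
The best-so-far fitness is non-increasing by construction, and identical
seed + configuration + fitness reproduce a run exactly.

The description of the algorithm claims a single tuning parameter; in
practice the peep scale, population size, iteration budget, babysitter
count and exchange period all matter, and all are exposed and logged.

## Evaluation

Class 1 (abnormal) is positive. Accuracy, sensitivity and specificity
are computed from pooled confusion counts. Protocols: a stratified
train-percentage split, and stratified k-fold cross-validation with
counts pooled over folds before computing metrics (macro-averaging is a
deliberate non-default; pooling is stated in each report). A metric with
a zero denominator is reported as missing with a warning, never as 0.
Feature selection and preprocessing are fitted inside each training
portion — stricter than protocols that select features once on the full
data, and the safer default.

## Synthetic cohorts

`synthdata` emulates the structure of small heart-disease cohorts: the
default preset has 300 patients and 13 attributes (9 numeric, 4
categorical with 2–4 levels), 5 informative, effect size 1.5, 2%
missing-at-random entries, balanced classes — the shape of the commonly
analysed 13-attribute clinical subset. Informative numeric attributes
are Normal(class·effect, 1); informative categorical attributes tilt
their level odds by `effect_size` log-odds across the level codes;
graded labels (0–4) are available via `label_levels=5`. The generator is
deterministic under its seed and never reproduces real patient records.

What passing the benchmark shows: the cascade finds planted mean-shift
signal, and the DMOA-trained network converts it into high held-out
accuracy/sensitivity/specificity. What it does not show: performance on
real cohorts with correlated attributes, nonlinear effects,
informative missingness, or class imbalance — none of which the
generator plants.

## Problem sizes used in the shipped benchmarks

The acceptance benchmarks run the optimizer at t=30 mongooses for
HU=200 iterations (sphere) or HU=150 (network training), the recovery
study at 50 cohorts of 500 patients, and the pipeline protocols on the
300-patient preset (90/10 split and 9-fold CV). These sizes make the
full benchmark reproducible in minutes on one CPU while leaving the
acceptance margins wide.
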