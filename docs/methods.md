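# Methods

This note documents the models, numerical choices, and known limits of
the package. It is written for a reader who wants to know exactly what is
computed, with which defaults, and why.

## Problem setting

The package targets three-class prognosis from a fused tabular cohort:
a small block of mixed-type clinical features (history variables, labs,
stroke-subtype categories) and a wide block of continuous radiomics-style
features extracted from imaging. Classes are outcome bands (A/B/C, e.g.
discharge NIHSS bands) with strong imbalance — the emulated cohort shape
is 106:289:46 over 441 patients. The original cohort is private, so every
experiment here runs on synthetic data with the same statistical shape.

## Synthetic cohorts

`synthetic.generate_dataset` draws continuous features from
class-conditional Gaussians with unit variance and categorical clinical
features (2–4 levels) from class-conditional multinomials. The outcome
bands are ordinal severity strata, so informative features shift
monotonically with class: per informative feature the class means sit at
centered positions (0, 1, 1.75) x `effect_size` x (+-1, alternating sign
per feature). `effect_size` is thus the A-to-B separation in SD units,
and the small severe band C lies only 0.75 x `effect_size` beyond B —
the adjacency that makes the minority class the hard one and gives class
balancing something to repair. Redundant radiomics blocks are noisy copies of
informative features with additive Gaussian noise calibrated to a target
within-block Pearson r (`block_corr`); pure-noise features fill the rest.
Missingness is MCAR and restricted to continuous clinical features
(radiomics features are machine-extracted and complete in practice).
Class counts follow largest-remainder rounding of the class proportions,
so the target cohort proportions are hit exactly at n=441.

Default `effect_size` is 1.1. This was calibrated once so that a single
deep learner reaches a test accuracy in the low-to-mid 0.80s on the
default cohort — the difficulty regime the method comparison operates in —
and is not adjusted per experiment.

`generate_split_signal_dataset` partitions the class signal across
modalities: clinical informative features separate class A from {B, C},
radiomics informative features separate C from {A, B}. Neither modality
alone can distinguish all three classes; the fused table can. This is the
design behind the joint-vs-single-modality comparison.

What the generator does **not** emulate: real radiomics marginals (heavy
tails, boundedness), feature-feature structure beyond the planted
correlation blocks, label noise, informative missingness, and site
effects. Passing tests therefore demonstrate the pipeline's mechanics and
relative orderings under controlled conditions, not clinical performance.

## Preprocessing

* **Imputation** — each missing continuous cell is replaced by the
  average of M = 5 repetitions of N = 20-draw bootstrap means of the
  feature's observed values (a repeated Monte-Carlo estimate of the
  feature mean); categorical cells take the modal observed level. In the
  pipeline the observed pools come from training rows only.
* **Variance filter** — population variance (divide by n), threshold 0.3
  by default, computed on raw values before standardization; applies to
  continuous features only. The estimator is fixed so that borderline
  cases are deterministic ({0,1,0,1} has variance 0.25 and is dropped at
  threshold 0.3).
* **One-hot encoding** — full n-level expansion with no reference level
  dropped; level sets are fitted on training rows and unseen levels are a
  hard error.
* **Standardization** — z-score with training-row mean and population SD;
  indicator columns stay 0/1. Constant features must be filtered first.
* **Split** — stratified 70/30 with per-class largest-remainder rounding;
  ties break in class order A < B < C. For the 106/289/46 cohort this
  gives train counts 74/202/32 exactly.

Fitting every parameter on training rows only is a deliberate choice;
protocols that select features on the full cohort before modeling can be
reproduced with `select_on_all=True`, which warns loudly.

## Feature selection

Two boosters score every feature: total split gain under a leaf-wise
grower (LightGBM) and split count ("weight") under a second-order
booster (XGBoost). The selection rule keeps
(top-50 of A ∩ top-50 of B) ∪ top-10 of A ∪ top-10 of B. Survivors pass a
greedy Pearson prune in descending importance order: any candidate with
|r| > 0.9 against an already-kept feature is dropped, so the kept set is
pairwise below threshold. Retaining the higher-importance member is
deterministic; a seeded random-order mode exists for protocols that kept
an arbitrary member. Clinical features skip the variance/booster funnel
and get only the correlation prune. Fusion is column-wise concatenation
aligned on sample id.

## Balancing

SMOTE interpolates synthetic minority points p + u(q − p) between a
minority sample and one of its k = 5 same-class Euclidean neighbors
(u ~ U(0,1)) until all classes match the majority count. ENN then removes
every sample whose own class loses the plurality vote of its k = 3
nearest neighbors; votes are computed once on the post-SMOTE set (no
iteration), matching a single prune stage. Distances are measured on the
encoded, standardized representation; interpolated indicator values are
left fractional since the learners consume them numerically. k-NN ties
break by sample index via a stable sort. Balancing is applied to
training rows only.

## Base learners

All three families share a fit / predict-probability contract, train
with Adam (first-moment decay = the configured momentum, default 0.9;
second moment 0.999) on softmax cross-entropy, and are bit-deterministic
given a seed (fixed init and shuffling).

* **DNN** — fully connected ReLU stack; each unit computes
  sigma(sum w_i x_i + b).
* **LSTM-RNN** — standard LSTM recurrences (input, forget, output gates;
  tanh cell candidate) followed by a fully connected softmax layer.
  Tabular rows enter as a single time step of feature width by default;
  a features-as-timesteps mode (one feature per step) is available behind
  a flag. Neither shaping is claimed to be canonical for tabular data.
* **DBN** — greedy layer-wise RBM pretraining with CD-1, then supervised
  fine-tuning of the unrolled network. The first RBM uses Gaussian
  visible units (mean-field reconstruction) because binary units cannot
  represent z-scored inputs; deeper layers are Bernoulli. Fine-tuning
  keeps sigmoid hidden activations — the activation the pretrained
  weights were learned under — rather than switching to ReLU.
  Pretraining runs 15 epochs at lr 0.01 in batches of 32.

The RBM energy is E(v,h) = −bᵀv − cᵀh − vᵀWh; the joint probability
exp(−E)/Z is validated against an exhaustive partition function on small
machines (≤16 total units).

Training profiles: the `full` profile is the method's reference
budget (1000 epochs, lr 1e-4, batch 20); the default `reduced` profile
(150 epochs, lr 1e-3) is the desk-scale setting used by the test suite,
chosen as the package's working scale. The architecture search evaluates
candidates at 40 epochs with batch 64 and refits winners at the profile
budget with batch 20.

## Stacking

Training rows are split into T = 5 stratified folds. Per family,
fold models trained on
the other four folds predict the held-out fold; the concatenated
probability blocks (3 classes x 3 families = 9 columns) train a
100-tree random-forest meta-learner. At inference the per-fold models
score the new rows and are averaged per family — the stacking
formulation in which the fold models themselves score the test data — which
also keeps the
test-time meta-feature distribution identical to the one the
meta-learner was trained on. (An earlier refit-on-full-train variant
produced a distribution shift between training and test meta-features
and measurably hurt the stack.) Meta-features are probabilities, not
hard labels, because they carry strictly more information. Hard voting
breaks ties toward the lowest class; soft voting takes the argmax of the
unweighted mean probability.

## Swarm optimizer

A PSO-style integer metaheuristic. Initialization: per galaxy and
dimension a chaotic state starts from a random integer in [0,100]/100 and
advances one step of the sinusoidal map m' = a·m²·sin(pi·m) (a = 2.3,
which keeps [0,1] invariant); the state maps affinely into the search
box and integer dimensions are rounded. Velocity update per iteration t:

    v <- w_w·v + ef1·r1·(p_best − x) + ef2·r2·(g_best − x),
    w_w = w_s − (w_s − w_e)·t/T

with fresh uniform r1, r2 per galaxy and dimension, ef1 = ef2 = 2.0,
w_s = 0.9, w_e = 0.4, and a velocity clamp at 0.2·(upper − lower) per
dimension to prevent integer-rounding oscillation. Personal and global
bests update only on strict improvement (greedy elitism), which makes the
best-so-far history monotone. Defaults: population 20, T = 100.

The velocity update uses one personal and one global attractor (the
PSO convention); a variant that reuses the personal best in both terms
never lets the global best steer the swarm and was rejected. The
initialization affine map is oriented so that [0,1] chaos covers
[lower, upper].

For architecture search the position vector is
[n_layers, neurons_1..neurons_Lmax] with n_layers in [1, L_max = 3] and
neurons in [1, 100]; unused slots are truncated on decoding. Fitness is
validation macro-F1 of the learner trained at the reduced search budget.
The inner 80/20 stratified carve is taken from the pre-balancing
training rows; the inner-train part is balanced with the run's method
and the validation part is left untouched, so fitness is always measured
on real samples rather than on synthetic resampled points. The first galaxy
is seeded with the pre-optimization incumbent (two layers of 10), so the
search result is never worse than the starting architecture on the
validation metric. Fitness values are memoized per position. Each family
is optimized independently and the winners are stacked.

## Metrics

Confusion-matrix accuracy is trace/total (summing TP_i + FP_i over
all classes equals n, so the one-vs-rest form reduces to it). Macro precision and
recall are unweighted means of the per-class one-vs-rest ratios;
macro-F1 is the harmonic mean of macro-P and macro-R — of the macro
values, not the mean of per-class F1s. A class with a zero denominator
contributes 0 with a warning. Per-class AUC is a trapezoid sweep over the
class's probability column with thresholds at distinct scores, which
equals the tie-aware Mann-Whitney statistic (ties credit 1/2); macro-AUC
is the unweighted mean of the three.

## Experiment scales

The test suite and the acceptance script run the comparisons at the
package's working scale: cohorts of n = 450 (proportions 106:289:46),
17 clinical + 100 radiomics features with 8 informative radiomics
features and three 4-copy redundant blocks, 5% missingness, the reduced
training profile, swarm search at population 5 x 5 iterations, and
medians over 5 seeds. The feature-recovery experiment plants 10
informative features among 200 at effect 1.5 SD with n = 400. The
split-signal comparison uses effect 1.5 so that the fused table is
separably informative while each single modality is not.

## Known limitations

* Synthetic Gaussians understate the difficulty of real radiomics data;
  absolute metric values here do not transfer to any clinical cohort.
* The reduced training profile undertrains all three families relative
  to the reference budget; orderings between methods are the meaningful
  output, not absolute scores.
* ENN can be destructive under heavy class overlap (it may remove a
  large share of the majority class); the balancing comparison is run in
  the moderate-overlap regime the method targets. Even there the
  SMOTEENN-over-no-balancing margin on synthetic Gaussian cohorts is
  small (a few hundredths of macro-F1) and seed-sensitive; treat its
  direction, not its size, as the finding.
* The LSTM sees sequences of length 1 by default; it degenerates to a
  gated feed-forward network, which is intended but worth knowing.
* ADASYN and Borderline-SMOTE comparison slots are delegation stubs and
  raise if configured.
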