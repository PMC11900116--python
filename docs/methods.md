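# Methods

## Problem and pipeline

`mirclass` classifies mature miRNAs as disease-associated ("selected") or
control ("random") from three feature families: intrinsic sequence
descriptors, predicted gene targets, and pathway annotations. The pipeline
is: ingest (or simulate) sequences and annotation tables → compute
descriptors → filter annotations by confidence → assemble a one-hot feature
table → correlation-based subset selection → stratified 10-fold
cross-validation of seven classifiers → retrain the two best and score them
on an independent validation set.

## Sequence descriptors

Per miRNA: length (nt), mononucleotide fractions, GC fraction, hydrogen-bond
count, mean residue mass, and one presence flag per tetramer (256 columns,
lexicographic order). Two descriptors that the field names without a fixed
formula are pinned down as follows:

* **Hydrogen-bond count.** Each base contributes its Watson–Crick pairing
  capacity: A/U → 2, G/C → 3, i.e. `2(n_A+n_U) + 3(n_G+n_C)`. This is the
  only sequence-intrinsic reading of "number of hydrogen bonds" for a single
  strand; no duplex or secondary structure is predicted.
* **Mean mass.** The average internal-residue mass of the ribonucleotide
  monophosphates, with the constant table A = 329.21, C = 305.18, G = 345.21,
  U = 306.17 Da. Fixing the table makes tests exact.

Motif features are binary presence, not counts, consistent with a one-hot
design; sequences shorter than 4 nt receive an all-zero motif block rather
than an error. The full 256-tetramer vocabulary is generated and attribute
selection prunes it.

## Annotation filters and table construction

Gene targets are kept when their prediction score is ≥ 97 (inclusive, "97 to
100"); pathways when their p-value is < 0.05 (strict). Duplicate
(miRNA, gene) rows keep the maximum score and duplicate (miRNA, pathway)
rows the minimum p-value, so ingestion is deterministic.

The training vocabulary is the sorted union of post-filter annotations over
the cohort; genes/pathways attached to no cohort member are excluded
(constant columns carry no information and break some learners). Validation
tables are built against the frozen training vocabulary — unseen annotations
are dropped, never appended — so train and validation matrices always align
by column name. miRNAs already used in training are removed from validation
cohorts before evaluation.

## Feature selection

CFS merit `k·r̄_cf / √(k + k(k−1)·r̄_ff)` with symmetric uncertainty as the
correlation measure. Numeric descriptors are discretized by equal-frequency
binning with 10 bins (deterministic; no MDL machinery). The search is greedy
best-first forward selection from the best singleton, expanding the highest-
merit open subset and stopping after 5 consecutive non-improving expansions;
ties break toward the lower feature index, making selection reproducible and
column-order invariant. No hard cap on subset size is imposed (published
analyses sometimes report a specific selected-feature count, but that is an
outcome on their data, not a parameter); a `--max-features` override exists
for parity experiments. If no feature carries class information the
selection is empty with merit 0 and the pipeline falls back to the full
table.

## Classifiers

Implemented from first principles (their update rules are the scientific
content):

* **Naïve Bayes** — add-1 (Laplace) Bernoulli likelihoods on binary columns,
  per-class Gaussians (variance floor 1e-9) on numeric columns, log-space
  accumulation, posteriors normalized to 1.
* **Hoeffding bound / tree** — `ε = √(R²·ln(1/δ)/2n)` with R = 1 bit for
  binary-class information gain. The tree (VFDT) streams instances into
  leaves that hold per-attribute class counts; a leaf splits when the gain
  gap between its two best attributes exceeds ε, or when ε falls below a tie
  threshold. Defaults δ = 0.05, grace period 20, tie threshold 0.05, and 10
  re-streaming passes: the algorithm was designed for long streams, and the
  canonical stream defaults (δ = 1e-7, grace 200) can never accumulate
  enough observations to split on an 88-row table, leaving a trivial
  prior-only predictor.
* **AdaBoost.M1** — weak learner error ε_t gives β_t = ε_t/(1−ε_t);
  correctly classified weights are multiplied by β_t and renormalized;
  ε_t = 0 stops with a perfect-learner flag, ε_t ≥ 0.5 aborts and keeps the
  committee built so far; the committee votes with log(1/β_t). Weak learners
  are depth-1 scikit-learn stumps (10 rounds).
* **Sequential network** — dense stack input→100→70→50→30→1, ReLU on the
  four hidden layers, sigmoid output, trained on binary cross-entropy with
  adaptive-moment gradient descent (learning rate 1e-3, β₁ = 0.9,
  β₂ = 0.999), 200 epochs, batch size 16, He-normal initialization. Training
  hyperparameters are conventional defaults; initialization and minibatch
  shuffling both derive from the recorded seed, so training is bit
  reproducible. The implementation is pure numpy (forward pass,
  backpropagation, optimizer).

Delegated to scikit-learn behind the common interface (commodity induction,
not the contribution): the **random tree** (`DecisionTreeClassifier` with
√m random attributes per split), the **random forest** (our own seeded
bagging over such trees, so that a 1-tree, no-bootstrap forest coincides
exactly with the seed-matched random tree), and the **shallow MLP**
(`MLPClassifier`, one hidden layer of (attributes+classes)/2 units, the
classic workbench sizing).

Numeric descriptor columns are z-scored with training-fold statistics before
the two gradient-trained learners (MLP, sequential network); one-hot columns
pass through. Without this, the scale disparity (mean mass ≈ 320 vs binary
flags) cripples gradient training. The classification threshold is 0.5; ROC
curves use the raw scores.

## Evaluation

Stratified k-fold (default k = 10, reduced with a warning if the smallest
class has fewer members) with pooled out-of-fold metrics: a single
correct/total count, confusion matrix and ROC over all folds, the workbench
reporting convention. Percent accuracy is `100·correct/total` rounded
half-up to two decimals. ROC sweeps every distinct score as a threshold and
records it with each point; AUC is the trapezoidal area, identical (ties
counted half) to the Mann–Whitney pair statistic — the test suite checks
this equivalence against a brute-force pairwise count. Holdout validation is
a single pass of a trained model over the validation table; column mismatch
is an error naming the offending columns.

Learners are re-initialized per fold with a fold-derived seed; z-scoring and
all fitting use the training fold only.

## Synthetic cohorts

The generator emulates the study conditions: 44 selected + 44 random
training miRNAs and an 18-miRNA validation set, sequences 18–25 nt (the
mature-miRNA range) drawn uniformly over {A, C, G, U}. Class signal enters
through

* 5 marker genes, carried with probability 0.9 by selected and 0.1 by random
  miRNAs, scores ~ U[90, 100] — so the ≥ 97 score filter removes about 70%
  of annotations and is genuinely exercised;
* 2 marker pathways with the same carriage probabilities, p-values
  ~ U[0.001, 0.06] (mostly passing the < 0.05 filter); background pathway
  p-values ~ U[0.03, 0.5] mostly fail it;
* 2 biased tetramers (AACA at 0.9/0.1, UCGU at 0.85/0.15) implanted at a
  random position.

40 background genes and 10 background pathways are annotated
class-independently at probability 0.3. The validation cohort is generated
class-balanced (9/9): threshold-free metrics (ROC/AUC) in the holdout report
require both classes. With carriage and score-filter survival combined, the
marker-gene columns separate the classes at roughly 0.27 vs 0.03 per gene —
strong but noisy, so selection and classification are non-trivial.

What the generator does **not** emulate: sequence-dependent target
prediction (no seed-match model), expression levels, inter-gene correlation
structure, or realistic pathway overlap. Passing tests therefore demonstrate
that the pipeline recovers planted class-conditional structure of realistic
strength at the study's sample size — not performance on real cohorts.

## Null protocol

The label-permutation null for cross-validated accuracy is computed on the
full, unselected feature table. Running attribute selection on permuted
labels and then cross-validating yields ~85% apparent accuracy at 319
features and n = 88 — that quantifies selection bias of the
select-then-validate design, not the learner's chance level. The signal arm
keeps the select-then-CV order; the null arm omits selection.

## Numerical choices and limitations

* Half-up decimal rounding (not banker's) for percent accuracy.
* SU is clamped to [0, 1] against floating-point entropy drift and defined
  as 0 when both marginal entropies vanish.
* Sigmoid outputs are clipped to (1e-12, 1 − 1e-12) so probabilities are
  strictly inside (0, 1) and cross-entropy is finite.
* Test and acceptance runs use the default study-scale problem sizes
  (88-row training table, ~319 features before selection, 18-row holdout);
  the sequential network trains in a few seconds per fold at this scale.
* The Hoeffding tree is the weakest learner at n = 88 — expected, since its
  split bound is built for data streams orders of magnitude longer.
* Boosting with depth-1 stumps can stop early on strongly separable tables
  (ε_t → 0); the committee built so far is used.
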