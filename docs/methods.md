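# Methods

## The prediction problem

Given two drugs and a cancer cell line, the package jointly predicts

* five continuous synergy scores — Loewe additivity, Bliss independence,
  ZIP (zero interaction potency), HSA (highest single agent) and the S
  score — each a different reference model for "the combination does more
  than its parts",
* a binary synergy call (Loewe score strictly above a threshold, default 5),
* a binary adverse drug–drug-interaction (DDI) call attached to the
  unordered drug pair.

Inputs are a per-drug vector of continuous chemical descriptors (541 at
full scale) and a per-cell-line vector of landmark-gene expression values
(927 at full scale).  Predicting all seven targets jointly regularizes each
one and lets downstream screening demand *consistency*: a combination is a
credible candidate only when several synergy models agree.

## Architecture

The model is a multi-gate mixture-of-experts with three expert families,
all mapping the raw triple (dx, dy, cr) to a shared d-dimensional latent:

* **dense** — two layers on the concatenation [dx, dy, cr];
* **bi-additive** — separate two-layer towers on [dx, cr] and [dy, cr],
  summed elementwise (an "or"-type interaction of the two drugs);
* **bi-interaction** — the same double tower, combined as
  `Layer_add(a + b) + Layer_prod(a ⊙ b)`, the bi-interaction pooling of
  neural factorization machines (an "and"-type interaction).

The default roster is six experts, two of each family.  Each task owns a
gating network (two affine layers, ReLU between, softmax output over the
six experts); the task's representation is the gate-weighted sum of the
expert latents, and a per-task tower (two layers plus a final linear map)
produces the output — one value for a regression task, two softmaxed logits
for a classification task.  A `share_one_gate` switch collapses the gates
into a single task-common gate, and a single-expert configuration
degenerates to a share-bottom architecture; both degenerate forms exist as
configurations for ablation, not as separate models.

Every "layer" is the composition *linear → ReLU → batch-norm → dropout*.
Normalizing after the activation is unusual; it is the composition the
architecture defines, and `norm_before_activation=True` restores the
conventional order for experiments.  Gating layers use plain affine+ReLU
with neither batch-norm nor dropout, keeping fusion weights noise-free.
Batch normalization always uses running statistics in eval mode, so
single-sample inference is well defined.  All affine maps are
Xavier-uniform initialized from a seeded generator.

**Gate output width.** The gate softmax must range over the M experts
(M = 6 by default), since it weights M latent vectors.  A task-count-sized
gate output (7) would not type-check against the fusion sum, so the gate
head width is defined as M.

**Latent width d.** The expert output width is the last entry of
`layer_widths` ({4096, 2048} at full scale, hence d = 2048; the reduced
preset uses {64, 32}, d = 32).

## Numerical core

The network runs on a small reverse-mode automatic-differentiation engine
over float64 numpy arrays (`synmoe._autodiff`), with exactly the operations
the graph needs: broadcasting arithmetic, matrix product, ReLU, exp/log,
reductions, concatenation and a clip guard for logarithms.  Gradients are
verified against central finite differences in the test suite, and
eval-mode forward passes are bitwise deterministic.  Checkpoints store every
parameter and batch-norm buffer keyed by module path in a single `.npz`
archive with the model config embedded as JSON; reloads are bit-exact.

## Training

The objective is the weighted sum of task losses: mean squared error with
weight 1 per regression task, label-smoothing cross-entropy (SCE) with
weight 10 per classification task.  The factor 10 balances the scales:
class probabilities live on [0, 1] while synergy scores span tens of
units.  SCE gives the true class weight (1 − ε) and each other class ε;
with ε = 0 it is plain cross-entropy.  The smoothing default is ε = 0.1,
the conventional label-smoothing setting; probabilities are floored at
1e-12 before logarithms.  Class imbalance (~1:15 synergy positives) is
handled only through the loss weighting — no resampling.

Training uses Adam (default learning rate 1e-4, batch size 128), an
order-augmented training set (every pair in both <x, y> and <y, x>
orientation, created *after* the data split so the two orders never
straddle folds), per-epoch reshuffling reseeded from the master seed, and
early stopping: training ends after `patience` epochs (default 100)
without a new validation-loss minimum, and the returned parameters are
those of the best-validation epoch.  Validation and test predictions
average the two drug orders, making predictions exactly symmetric under
drug swap.  Validation monitoring uses the total multi-task loss with
order-averaged, un-augmented predictions, mirroring test-time behavior.

The five-fold protocol shuffles once, splits into near-equal folds, and in
iteration *i* tests on fold *i*, validates on fold *i+1 (mod 5)* and trains
on the rest, so each sample is tested exactly once.

### Desk-scale settings

The benchmark protocols (`synmoe.benchmarks`) run the full pipeline at
sizes that finish in minutes on one CPU: a 2,000-sample cohort, the reduced
architecture (expert widths {64, 32}, d = 32, gate hidden 64, towers
{32, 32}), at most 200 epochs.  Reduced runs use learning rate 1e-3 and
dropout 0.1: at this scale only ~5,000 optimizer steps are available, so
the full-scale step size cannot traverse the required parameter distance,
and a 0.5 dropout rate calibrated for 2048-wide layers is overly
destructive at width 32.  The single-batch overfit diagnostic (8 samples,
learning rate 3e-3) deliberately aliases the training and validation sets
so early stopping monitors the fit itself.

## Synthetic cohorts

The generator (`synmoe.synthetic`) emulates the statistical structure of a
curated combination screen without reproducing any real measurement:

* drugs and cell lines have latent embeddings (dim 8 by default); observed
  features are a noisy linear read-out, so feature vectors carry learnable
  low-rank structure;
* each synergy score is `intercept + scale·(shared_w·f + specific_w·g_t) +
  noise`, where f (shared across tasks) and g_t (task-specific) are
  symmetric functions of the two drug embeddings and the cell embedding
  (built from `ex ⊙ ey`, `ex + ey` and `(ex + ey) ⊙ ec` terms).  The shared
  component induces positive cross-score correlation controlled by
  `task_shared_weight`; the S score defaults to a low shared weight, making
  it the weakly-correlated outlier, as in real screens;
* score noise is keyed to the unordered (pair, cell, replicate) triple, so
  scores are exactly symmetric under drug swap and reproducible;
* `score_scale` defaults to 5, giving score standard deviations near 9.
  With ~1/16 of samples above the +5 labeling threshold this puts the
  Loewe mean near −9 — the regime of a real cohort whose Loewe median and
  mean are a few units below zero;
* the Loewe intercept is calibrated on the sampled cohort so the positive
  fraction matches `target_positive_rate` (default 1/16, the ~1:15
  imbalance of curated screens);
* adverse DDI pairs are the top `ddi_positive_rate` fraction (default
  0.073) of a symmetric latent interaction score over all drug pairs —
  pair-level, cell-line independent, and learnable from the drug features,
  mirroring the chemistry-driven and easily-predicted character of curated
  interaction labels;
* with probability `replicate_prob` a triple is emitted twice with
  independent noise, collapsible by `average_replicates`.

What the generator does **not** emulate: heavy-tailed score distributions
(noise is Gaussian), dose–response matrices (scores are sampled directly,
never derived from response surfaces), drug-specific descriptor semantics,
and any batch or assay structure.  Passing tests therefore demonstrate that
the machinery is correct and can recover a low-rank synergy surface — not
that the architecture attains any particular accuracy on real screens.

## Label and data handling

* Synergy label: 1 iff Loewe > threshold, *strictly*; a score exactly at
  the threshold is negative, keeping the positive set conservative.
* DDI label: 1 iff the pair's recorded interaction category is adverse
  (16 of the 18 default categories); benign categories and unrecorded
  pairs are 0.  The label attaches to the unordered pair and is copied to
  every cell line of that pair.
* Replicates: grouped by unordered pair plus cell line, scores averaged
  arithmetically, synergy label re-derived from the averaged Loewe score;
  conflicting DDI labels within a group are an error.
* Zero-variance descriptor columns can be removed exactly
  (`drop_constant_features`), reported as strictly increasing kept indices.

## Metrics

Regression: RMSE; Spearman correlation computed as Pearson on average
ranks (equivalent to the classical 1 − 6Σd²/(m(m²−1)) formula when there
are no ties, and well defined under ties); R² in the standard form
1 − Σ(Yᵢ−yᵢ)²/Σ(Yᵢ−Ȳ)².  A `printed_denominator` flag switches the R²
denominator to Σ(yᵢ−Ȳ)² for exact comparison against the nonstandard
printed form of the formula; the standard form is the default and the one
reported.  Classification: accuracy, precision, recall, F1 at cutoff 0.5
(the larger of the two class probabilities), AUROC (rank statistic with
half credit for ties) and AUPR (precision–recall step-curve area).
Cross-validation aggregation reports mean, sample variance and
t-based 95% CI half-widths across folds.

## Screening

Candidate triage mirrors the published post-hoc rules: the *support count*
of a prediction row is the number of its five predicted synergy scores
strictly exceeding 5 ("exceeding" read as strict); `prob_threshold` keeps
rows whose predicted synergy probability clears a bar (0.99 in the
published screen); `all_scores_threshold` keeps rows with all five
predicted scores above a bar (30 in the published screen);  `ddi_exclude`
drops rows whose predicted adverse-interaction probability exceeds its
threshold.  Rules apply conjunctively and preserve row order, so pure
filters commute.

## Known limitations

* The full-scale architecture (541/927-dim inputs, 4096-wide experts) is
  expressible but slow on this numpy engine; the package is intended for
  method study at reduced widths, not production-scale training.
* Gaussian score noise understates the tail mass of real synergy scores;
  a heavy-tailed option is deferred.
* The DDI generator draws a single adverse/benign dichotomy; the 18-way
  category taxonomy exists in the data model but is not simulated.
* Validation monitoring uses the total multi-task loss; monitoring a
  single task's loss would change early-stopping behavior for strongly
  imbalanced task subsets.
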