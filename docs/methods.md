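# Methods

## Model and assumptions

The toolkit addresses semisupervised classification with a small labeled
set, a large unlabeled pool, and class imbalance. The working assumptions
are the standard ones for self-training: the backbone classifier's softmax
confidence is informative (higher-probability predictions are more often
correct), and the unlabeled pool is drawn from the same distribution as
the labeled data. Neither assumption is checked at run time; when they
fail, pseudolabels inject noise that retraining can amplify.

The loop alternates two steps. With model weights fixed, pseudolabels for
the unlabeled pool are chosen to minimize the joint objective

    L(W, Ŷ) = −Σ_l log p(y_l | W) − Σ_t ŷ_t · log p(I_t | W) + Σ_t k_{c(t)},

whose closed-form minimizer over one-hot-or-zero `ŷ_t` is the
class-normalized solver below. With pseudolabels fixed, the backend refits
on labeled ∪ selected samples. The `k_c` term is constant in `W`, so it
shapes which pseudolabels are admitted but never the gradient step; the
loss breakdown reports it separately, and the scalar total adds it with a
configurable sign (default `+`) since only the breakdown is ever consumed
downstream.

## Threshold determination and the two solvers

For each class `c`, the class-`c` probabilities of the samples
argmax-predicted as `c` are sorted in descending order and the threshold
`exp(−k_c)` is the value at 1-based rank `⌈p · N_c⌉`. The ceiling makes
at least one sample per nonempty class selectable at any `p > 0` and makes
`p = 1` admit every sample, which is the semantics the selection fraction
promises ("the top p·100% of each class"). A class with `N_c = 0` has no
defined rank; it receives a NaN sentinel and is unselectable that round.

The class-balanced solver labels sample `n` with
`argmax_c p_n(c)/exp(−k_c)` when that ratio reaches 1. Two numerical
choices matter here:

* **Acceptance is `ratio ≥ 1 − ε`**, ε = 1e−12 by default. A strict
  `> 1` would exclude the rank-defining sample itself (its ratio is
  exactly 1 up to floating point), yielding `⌈p·N_c⌉ − 1` selections and
  breaking the top-p% contract; the ε absorbs division round-off.
* **Ties break toward the lowest class index** (both in argmax prediction
  and in the ratio comparison), and equal confidences rank by ascending
  sample index in the matched-count vanilla mode. This makes every
  operation deterministic under fixed input and permutation-equivariant.

Because thresholds are computed on raw-argmax groups while assignment uses
the normalized argmax, a sample can be relabeled into a different class
than its raw prediction ("class flip") — typically into a rarer class
whose threshold is low. Flips are allowed by default and counted in the
per-round history; `restrict_to_argmax=True` confines each sample to its
raw argmax class for users who want the grouping and the assignment to
coincide. With flips enabled, the guarantee "exactly `⌈p·N_c⌉` class-c
samples pass their class threshold" refers to threshold passage, not to
the final per-class label counts, which can differ by the flip count.

The vanilla solver applies a single global cutoff: label the argmax class
iff `p_n(argmax) > exp(−k)`, strictly — so `k = 0` (cutoff 1) selects
nothing. For budget-matched comparisons, `select_top_fraction(...,
mode="vanilla")` instead selects exactly `⌈p·N⌉` samples globally by
descending argmax probability. This is the fair baseline for the balance
contrast: same number of pseudolabels, different composition.

## Curriculum and stopping

The self-paced schedule starts at `p₀ = 0.10` and adds `Δ = 0.05` per
round, capped at 1; a `fixed` mode holds `p` constant for top-K%-style
runs. Because thresholds are monotone in `p` (a deeper rank is a lower
probability), the selected set at one round is always contained in the
next round's set for fixed predictions — the easy-to-hard property.

Rounds stop at `max_rounds` (default 5) or as soon as validation accuracy
fails to exceed the previous round's by more than `improvement_tol`
(default 0). Validation, not test, accuracy drives the rule to avoid
leakage; the validation set is the stratified 30% of the labeled training
block. Each round refits the backend cold from the same initialization
(seeded `master_seed + round`); a `warm_start` backend flag continues from
the previous round's weights instead. Pseudolabels are regenerated from
scratch on the full pool every round — selections are never accumulated —
so an early wrong label can be corrected by a later, better model.

## Reference backend

`SoftmaxRegression` is a multinomial logistic regression trained by
full-batch gradient descent from zero initialization, with the polynomial
decay schedule `α(t) = init_lr · (1 − t/T)^power` on its step size and a
small L2 penalty (1e−4) for conditioning. Defaults `init_lr = 0.5`,
`epochs = 200`, `power = 1` are tuned to desk-scale standardized features:
the objective is convex, so a large initial step with linear decay
converges quickly and deterministically. Zero init plus full-batch updates
make fits bit-reproducible independent of the seed (the `random_state`
parameter is honoured for contract uniformity and reserved for stochastic
backends). Deep backbones plug in through the same sklearn contract
(`fit`/`predict_proba`/`classes_`, registered by name); the loop passes
them the global class list and zero-fills probabilities of classes absent
from a round's training set.

## Synthetic data

`generate_imbalanced_blobs` draws class `c` from an isotropic Gaussian at
vertex `c` of a regular simplex with edge length `separation × noise_sd`,
so `separation` is the inter-centroid distance in noise units: 0 means
indistinguishable classes (accuracy ≈ majority prior), ≥ 6 essentially
separable. `generate_toy_texture_images` produces small grayscale
sinusoidal gratings whose class sets the spatial frequency
(`2 + separation·c` cycles/image) plus pixel noise — a minimal stand-in
for fine-grained texture classes that differ subtly rather than
structurally.

What the generators deliberately do not emulate: stain/contrast
variability, intra-class heterogeneity, label noise, spatial correlation
of real tissue, or any covariate shift between labeled and unlabeled
pools. Passing tests on these fixtures therefore demonstrates the
*mechanics* — balanced selection, curriculum nesting, determinism, the
improvement of self-training over its own supervised baseline under label
scarcity — not performance on real histopathology.

`split_dataset` applies the protocol split: stratified 70/30 into a
training block and a pool block, the training block further split 70:30
into train and validation. By default the pool block serves as both the
unlabeled pool and the test set (transductive evaluation, matching the
protocol the method was designed under); `transductive=False` divides it
into disjoint halves for an honest inductive estimate. `withhold_labels`
moves a stratified complement of the training block into the pool to
emulate label scarcity.

## Study conditions used by the test suite and acceptance script

Chosen once as a realistic desk-scale analogue and kept fixed: two-class
blobs with 900/100 samples (9:1, matching the order of imbalance of the
motivating dataset), `separation = 4.0` (moderate overlap — hard enough
that extra pseudolabeled data can help, not so hard that confidence is
uninformative), 10% of the training block labeled, the default
incremental curriculum, 5 rounds, 5 repeat seeds. Solver–oracle
equivalence is checked on 1,000 random Dirichlet probability matrices
with N ≤ 200 and C ∈ {2, 8}.

## Experiment orchestration

`run_experiment` executes one configuration per master seed and writes
per-seed JSON (full round history, losses, test metrics, embedded resolved
config), the final pseudolabel assignment TSV (sample id, class or
IGNORED, confidence, round), and a summary aggregating seeds as
mean ± sample-s.d. (n−1 denominator; a single run reports ± 0.00). Reports
carry no timestamps and are serialized with sorted keys, so identical
configs produce byte-identical files. Image augmentation (uniform rotation
in ±90° with reflection padding — a rotation *range*, not discrete steps,
though a flag provides those — and horizontal flips at probability 0.5) is
available for image-mode data and is deterministic per seed.

## Metrics

Confusion matrices follow the rows-true/columns-predicted convention.
Precision, recall and F1 are computed per class from the matrix; the
headline average is the unweighted macro mean, which is the
imbalance-sensitive choice (a support-weighted variant is also reported).
A zero denominator yields 0 with a per-class degenerate flag rather than
NaN or an error.

## Known limitations

* Confidence calibration is taken on faith; an overconfident backend
  defeats the ranking that the thresholds rely on.
* With class flips enabled, per-class selected counts are only
  approximately `⌈p·N_c⌉`; exactness holds for threshold passage.
* The transductive default scores the model on the same pool it exploited
  during training; use the inductive split for generalization claims.
* The stopping rule compares single validation-accuracy values and can
  stop one round early on a noisy plateau; `improvement_tol < 0` trades
  patience for compute.
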