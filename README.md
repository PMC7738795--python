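# selfpaced

Self-training with self-paced, class-balanced pseudolabel selection for
imbalanced classification.

Labeled data is scarce and expensive in many imaging domains — breast-cancer
histopathology being the motivating case — while unlabeled images are
plentiful and the class distribution is heavily skewed. Self-training
exploits the unlabeled pool by letting the current model label it and
retraining on its own most confident predictions ("pseudolabels"). On
imbalanced data the naive version fails quietly: a single global confidence
cutoff admits almost exclusively majority-class pseudolabels, because the
top of the confidence ranking belongs to the class the model already knows
best. The rare classes — the ones that needed the extra data — are starved,
and early mistakes get reinforced across iterations.

This package implements a selection scheme that fixes both problems, usable
with any probabilistic classifier backend.

## The method

Given a model with softmax outputs `p_n(c | W)` and a selection fraction
`p ∈ (0, 1]`:

1. **Per-class thresholds by ranking.** Predict the whole unlabeled pool.
   For each class `c`, rank the class-`c` probabilities of the `N_c`
   samples whose argmax is `c` in descending order, and set the threshold
   `exp(−k_c)` to the probability at rank `⌈p · N_c⌉`. Each class thus
   gets its own bar, calibrated so that exactly its top `p·100%` clears it.
2. **Class-normalized solver.** Each sample `n` is assigned

   `ŷ_n = argmax_c  p_n(c) / exp(−k_c)`   if that ratio ≥ 1, else *ignored*.

   Dividing by `exp(−k_c)` boosts classes whose threshold is low — the
   less-represented, harder classes — so a sample with modest absolute
   confidence but high *intraclass* confidence can still be selected, and
   can even be relabeled away from its raw argmax.
3. **Self-paced curriculum.** The fraction starts at `p = 0.10` and grows
   by 0.05 each round (easy-to-hard): confident pseudolabels first,
   harder ones only after the model has improved.
4. **Iterate.** Train on labeled data (round 0, the supervised baseline);
   each round re-predict the *entire* pool, select, rebuild the training
   set as labeled ∪ current selections, and refit. Stop when validation
   accuracy stops improving or after 5 rounds.

The joint objective is
`L = −Σ_l log p(y_l) − Σ_t ŷ_t·log p(I_t) + Σ_t k_{c(t)}`,
cross-entropy on labeled and pseudolabeled samples plus the per-class
regularizer that prices each admitted pseudolabel. A baseline solver with a
single global cutoff `p_n(argmax) > exp(−k)` is included for comparison, as
is a polynomial learning-rate schedule
`α(e) = initLR · (1 − e/T)^p`.

The main entry points are the sklearn-style estimator
`SelfPacedSelfTrainingClassifier` (unlabeled samples marked `y = -1`, as in
`sklearn.semi_supervised`), the functional loop `run_self_training`, and
the selection primitives (`determine_class_thresholds`,
`solve_class_balanced`, `solve_vanilla`, `select_top_fraction`).

## Worked example

Imbalanced two-class Gaussian blobs (900 vs 100 samples, centroids 4
noise-s.d. apart), protocol split 70/30 with the 30% block as the
unlabeled pool, and only 10% of the training block labeled:

```python
import numpy as np
from selfpaced import (
    SyntheticConfig, generate_imbalanced_blobs, split_dataset, withhold_labels,
    run_self_training, SoftmaxRegression,
)

cfg = SyntheticConfig(per_class_counts=(900, 100), separation=4.0, dims=2, seed=7)
X, y = generate_imbalanced_blobs(cfg)
split = split_dataset(X, y, seed=7)
X_lab, y_lab, X_extra, _ = withhold_labels(split.X_train, split.y_train, 0.1, seed=7)
X_pool = np.concatenate([split.X_unlabeled, X_extra])

state = run_self_training(
    X_lab, y_lab, X_pool, split.X_val, split.y_val,
    selection_mode="class_balanced", seed=7,
)
for rec in state.history:
    print(f"round {rec.round}: p={rec.fraction:.2f}  "
          f"val_acc={rec.val_accuracy:.4f}  selected={rec.selected_per_class}")
print("stopped:", state.stopped_reason)

baseline = SoftmaxRegression().fit(X_lab, y_lab)
print(f"baseline test accuracy:   {np.mean(baseline.predict(split.X_test) == split.y_test):.4f}")
print(f"self-trained test accuracy: {np.mean(state.estimator.predict(split.X_test) == split.y_test):.4f}")
```

Output:

```
round 0: p=0.00  val_acc=0.9905  selected=[0, 0]
round 1: p=0.10  val_acc=0.9905  selected=[67, 8]
stopped: no_improvement
baseline test accuracy:   0.9867
self-trained test accuracy: 0.9900
```

Round 0 is the supervised baseline trained on the 63 labeled samples. In
round 1 the curriculum admits the top 10% of each predicted class — 67
majority and 8 minority pseudolabels, the minority represented in
proportion to its predicted pool rather than crowded out — and retraining
on the augmented set lifts test accuracy from 0.9867 to 0.9900. The
validation plateau then triggers the stopping rule.

The same experiment, repeated over seeds with reports on disk, runs from a
YAML config:

```bash
selfpaced run --config experiment.yaml
```

and `selfpaced generate / evaluate / compare` create synthetic fixtures,
score prediction files, and contrast the two selection policies on a saved
probability matrix.

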