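"""Loss evaluation and the polynomial learning-rate schedule.

The semisupervised objective is a sum of three pieces: cross-entropy on the
labeled set, cross-entropy on the pseudolabeled selections, and a per-class
regularizer ``sum_n k_{c(n)}`` that prices each admitted pseudolabel by how
far its class threshold ``exp(-k_c)`` sits below certainty.  The ``k``
term is constant in the model weights — it shapes which pseudolabels are
admitted, not the gradient step — so it is reported separately in the
breakdown and added to the scalar total under a configurable sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .selection import ClassThresholdSet, PseudoLabelAssignment, _as_proba_array

__all__ = [
    "LossBreakdown",
    "LRScheduleConfig",
    "labeled_cross_entropy",
    "joint_objective",
    "polynomial_decay",
]

#: Probabilities are clipped here before logs to avoid -inf on hard zeros.
DEFAULT_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class LossBreakdown:
    """Additive decomposition of the joint objective."""

    labeled_ce: float
    pseudo_ce: float
    kc_term: float
    total: float

    def to_dict(self) -> dict:
        return {
            "labeled_ce": self.labeled_ce,
            "pseudo_ce": self.pseudo_ce,
            "kc_term": self.kc_term,
            "total": self.total,
        }


@dataclass(frozen=True)
class LRScheduleConfig:
    """Polynomial learning-rate decay: ``init_lr * (1 - epoch/T)**power``.

    ``init_lr`` is the base rate at epoch 0; the rate reaches exactly 0 at
    ``total_epochs``; ``power=1`` gives linear decay.
    """

    init_lr: float = 0.001
    total_epochs: int = 50
    power: float = 1.0

    def __post_init__(self):
        if self.init_lr <= 0:
            raise ValueError("init_lr must be positive")
        if self.total_epochs <= 0:
            raise ValueError("total_epochs must be a positive integer")
        if self.power <= 0:
            raise ValueError("power must be positive")


def polynomial_decay(epoch: int, cfg: LRScheduleConfig) -> float:
    """Learning rate at ``epoch`` under polynomial decay.

    Valid for ``0 <= epoch <= cfg.total_epochs``; equals ``init_lr`` at
    epoch 0 and 0 at the final epoch.
    """
    if not 0 <= epoch <= cfg.total_epochs:
        raise ValueError(
            f"epoch must lie in [0, {cfg.total_epochs}], got {epoch}"
        )
    return cfg.init_lr * (1.0 - epoch / cfg.total_epochs) ** cfg.power


def labeled_cross_entropy(
    true_labels,
    P,
    *,
    floor: float = DEFAULT_PROB_FLOOR,
    reduction: str = "sum",
) -> float:
    """Softmax cross-entropy ``-sum_n log p_n(y_n)`` on the labeled set.

    ``reduction="mean"`` divides by the number of samples (useful when a
    backend optimizes the mean loss); the default matches the summation
    form of the objective.
    """
    arr = _as_proba_array(P)
    y = np.asarray(true_labels, dtype=int)
    if y.shape != (arr.shape[0],):
        raise ValueError("true_labels length must match number of rows")
    if y.size == 0:
        return 0.0
    if y.min() < 0 or y.max() >= arr.shape[1]:
        raise ValueError("label out of range for the class count")
    picked = np.clip(arr[np.arange(arr.shape[0]), y], floor, None)
    total = float(-np.sum(np.log(picked)))
    if reduction == "mean":
        return total / y.size
    if reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    return total


def joint_objective(
    true_labels,
    P_labeled,
    assignment: PseudoLabelAssignment,
    P_unlabeled,
    thresholds: ClassThresholdSet,
    *,
    kc_sign: float = 1.0,
    floor: float = DEFAULT_PROB_FLOOR,
) -> LossBreakdown:
    """Joint labeled + pseudolabeled objective with the per-class regularizer.

    ``pseudo_ce = -sum_n log p_n(c_hat_n)`` over the selected samples and
    ``kc_term = sum_n k_{c_hat_n}`` with ``k_c = -log thresholds[c]``;
    IGNORED samples contribute nothing.  A selection referencing a
    sentinel-threshold class is a contract violation and raises.

    The scalar ``total`` is ``labeled_ce + pseudo_ce + kc_sign * kc_term``.
    """
    labeled_ce = labeled_cross_entropy(true_labels, P_labeled, floor=floor)
    arr_u = _as_proba_array(P_unlabeled)
    if assignment.labels.shape[0] != arr_u.shape[0]:
        raise ValueError("assignment is not aligned with the unlabeled matrix")
    sel = assignment.selected
    pseudo_ce = 0.0
    kc_term = 0.0
    if np.any(sel):
        classes = assignment.labels[sel]
        thr = thresholds.thresholds[classes]
        if np.any(np.isnan(thr)):
            bad = int(classes[np.isnan(thr)][0])
            raise ValueError(
                f"assignment references class {bad}, which has a sentinel threshold"
            )
        picked = np.clip(arr_u[np.flatnonzero(sel), classes], floor, None)
        pseudo_ce = float(-np.sum(np.log(picked)))
        kc_term = float(np.sum(-np.log(thr)))
    total = labeled_ce + pseudo_ce + kc_sign * kc_term
    return LossBreakdown(
        labeled_ce=labeled_ce, pseudo_ce=pseudo_ce, kc_term=kc_term, total=total
    )
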