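"""Iterative self-training under a self-paced curriculum.

The loop: fit the backend on the labeled set (round 0, the supervised
baseline), then each round predict the *entire* unlabeled pool, derive
per-class thresholds at the current curriculum fraction, select
pseudolabels, rebuild the training set as labeled + current selections,
and refit.  Pseudolabels are regenerated from scratch every round — stale
labels are never carried forward, which limits mistake reinforcement — and
the base labeled set is never relabeled or dropped.

The curriculum starts with the most confident 10% of each predicted class
and adds 5 percentage points per round ("easy-to-hard"), until either a
round fails to improve validation accuracy or the round budget (default 5)
is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .backends import SoftmaxRegression, clone_backend, predict_proba_in_classes
from .objective import joint_objective
from .selection import (
    PseudoLabelAssignment,
    determine_class_thresholds,
    select_top_fraction,
    solve_class_balanced,
)

__all__ = [
    "CurriculumSchedule",
    "RoundRecord",
    "StopDecision",
    "SelfTrainingState",
    "curriculum_fraction",
    "augment_training_set",
    "should_stop",
    "run_self_training",
    "SelfPacedSelfTrainingClassifier",
]

#: Unlabeled marker in the estimator's ``fit(X, y)`` interface.
UNLABELED = -1


@dataclass(frozen=True)
class CurriculumSchedule:
    """Selection-fraction policy over self-training rounds.

    ``incremental`` mode grows the fraction ``min(1, p0 + r * increment)``
    with the round index ``r`` (defaults 10% + 5%/round); ``fixed`` mode
    uses ``initial_fraction`` every round.  ``max_rounds`` caps the number
    of self-training rounds and ``improvement_tol`` is the slack on the
    validation-accuracy stopping rule.
    """

    mode: str = "incremental"
    initial_fraction: float = 0.10
    increment: float = 0.05
    max_rounds: int = 5
    improvement_tol: float = 0.0

    def __post_init__(self):
        if self.mode not in ("incremental", "fixed"):
            raise ValueError(f"mode must be 'incremental' or 'fixed', got {self.mode!r}")
        if not 0 < self.initial_fraction <= 1:
            raise ValueError("initial_fraction must be in (0, 1]")
        if self.increment < 0:
            raise ValueError("increment must be >= 0")
        if self.max_rounds < 0:
            raise ValueError("max_rounds must be >= 0")


def curriculum_fraction(round_index: int, sched: CurriculumSchedule) -> float:
    """Selection fraction used at self-paced round ``round_index`` (0-based)."""
    if round_index < 0:
        raise ValueError("round_index must be >= 0")
    if sched.mode == "fixed":
        return sched.initial_fraction
    return min(1.0, sched.initial_fraction + round_index * sched.increment)


@dataclass
class RoundRecord:
    """Per-round history entry of a self-training run."""

    round: int
    fraction: float
    val_accuracy: float
    selected_per_class: list
    n_selected: int
    flip_count: int
    losses: dict

    def to_dict(self) -> dict:
        return {
            "round": self.round,
            "fraction": self.fraction,
            "val_accuracy": self.val_accuracy,
            "selected_per_class": list(map(int, self.selected_per_class)),
            "n_selected": int(self.n_selected),
            "flip_count": int(self.flip_count),
            "losses": self.losses,
        }


@dataclass(frozen=True)
class StopDecision:
    stop: bool
    reason: str | None = None


@dataclass
class SelfTrainingState:
    """Result of a self-training run: final model plus full history."""

    estimator: object
    classes: np.ndarray
    history: list = field(default_factory=list)
    stopped_reason: str = ""
    provenance: pd.DataFrame | None = None
    final_assignment: PseudoLabelAssignment | None = None

    @property
    def baseline_accuracy(self) -> float:
        return self.history[0].val_accuracy

    @property
    def final_accuracy(self) -> float:
        return self.history[-1].val_accuracy


def augment_training_set(
    X_labeled,
    y_labeled,
    X_unlabeled,
    assignment: PseudoLabelAssignment,
    *,
    classes=None,
    round_index: int = 0,
):
    """Union of the labeled set with the current round's selections.

    Returns ``(X, y, provenance)`` where provenance is a DataFrame with one
    row per training example: ``source`` ('labeled' or 'pseudo'), the index
    into the source array, and the round the pseudolabel was produced in.
    Original labeled entries are passed through unchanged; the pseudo block
    is rebuilt from scratch each round, so labels can never accumulate or
    duplicate across rounds.
    """
    X_l = np.asarray(X_labeled)
    y_l = np.asarray(y_labeled)
    X_u = np.asarray(X_unlabeled)
    if assignment.labels.shape[0] != X_u.shape[0]:
        raise ValueError("assignment is not aligned with the unlabeled samples")
    sel = np.flatnonzero(assignment.selected)
    col_labels = assignment.labels[sel]
    y_pseudo = (
        np.asarray(classes)[col_labels] if classes is not None else col_labels
    )
    X = np.concatenate([X_l, X_u[sel]], axis=0) if sel.size else X_l.copy()
    y = np.concatenate([y_l, y_pseudo], axis=0) if sel.size else y_l.copy()
    provenance = pd.DataFrame(
        {
            "source": ["labeled"] * len(y_l) + ["pseudo"] * sel.size,
            "source_index": np.concatenate([np.arange(len(y_l)), sel]),
            "round": [0] * len(y_l) + [round_index] * sel.size,
        }
    )
    return X, y, provenance


def should_stop(history, sched: CurriculumSchedule) -> StopDecision:
    """Apply the stopping rule to the run history.

    Stops with reason ``max_rounds`` once the latest completed self-paced
    round reaches ``sched.max_rounds``, and with ``no_improvement`` when
    the latest validation accuracy fails to exceed the previous round's by
    more than ``improvement_tol``.  Accepts a list of
    :class:`RoundRecord` or plain accuracy floats.
    """
    if len(history) == 0:
        return StopDecision(False)
    if isinstance(history[-1], RoundRecord):
        accs = [h.val_accuracy for h in history]
        rounds_done = history[-1].round
    else:
        accs = [float(h) for h in history]
        rounds_done = len(accs)
    if rounds_done >= sched.max_rounds:
        return StopDecision(True, "max_rounds")
    if len(accs) >= 2 and accs[-1] <= accs[-2] + sched.improvement_tol:
        return StopDecision(True, "no_improvement")
    return StopDecision(False)


def _accuracy(estimator, X, y) -> float:
    if len(y) == 0:
        return float("nan")
    return float(np.mean(estimator.predict(X) == np.asarray(y)))


def run_self_training(
    X_labeled,
    y_labeled,
    X_unlabeled,
    X_val,
    y_val,
    backend=None,
    sched: CurriculumSchedule | None = None,
    selection_mode: str = "class_balanced",
    seed: int = 0,
    *,
    eps: float = 1e-12,
    restrict_to_argmax: bool = False,
) -> SelfTrainingState:
    """Execute the full self-training loop.

    Round 0 is the purely supervised fit on the labeled set.  Each later
    round ``r`` predicts every unlabeled sample, selects pseudolabels at
    ``curriculum_fraction(r - 1)``, rebuilds the training set as
    labeled + selections, and refits a fresh backend seeded ``seed + r``.
    Deterministic given the seed and inputs.

    ``selection_mode`` is ``"class_balanced"`` (per-class thresholds,
    normalized solver) or ``"vanilla"`` (global matched-count cutoff).
    """
    if backend is None:
        backend = SoftmaxRegression()
    if sched is None:
        sched = CurriculumSchedule()
    X_l = np.asarray(X_labeled, dtype=float)
    y_l = np.asarray(y_labeled)
    X_u = np.asarray(X_unlabeled, dtype=float)
    classes = np.unique(y_l)
    if classes.shape[0] < 2:
        raise ValueError("labeled set must cover at least 2 classes")

    est = clone_backend(backend, random_state=seed).fit(X_l, y_l)
    y_l_idx = np.searchsorted(classes, y_l)
    P_l = predict_proba_in_classes(est, X_l, classes)
    history = [
        RoundRecord(
            round=0,
            fraction=0.0,
            val_accuracy=_accuracy(est, X_val, y_val),
            selected_per_class=[0] * classes.shape[0],
            n_selected=0,
            flip_count=0,
            losses=joint_objective(
                y_l_idx,
                P_l,
                PseudoLabelAssignment(
                    labels=np.full(0, -1, dtype=int), confidences=np.zeros(0)
                ),
                np.zeros((0, classes.shape[0])) + 1.0 / classes.shape[0],
                determine_class_thresholds(P_l, 1.0),
            ).to_dict(),
        )
    ]
    state = SelfTrainingState(estimator=est, classes=classes, history=history)
    if X_u.shape[0] == 0 or sched.max_rounds == 0:
        state.stopped_reason = "max_rounds"
        return state

    for r in range(1, sched.max_rounds + 1):
        frac = curriculum_fraction(r - 1, sched)
        P_u = predict_proba_in_classes(est, X_u, classes)
        thresholds = determine_class_thresholds(P_u, frac)
        if selection_mode == "class_balanced":
            assignment = solve_class_balanced(
                P_u, thresholds, eps=eps, restrict_to_argmax=restrict_to_argmax
            )
        elif selection_mode == "vanilla":
            assignment = select_top_fraction(P_u, frac, mode="vanilla")
        else:
            raise ValueError(f"unknown selection_mode {selection_mode!r}")

        raw_argmax = np.argmax(P_u, axis=1)
        sel = assignment.selected
        flips = int(np.count_nonzero(assignment.labels[sel] != raw_argmax[sel]))

        losses = joint_objective(
            y_l_idx,
            predict_proba_in_classes(est, X_l, classes),
            assignment,
            P_u,
            thresholds,
        )
        X_aug, y_aug, provenance = augment_training_set(
            X_l, y_l, X_u, assignment, classes=classes, round_index=r
        )
        est = clone_backend(backend, random_state=seed + r).fit(X_aug, y_aug)
        history.append(
            RoundRecord(
                round=r,
                fraction=frac,
                val_accuracy=_accuracy(est, X_val, y_val),
                selected_per_class=[
                    int(v) for v in assignment.counts_per_class(classes.shape[0])
                ],
                n_selected=assignment.n_selected,
                flip_count=flips,
                losses=losses.to_dict(),
            )
        )
        state.estimator = est
        state.provenance = provenance
        state.final_assignment = assignment
        decision = should_stop(history, sched)
        if decision.stop:
            state.stopped_reason = decision.reason
            return state
    state.stopped_reason = "max_rounds"
    return state


class SelfPacedSelfTrainingClassifier(BaseEstimator, ClassifierMixin):
    """Semisupervised classifier: self-training with class-balanced selection.

    Follows the sklearn semisupervised convention: ``fit(X, y)`` where
    unlabeled samples carry the label ``-1``.  A stratified
    ``validation_fraction`` of the labeled samples is held out to drive the
    no-improvement stopping rule; the rest seed the supervised baseline.

    Parameters
    ----------
    backend : estimator, optional
        Probabilistic classifier (``fit`` / ``predict_proba`` /
        ``classes_``).  Defaults to :class:`SoftmaxRegression`.
    selection_mode : {"class_balanced", "vanilla"}
        Per-class-threshold normalized selection, or the global
        matched-count confidence cutoff.
    curriculum_mode : {"incremental", "fixed"}
    initial_fraction, increment : float
        Curriculum start (default 10%) and per-round growth (default 5
        percentage points).
    max_rounds : int, default=5
    improvement_tol : float, default=0.0
        Slack on the validation-accuracy stopping comparison.
    validation_fraction : float, default=0.3
        Share of labeled data held out for the stopping rule.
    eps : float, default=1e-12
        Slack in the normalized-ratio acceptance test.
    restrict_to_argmax : bool, default=False
        Confine each sample's pseudolabel to its raw argmax class.
    random_state : int, default=0
        Master seed; round ``r`` refits use ``random_state + r``.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in the labeled data.
    estimator_ : object
        Final fitted backend.
    history_ : list of RoundRecord
    stopped_reason_ : str
    n_rounds_ : int
        Completed self-paced rounds (round 0 baseline excluded).
    """

    def __init__(
        self,
        backend=None,
        selection_mode: str = "class_balanced",
        curriculum_mode: str = "incremental",
        initial_fraction: float = 0.10,
        increment: float = 0.05,
        max_rounds: int = 5,
        improvement_tol: float = 0.0,
        validation_fraction: float = 0.3,
        eps: float = 1e-12,
        restrict_to_argmax: bool = False,
        random_state: int = 0,
    ):
        self.backend = backend
        self.selection_mode = selection_mode
        self.curriculum_mode = curriculum_mode
        self.initial_fraction = initial_fraction
        self.increment = increment
        self.max_rounds = max_rounds
        self.improvement_tol = improvement_tol
        self.validation_fraction = validation_fraction
        self.eps = eps
        self.restrict_to_argmax = restrict_to_argmax
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        labeled = y != UNLABELED
        X_l, y_l = X[labeled], y[labeled]
        X_u = X[~labeled]
        if np.unique(y_l).shape[0] < 2:
            raise ValueError("labeled samples must cover at least 2 classes")
        if 0 < self.validation_fraction < 1 and len(y_l) >= 4:
            X_tr, X_val, y_tr, y_val = train_test_split(
                X_l,
                y_l,
                test_size=self.validation_fraction,
                stratify=y_l,
                random_state=self.random_state,
            )
        else:
            X_tr, y_tr, X_val, y_val = X_l, y_l, X_l, y_l
        sched = CurriculumSchedule(
            mode=self.curriculum_mode,
            initial_fraction=self.initial_fraction,
            increment=self.increment,
            max_rounds=self.max_rounds,
            improvement_tol=self.improvement_tol,
        )
        state = run_self_training(
            X_tr,
            y_tr,
            X_u,
            X_val,
            y_val,
            backend=self.backend,
            sched=sched,
            selection_mode=self.selection_mode,
            seed=self.random_state,
            eps=self.eps,
            restrict_to_argmax=self.restrict_to_argmax,
        )
        self.classes_ = state.classes
        self.estimator_ = state.estimator
        self.history_ = state.history
        self.stopped_reason_ = state.stopped_reason
        self.state_ = state
        self.n_rounds_ = state.history[-1].round
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        return predict_proba_in_classes(
            self.estimator_, np.asarray(X, dtype=float), self.classes_
        )
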