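"""Pseudolabel generation and selection.

Self-training promotes unlabeled samples into the training set by trusting
the current model's most confident predictions.  On imbalanced data a single
global confidence cutoff starves rare classes: the majority class dominates
the top of the confidence ranking, so its pseudolabels crowd out everyone
else's.  The class-balanced scheme implemented here fixes this by ranking
confidences *within* each predicted class and deriving one threshold per
class, so the top ``p*100%`` of every class qualifies regardless of how many
samples that class attracted.

Two solvers are provided:

* :func:`solve_vanilla` — a single global cutoff ``exp(-k)`` on the argmax
  probability (the classic confidence-thresholded pseudolabeler).
* :func:`solve_class_balanced` — each sample's probabilities are divided by
  the per-class thresholds ``exp(-k_c)``; the sample is labeled with the
  class of the largest *normalized* score provided that score reaches 1.
  Dividing by a small minority-class threshold boosts that class's scores,
  which is what lets high intraclass confidence beat high absolute
  confidence.

Per-class thresholds come from :func:`determine_class_thresholds`: for each
class ``c``, sort the class-``c`` probabilities of the samples whose argmax
is ``c`` in descending order and read off the value at rank
``ceil(p * N_c)``.  ``exp(-k_c)`` is that value, so exactly the top
``p*100%`` of each class sits at or above its threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

__all__ = [
    "IGNORED",
    "ProbabilityMatrix",
    "ClassThresholdSet",
    "PseudoLabelAssignment",
    "predicted_class_counts",
    "determine_class_thresholds",
    "solve_class_balanced",
    "solve_vanilla",
    "select_top_fraction",
]

#: Label value marking a sample that contributes no pseudolabeled example.
IGNORED: int = -1


def _as_proba_array(P) -> np.ndarray:
    """Coerce input to a validated (N, C) probability array."""
    if isinstance(P, ProbabilityMatrix):
        return P.values
    arr = np.asarray(P, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"probability matrix must be 2-D, got shape {arr.shape}")
    if arr.shape[1] < 2:
        raise ValueError("probability matrix needs at least 2 classes")
    if arr.size and (arr.min() < -1e-9 or arr.max() > 1 + 1e-9):
        raise ValueError("probabilities must lie in [0, 1]")
    if arr.size:
        rowsums = arr.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-6):
            bad = int(np.argmax(np.abs(rowsums - 1.0)))
            raise ValueError(
                f"row {bad} sums to {rowsums[bad]:.8f}, not 1 within 1e-6"
            )
    return arr


@dataclass(frozen=True)
class ProbabilityMatrix:
    """Per-sample class-probability output of a classifier.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_classes)
        Softmax outputs; every row must sum to 1 within ``1e-6``.
    sample_ids : ndarray of shape (n_samples,), optional
        Opaque identifiers; defaults to ``arange(n_samples)``.
    """

    values: np.ndarray
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        arr = _as_proba_array(self.values)
        object.__setattr__(self, "values", arr)
        ids = self.sample_ids
        if ids is None:
            ids = np.arange(arr.shape[0])
        else:
            ids = np.asarray(ids)
            if ids.shape != (arr.shape[0],):
                raise ValueError("sample_ids length must match number of rows")
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ClassThresholdSet:
    """Per-class confidence thresholds ``exp(-k_c)``.

    ``thresholds[c]`` is NaN (the sentinel) for a class no sample was
    predicted as: such a class is unselectable this round.  ``counts[c]``
    is ``N_c``, the number of samples argmax-predicted as class ``c``, and
    ``fraction`` is the selection fraction ``p`` the thresholds encode.
    """

    thresholds: np.ndarray
    counts: np.ndarray
    fraction: float

    def __post_init__(self):
        thr = np.asarray(self.thresholds, dtype=float)
        cnt = np.asarray(self.counts, dtype=int)
        if thr.shape != cnt.shape or thr.ndim != 1:
            raise ValueError("thresholds and counts must be 1-D with equal length")
        ok = cnt > 0
        if np.any(np.isnan(thr[ok])):
            raise ValueError("finite threshold required for every nonempty class")
        if thr[ok].size and (thr[ok].min() <= 0 or thr[ok].max() > 1):
            raise ValueError("thresholds of nonempty classes must lie in (0, 1]")
        object.__setattr__(self, "thresholds", thr)
        object.__setattr__(self, "counts", cnt)

    @property
    def n_classes(self) -> int:
        return self.thresholds.shape[0]

    @property
    def k_values(self) -> np.ndarray:
        """Per-class ``k_c = -log(threshold)``; NaN for sentinel classes."""
        with np.errstate(invalid="ignore"):
            return -np.log(self.thresholds)


@dataclass(frozen=True)
class PseudoLabelAssignment:
    """Outcome of a pseudolabel solver.

    ``labels[n]`` is a class index or :data:`IGNORED`; ``confidences[n]``
    is the deciding score (the normalized ratio for the class-balanced
    solver, the raw argmax probability for the vanilla one).
    """

    labels: np.ndarray
    confidences: np.ndarray
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        lab = np.asarray(self.labels, dtype=int)
        conf = np.asarray(self.confidences, dtype=float)
        if lab.shape != conf.shape or lab.ndim != 1:
            raise ValueError("labels and confidences must be 1-D with equal length")
        ids = self.sample_ids
        if ids is None:
            ids = np.arange(lab.shape[0])
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "confidences", conf)
        object.__setattr__(self, "sample_ids", np.asarray(ids))

    @property
    def selected(self) -> np.ndarray:
        """Boolean mask of samples that received a pseudolabel."""
        return self.labels != IGNORED

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.selected))

    def counts_per_class(self, n_classes: int) -> np.ndarray:
        """Number of assigned pseudolabels per class."""
        sel = self.labels[self.selected]
        return np.bincount(sel, minlength=n_classes)

    def to_frame(self, round_index: int = 0) -> pd.DataFrame:
        """Tabular form: sample_id, assigned_class (or 'IGNORED'), confidence, round."""
        assigned = np.where(
            self.selected, self.labels.astype(str), "IGNORED"
        )
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "assigned_class": assigned,
                "confidence": self.confidences,
                "round": round_index,
            }
        )


def predicted_class_counts(P) -> np.ndarray:
    """Count samples argmax-predicted per class (``N_c``).

    Ties in a row are broken toward the lowest class index.  Raises on an
    empty matrix (no predictions to count).
    """
    arr = _as_proba_array(P)
    if arr.shape[0] == 0:
        raise ValueError("no predictions available: probability matrix is empty")
    pred = np.argmax(arr, axis=1)  # np.argmax returns the first (lowest) max index
    return np.bincount(pred, minlength=arr.shape[1])


def determine_class_thresholds(P, fraction: float) -> ClassThresholdSet:
    """Derive per-class thresholds ``exp(-k_c)`` by within-class ranking.

    For each class ``c`` with ``N_c > 0`` samples argmax-predicted as ``c``,
    the class-``c`` probabilities of those samples are sorted in descending
    order and the threshold is the value at 1-based rank
    ``ceil(fraction * N_c)`` — so at least one sample per nonempty class is
    always selectable and ``fraction=1`` admits them all.  Classes with
    ``N_c = 0`` get a NaN sentinel (unselectable this round).

    Parameters
    ----------
    P : array-like or ProbabilityMatrix, shape (n_samples, n_classes)
    fraction : float in (0, 1]
        Selection fraction ``p``.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    arr = _as_proba_array(P)
    counts = predicted_class_counts(arr)
    pred = np.argmax(arr, axis=1)
    C = arr.shape[1]
    thresholds = np.full(C, np.nan)
    for c in range(C):
        if counts[c] == 0:
            continue
        probs = np.sort(arr[pred == c, c])[::-1]
        rank = ceil(fraction * counts[c])  # 1-based
        thresholds[c] = probs[rank - 1]
    return ClassThresholdSet(thresholds=thresholds, counts=counts, fraction=fraction)


def solve_class_balanced(
    P,
    thresholds: ClassThresholdSet,
    *,
    eps: float = 1e-12,
    restrict_to_argmax: bool = False,
) -> PseudoLabelAssignment:
    """Assign pseudolabels by class-wise normalized confidence.

    Each sample's probabilities are divided by the per-class thresholds,
    ``r_c = p_n(c) / exp(-k_c)``; the sample is labeled
    ``argmax_c r_c`` (ties to the lowest class index) when that ratio
    reaches ``1 - eps``, else :data:`IGNORED`.  The ``eps`` slack keeps the
    rank-defining sample itself selectable despite floating-point division.

    Normalization can relabel a sample into a class other than its raw
    argmax ("class flip"): a minority class with a low threshold may win
    the ratio comparison.  Set ``restrict_to_argmax=True`` to confine each
    sample to its raw argmax class (only that class's ratio is considered).

    Sentinel (NaN) thresholds exclude their class from the comparison; if
    every class is sentinel, all samples are IGNORED and a warning is
    emitted.
    """
    arr = _as_proba_array(P)
    thr = thresholds.thresholds
    if thr.shape[0] != arr.shape[1]:
        raise ValueError(
            f"threshold set has {thr.shape[0]} classes, matrix has {arr.shape[1]}"
        )
    ids = P.sample_ids if isinstance(P, ProbabilityMatrix) else None
    n = arr.shape[0]
    if np.all(np.isnan(thr)):
        warnings.warn(
            "all class thresholds are sentinels; every sample is IGNORED",
            stacklevel=2,
        )
        return PseudoLabelAssignment(
            labels=np.full(n, IGNORED),
            confidences=np.zeros(n),
            sample_ids=ids,
        )
    with np.errstate(invalid="ignore"):
        ratios = arr / thr[None, :]
    ratios = np.where(np.isnan(thr)[None, :], -np.inf, ratios)
    if restrict_to_argmax:
        pred = np.argmax(arr, axis=1)
        mask = np.full_like(ratios, -np.inf)
        mask[np.arange(n), pred] = ratios[np.arange(n), pred]
        ratios = mask
    best = np.argmax(ratios, axis=1)
    best_ratio = ratios[np.arange(n), best]
    labels = np.where(best_ratio >= 1 - eps, best, IGNORED)
    return PseudoLabelAssignment(
        labels=labels, confidences=np.where(np.isfinite(best_ratio), best_ratio, 0.0),
        sample_ids=ids,
    )


def solve_vanilla(P, k: float) -> PseudoLabelAssignment:
    """Assign pseudolabels by a single global confidence cutoff.

    Sample ``n`` receives its raw argmax class iff
    ``p_n(argmax) > exp(-k)`` (strict); otherwise IGNORED.  ``k = 0`` means
    a cutoff of 1, which no probability can exceed, so nothing is selected.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    arr = _as_proba_array(P)
    ids = P.sample_ids if isinstance(P, ProbabilityMatrix) else None
    pred = np.argmax(arr, axis=1)
    top = arr[np.arange(arr.shape[0]), pred]
    cutoff = np.exp(-k)
    labels = np.where(top > cutoff, pred, IGNORED)
    return PseudoLabelAssignment(labels=labels, confidences=top, sample_ids=ids)


def select_top_fraction(
    P,
    fraction: float,
    mode: str = "class_balanced",
    *,
    eps: float = 1e-12,
    restrict_to_argmax: bool = False,
) -> PseudoLabelAssignment:
    """Select the most confident ``fraction*100%`` of pseudolabels.

    ``mode="class_balanced"`` composes :func:`determine_class_thresholds`
    with :func:`solve_class_balanced`: the top fraction of *each* predicted
    class passes its class threshold, so minority classes are represented
    proportionally.

    ``mode="vanilla"`` selects the same total number of samples,
    ``ceil(fraction * N)``, but globally by descending argmax probability
    (ties broken by ascending sample index) — the matched-count baseline
    that lets the two policies be compared at equal budget.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    arr = _as_proba_array(P)
    ids = P.sample_ids if isinstance(P, ProbabilityMatrix) else None
    if mode == "class_balanced":
        thr = determine_class_thresholds(arr, fraction)
        out = solve_class_balanced(
            arr, thr, eps=eps, restrict_to_argmax=restrict_to_argmax
        )
        return PseudoLabelAssignment(
            labels=out.labels, confidences=out.confidences, sample_ids=ids
        )
    if mode == "vanilla":
        n = arr.shape[0]
        if n == 0:
            raise ValueError("no predictions available: probability matrix is empty")
        pred = np.argmax(arr, axis=1)
        top = arr[np.arange(n), pred]
        budget = ceil(fraction * n)
        # stable sort on ascending index inside descending confidence
        order = np.lexsort((np.arange(n), -top))
        chosen = order[:budget]
        labels = np.full(n, IGNORED)
        labels[chosen] = pred[chosen]
        return PseudoLabelAssignment(labels=labels, confidences=top, sample_ids=ids)
    raise ValueError(f"unknown mode {mode!r}; expected 'class_balanced' or 'vanilla'")
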