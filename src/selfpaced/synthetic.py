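"""Synthetic imbalanced datasets for exercising the self-training stack.

Two desk-scale generators mirror the statistical structure the method is
designed for — a multiclass problem with a skewed class distribution (for
instance the roughly 2:1 benign/malignant split, or the much harsher
subtype imbalance, of a typical histopathology collection) and tunable
class separation:

* :func:`generate_imbalanced_blobs` — feature vectors from isotropic
  Gaussians whose centroids sit at a controlled pairwise distance measured
  in noise standard deviations, so ``separation`` maps directly onto task
  difficulty (0 = indistinguishable classes, >5 = essentially separable).
* :func:`generate_toy_texture_images` — small grayscale gratings whose
  class sets the spatial frequency, a cartoon of fine-grained texture
  classes that differ subtly rather than structurally.

:func:`split_dataset` reproduces the standard protocol: a stratified 70/30
split into a training block and a test/unlabeled block, the training block
further split 70:30 into train and validation.  By default the 30% block
plays both the unlabeled-pool and test-set roles (transductive
evaluation); an inductive flag splits it into disjoint halves instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = [
    "SyntheticConfig",
    "DatasetSplit",
    "generate_imbalanced_blobs",
    "generate_toy_texture_images",
    "split_dataset",
    "withhold_labels",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Recipe for a synthetic dataset.

    ``per_class_counts`` fixes both the class count and the imbalance
    profile; ``separation`` is the pairwise inter-centroid distance in
    units of the noise standard deviation (feature mode) or the per-class
    spacing of grating frequencies in cycles per image (image mode).
    """

    per_class_counts: tuple
    separation: float = 4.0
    dims: int = 2
    image_size: int = 16
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        counts = tuple(int(c) for c in self.per_class_counts)
        if len(counts) < 2:
            raise ValueError("need at least 2 classes")
        if any(c < 1 for c in counts):
            raise ValueError("every class needs at least 1 sample")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.dims < 1:
            raise ValueError("dims must be >= 1")
        if self.image_size < 2:
            raise ValueError("image_size must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "per_class_counts", counts)

    @property
    def class_count(self) -> int:
        return len(self.per_class_counts)

    @property
    def total(self) -> int:
        return sum(self.per_class_counts)


def _simplex_centroids(C: int, dims: int, distance: float) -> np.ndarray:
    """C centroids in `dims` dimensions at equal pairwise `distance`."""
    if dims < C - 1:
        raise ValueError(
            f"{C} equidistant centroids need at least {C - 1} dimensions, got {dims}"
        )
    V = np.eye(C) * distance / np.sqrt(2)  # pairwise distance = `distance`
    V = V - V.mean(axis=0)
    # rotate into the (C-1)-dimensional affine hull
    U, s, _ = np.linalg.svd(V, full_matrices=False)
    coords = U[:, : C - 1] * s[: C - 1]
    out = np.zeros((C, dims))
    out[:, : C - 1] = coords
    return out


def generate_imbalanced_blobs(cfg: SyntheticConfig):
    """Gaussian-blob features with controllable imbalance and separation.

    Class ``c`` is drawn from an isotropic Gaussian (s.d. ``noise_sd``)
    centred on vertex ``c`` of a regular simplex whose edge length is
    ``separation * noise_sd``.  Deterministic given ``cfg.seed``.

    Returns ``(X, y)`` with ``X`` of shape (N, dims) and integer labels.
    """
    rng = np.random.default_rng(cfg.seed)
    C = cfg.class_count
    centroids = _simplex_centroids(C, cfg.dims, cfg.separation * cfg.noise_sd)
    xs, ys = [], []
    for c, n_c in enumerate(cfg.per_class_counts):
        xs.append(centroids[c] + cfg.noise_sd * rng.standard_normal((n_c, cfg.dims)))
        ys.append(np.full(n_c, c))
    return np.concatenate(xs), np.concatenate(ys)


def generate_toy_texture_images(cfg: SyntheticConfig):
    """Grayscale periodic-texture images, one grating frequency per class.

    Class ``c`` uses a horizontal sinusoidal grating of frequency
    ``2 + separation * c`` cycles per image, plus i.i.d. Gaussian pixel
    noise of s.d. ``noise_sd`` (sensible values here are ~0.05-0.2; pixel
    range is [0, 1]).  With ``noise_sd=0`` all images of a class are
    identical; with ``separation=0`` all classes share one frequency.

    Returns ``(images, y)`` with images of shape (N, size, size) in [0, 1].
    """
    rng = np.random.default_rng(cfg.seed)
    s = cfg.image_size
    x = np.arange(s) / s
    imgs, ys = [], []
    for c, n_c in enumerate(cfg.per_class_counts):
        freq = 2.0 + cfg.separation * c
        base = 0.5 + 0.3 * np.sin(2 * np.pi * freq * x)[None, :]
        pattern = np.broadcast_to(base, (s, s))
        noise = cfg.noise_sd * rng.standard_normal((n_c, s, s))
        imgs.append(np.clip(pattern[None, :, :] + noise, 0.0, 1.0))
        ys.append(np.full(n_c, c))
    return np.concatenate(imgs), np.concatenate(ys)


@dataclass
class DatasetSplit:
    """Protocol split of a dataset.

    ``y_unlabeled_true`` holds the withheld labels of the unlabeled pool
    for scoring only; it is never to be passed to ``fit``.  Under the
    default transductive protocol ``X_test``/``y_test`` alias the
    unlabeled block.
    """

    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    X_unlabeled: np.ndarray
    y_unlabeled_true: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray


def split_dataset(X, y, seed: int = 0, *, transductive: bool = True) -> DatasetSplit:
    """Stratified 70/30 + 70:30 protocol split.

    70% of the data forms the training block and 30% the test/unlabeled
    block; the training block is further split 70:30 into train and
    validation.  All splits are stratified by class.  With
    ``transductive=True`` (default) the 30% block serves as both the
    unlabeled pool and the test set; otherwise it is divided into two
    disjoint stratified halves.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if len(y) < 10:
        raise ValueError("need at least 10 samples to split")
    classes, counts = np.unique(y, return_counts=True)
    min_needed = 7 if transductive else 8
    too_small = classes[counts < min_needed]
    if too_small.size:
        raise ValueError(
            f"class {too_small[0].item()!r} has too few samples "
            f"({int(counts[classes == too_small[0]][0])}) to stratify the split"
        )
    X_block, X_pool, y_block, y_pool = train_test_split(
        X, y, test_size=0.3, stratify=y, random_state=seed
    )
    X_train, X_val, y_train, y_val = train_test_split(
        X_block, y_block, test_size=0.3, stratify=y_block, random_state=seed
    )
    if transductive:
        return DatasetSplit(
            X_train, y_train, X_val, y_val, X_pool, y_pool, X_pool, y_pool
        )
    X_unl, X_test, y_unl, y_test = train_test_split(
        X_pool, y_pool, test_size=0.5, stratify=y_pool, random_state=seed
    )
    return DatasetSplit(
        X_train, y_train, X_val, y_val, X_unl, y_unl, X_test, y_test
    )


def withhold_labels(X, y, labeled_fraction: float, seed: int = 0):
    """Keep a stratified fraction of labels; move the rest to the pool.

    Emulates label scarcity: returns
    ``(X_labeled, y_labeled, X_unlabeled, y_unlabeled_true)`` where the
    final array is ground truth retained for scoring only.
    """
    if not 0 < labeled_fraction < 1:
        raise ValueError("labeled_fraction must be in (0, 1)")
    X = np.asarray(X)
    y = np.asarray(y)
    X_l, X_u, y_l, y_u = train_test_split(
        X, y, train_size=labeled_fraction, stratify=y, random_state=seed
    )
    return X_l, y_l, X_u, y_u
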