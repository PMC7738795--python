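"""Dataset readers/writers and image augmentation.

Image folders follow the class-per-subdirectory layout common to
histopathology collections: ``root/<class_name>/*.png``, with an optional
magnification token embedded in filenames (e.g. ``...-40X-...``).  Class
indices are assigned by lexicographic subdirectory order so they are
stable across file systems.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "read_image_folder",
    "write_image_folder",
    "save_feature_table",
    "load_feature_table",
    "augment_batch",
]


def read_image_folder(
    path,
    magnification: str | None = None,
    image_size: int = 32,
):
    """Load a class-per-subdirectory folder of PNG images.

    Images are converted to grayscale, resized to
    ``image_size × image_size`` and scaled to [0, 1].  When
    ``magnification`` is given, only files whose name contains that token
    are kept; an empty selection is an error.

    Returns ``(images, labels, class_names)`` with images of shape
    (N, image_size, image_size).
    """
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"image folder not found: {root}")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories in {root}")
    images, labels, class_names = [], [], []
    for idx, d in enumerate(class_dirs):
        class_names.append(d.name)
        files = sorted(d.glob("*.png"))
        if magnification is not None:
            files = [f for f in files if magnification in f.name]
        for f in files:
            try:
                with Image.open(f) as im:
                    im = im.convert("L").resize(
                        (image_size, image_size), Image.BILINEAR
                    )
            except Exception as exc:
                raise ValueError(f"unreadable image file: {f}") from exc
            images.append(np.asarray(im, dtype=float) / 255.0)
            labels.append(idx)
    if not images:
        detail = f" at magnification {magnification!r}" if magnification else ""
        raise ValueError(f"no PNG files found under {root}{detail}")
    return np.stack(images), np.asarray(labels), class_names


def write_image_folder(
    images,
    labels,
    path,
    class_names=None,
    magnification: str | None = None,
) -> None:
    """Write grayscale images ([0, 1] floats) as a class-subdirectory PNG tree."""
    images = np.asarray(images)
    labels = np.asarray(labels)
    root = Path(path)
    if class_names is None:
        class_names = [f"class_{c}" for c in range(int(labels.max()) + 1)]
    tag = f"-{magnification}-" if magnification else "-"
    for i, (img, lab) in enumerate(zip(images, labels)):
        d = root / class_names[int(lab)]
        d.mkdir(parents=True, exist_ok=True)
        arr = np.clip(np.asarray(img) * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(d / f"sample{tag}{i:05d}.png")


def save_feature_table(X, y, path) -> None:
    """Write features + labels as a TSV (columns f0..fD-1, label)."""
    X = np.asarray(X)
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
    df["label"] = np.asarray(y)
    df.to_csv(path, sep="\t", index=False)


def load_feature_table(path):
    """Read a TSV written by :func:`save_feature_table`; returns (X, y)."""
    df = pd.read_csv(path, sep="\t")
    y = df.pop("label").to_numpy()
    return df.to_numpy(dtype=float), y


def augment_batch(
    images,
    seed: int = 0,
    *,
    rotation_range: float = 90.0,
    flip_prob: float = 0.5,
    discrete_rotation: bool = False,
    enabled: bool = True,
):
    """Randomly rotate and horizontally flip a batch of images.

    Each image is independently rotated by an angle drawn uniformly from
    ``[-rotation_range, +rotation_range]`` degrees (reflection padding,
    shape preserved) and mirrored left-right with probability
    ``flip_prob``.  ``discrete_rotation=True`` instead draws from
    {0°, 90°, 180°, 270°}.  Deterministic given the seed;
    ``enabled=False`` returns the batch unchanged.
    """
    images = np.asarray(images)
    if images.ndim < 3:
        raise ValueError("augment_batch expects image data of shape (N, H, W, ...)")
    if not enabled:
        return images.copy()
    rng = np.random.default_rng(seed)
    out = np.empty_like(images)
    for i, img in enumerate(images):
        if discrete_rotation:
            angle = float(rng.choice([0.0, 90.0, 180.0, 270.0]))
        else:
            angle = float(rng.uniform(-rotation_range, rotation_range))
        rotated = ndimage.rotate(
            img, angle, reshape=False, mode="reflect", order=1
        )
        if rng.uniform() < flip_prob:
            rotated = rotated[:, ::-1]
        out[i] = rotated
    return out
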