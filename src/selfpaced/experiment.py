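"""Experiment orchestration: config files, repeated runs, reports.

One experiment = (dataset source, backend, curriculum, selection mode) run
once per master seed.  Every run writes a per-seed JSON with the full
round history and test metrics, a TSV of the final pseudolabel
assignments, and a summary aggregating the seeds as mean ± sd.  Reports
embed the resolved configuration, carry no timestamps, and are written
with sorted keys, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .backends import get_backend
from .datasets import read_image_folder
from .evaluation import confusion_matrix, precision_recall_f1, summarize_repeats
from .self_training import CurriculumSchedule, run_self_training
from .synthetic import (
    SyntheticConfig,
    generate_imbalanced_blobs,
    generate_toy_texture_images,
    split_dataset,
    withhold_labels,
)

__all__ = ["ExperimentConfig", "run_experiment"]


@dataclass
class ExperimentConfig:
    """Fully serializable experiment description.

    Exactly one of ``synthetic`` / ``image_folder`` must be set.
    ``synthetic`` holds SyntheticConfig fields plus ``"kind"``
    ("blobs" or "textures"); the per-run seed is injected from ``seeds``.
    """

    synthetic: dict | None = None
    image_folder: str | None = None
    magnification: str | None = None
    image_size: int = 32
    backend: str = "softmax"
    backend_params: dict = field(default_factory=dict)
    selection_mode: str = "class_balanced"
    curriculum: dict = field(
        default_factory=lambda: {
            "mode": "incremental",
            "initial_fraction": 0.10,
            "increment": 0.05,
            "max_rounds": 5,
            "improvement_tol": 0.0,
        }
    )
    labeled_fraction: float = 1.0
    transductive: bool = True
    seeds: list = field(default_factory=lambda: [0, 1, 2])
    output_dir: str = "selfpaced_out"

    def __post_init__(self):
        if (self.synthetic is None) == (self.image_folder is None):
            raise ValueError("set exactly one of 'synthetic' or 'image_folder'")
        if not self.seeds:
            raise ValueError("need at least one seed")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _load_dataset(cfg: ExperimentConfig, seed: int):
    if cfg.synthetic is not None:
        spec = dict(cfg.synthetic)
        kind = spec.pop("kind", "blobs")
        spec["seed"] = seed
        syn = SyntheticConfig(**spec)
        if kind == "blobs":
            X, y = generate_imbalanced_blobs(syn)
        elif kind == "textures":
            imgs, y = generate_toy_texture_images(syn)
            X = imgs.reshape(imgs.shape[0], -1)
        else:
            raise ValueError(f"unknown synthetic kind {kind!r}")
        return X, y
    imgs, y, _ = read_image_folder(
        cfg.image_folder, cfg.magnification, cfg.image_size
    )
    return imgs.reshape(imgs.shape[0], -1), y


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the experiment for every seed and write the report files.

    Per seed: stratified protocol split, optional label withholding, the
    self-training loop, and a test-set evaluation of both the supervised
    baseline (round 0) and the final self-trained model.  Returns the
    summary dict that is also written to ``summary.json``.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = cfg.to_dict()
    per_seed_metrics = []
    for seed in cfg.seeds:
        X, y = _load_dataset(cfg, seed)
        split = split_dataset(X, y, seed=seed, transductive=cfg.transductive)
        X_train, y_train = split.X_train, split.y_train
        X_pool = split.X_unlabeled
        if cfg.labeled_fraction < 1.0:
            X_train, y_train, X_extra, _ = withhold_labels(
                split.X_train, split.y_train, cfg.labeled_fraction, seed=seed
            )
            X_pool = np.concatenate([X_pool, X_extra])
        backend = get_backend(cfg.backend, **cfg.backend_params)
        sched = CurriculumSchedule(**cfg.curriculum)
        state = run_self_training(
            X_train,
            y_train,
            X_pool,
            split.X_val,
            split.y_val,
            backend=backend,
            sched=sched,
            selection_mode=cfg.selection_mode,
            seed=seed,
        )
        C = state.classes.shape[0]
        y_pred = state.estimator.predict(split.X_test)
        report = precision_recall_f1(
            confusion_matrix(split.y_test, y_pred, C)
        )
        baseline = get_backend(cfg.backend, **cfg.backend_params)
        if "random_state" in baseline.get_params():
            baseline.set_params(random_state=seed)
        baseline.fit(X_train, y_train)
        baseline_acc = float(
            np.mean(baseline.predict(split.X_test) == split.y_test)
        )
        record = {
            "seed": seed,
            "rounds": [r.to_dict() for r in state.history],
            "stopped_reason": state.stopped_reason,
            "baseline_test_accuracy": baseline_acc,
            "test": report.to_dict(),
        }
        _json_dump({"config": resolved, **record}, out / f"run_seed{seed}.json")
        if state.final_assignment is not None:
            state.final_assignment.to_frame(
                round_index=state.history[-1].round
            ).to_csv(out / f"assignments_seed{seed}.tsv", sep="\t", index=False)
        per_seed_metrics.append(
            {
                "accuracy": report.accuracy,
                "baseline_accuracy": baseline_acc,
                "macro_precision": report.macro["precision"],
                "macro_recall": report.macro["recall"],
                "macro_f1": report.macro["f1"],
            }
        )
    summary = {
        "config": resolved,
        "seeds": list(cfg.seeds),
        "metrics": summarize_repeats(per_seed_metrics),
    }
    _json_dump(summary, out / "summary.json")
    return summary
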