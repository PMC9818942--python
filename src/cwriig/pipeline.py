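"""End-to-end orchestration: images -> stacks -> split -> train -> metrics.

``run_pipeline`` executes the full classification experiment on a synthetic
two-class dataset (or on a directory of labelled images): multiresolution
decomposition, delta-mapping, correlated weighting, six-channel stacking,
a grouped train/test split with translational augmentation of the training
side, CNN training, and confusion-matrix evaluation with either the CNN
itself or a classical classifier on its pooled features.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .classify import Metrics, augment_translate, evaluate_predictions, fit_classical, grouped_split
from .cnn import (
    NetworkSpec,
    TrainingConfig,
    build_network,
    extract_features,
    predict_labels,
    stacks_to_arrays,
    train,
)
from .images import load_gray
from .keys import SubbandKey
from .parametric import SubbandStack, build_stack
from .synthetic import BENIGN_DEFAULT, MALIGNANT_DEFAULT, LabeledImage, make_dataset

__all__ = ["PipelineConfig", "run_pipeline", "stacks_from_images"]

log = logging.getLogger("cwriig")

_TRANSFORMS = ("contourlet", "curvelet")
_MODELS = ("riig", "nakagami", "nig")
_WEIGHTINGS = ("correlated", "multiplicative")
_CLASSIFIERS = ("cnn", "svm", "knn", "random_forest")


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips through YAML."""

    transform: str = "contourlet"
    model: str = "riig"
    weighting: str = "correlated"
    subband_keys: list[str] | None = None  # default: the transform's six names
    window: int = 13
    stride: int = 1
    classifier: str = "cnn"
    gap_mode: str = "flatten"
    training: TrainingConfig = field(default_factory=TrainingConfig)
    n_per_class: int = 100
    image_size: int = 256
    n_augment: int = 1  # augmented variants per image
    max_shift: int = 11
    image_dir: str | None = None  # labelled PNG/BMP inputs instead of synthesis
    out_dir: str = "runs/out"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value, allowed in (
            ("transform", self.transform, _TRANSFORMS),
            ("model", self.model, _MODELS),
            ("weighting", self.weighting, _WEIGHTINGS),
            ("classifier", self.classifier, _CLASSIFIERS),
        ):
            if value not in allowed:
                raise ValueError(f"invalid {name} {value!r}; expected one of {allowed}")
        if isinstance(self.training, dict):
            self.training = TrainingConfig(**self.training)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def resolved_keys(self) -> list[SubbandKey] | None:
        if self.subband_keys is None:
            return None
        return [SubbandKey.from_name(n) for n in self.subband_keys]


def _load_image_dir(directory: str | Path) -> list[LabeledImage]:
    """Read ``<label>_<id>.png|bmp`` files from a directory."""
    directory = Path(directory)
    out = []
    for p in sorted(directory.glob("*")):
        if p.suffix.lower() not in (".png", ".bmp"):
            continue
        label = p.stem.split("_")[0]
        if label not in ("benign", "malignant"):
            raise ValueError(f"cannot infer class from file name {p.name!r}")
        out.append(LabeledImage(load_gray(p), label, p.stem, -1))
    if not out:
        raise ValueError(f"no PNG/BMP images found in {directory}")
    return out


def stacks_from_images(
    images: list[LabeledImage],
    config: PipelineConfig,
    n_augment: int | None = None,
) -> list[SubbandStack]:
    """Build stacks for each image plus its translational augmentations.

    Augmented variants inherit the source image's ``source_id`` so a
    grouped split keeps them on the same side as their source.
    """
    n_augment = config.n_augment if n_augment is None else n_augment
    stacks = []
    for rec in images:
        variants = [rec.image]
        if n_augment:
            sid_hash = int(hashlib.sha256(rec.source_id.encode()).hexdigest()[:8], 16)
            variants += augment_translate(
                rec.image, n_augment, max_shift=config.max_shift,
                seed=(sid_hash + config.seed) % 2**31,
            )
        for img in variants:
            stacks.append(
                build_stack(
                    img,
                    transform=config.transform,
                    model=config.model,
                    keys=config.resolved_keys(),
                    window=config.window,
                    stride=config.stride,
                    weighting=config.weighting,
                    label=rec.label,
                    source_id=rec.source_id,
                )
            )
    return stacks


def run_pipeline(config: PipelineConfig) -> Metrics:
    """Execute the configured experiment end to end; writes artifacts.

    Outputs under ``config.out_dir``: the resolved config, metrics and
    confusion-matrix CSVs, the per-iteration loss trace, the trained
    checkpoint and a run log.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out, t_start)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path, t_start: float) -> Metrics:
    config.to_yaml(out / "config.yaml")
    log.info("run start: hash=%s seed=%d", config.config_hash(), config.seed)

    if config.image_dir:
        images = _load_image_dir(config.image_dir)
    else:
        images = make_dataset(config.n_per_class, BENIGN_DEFAULT, MALIGNANT_DEFAULT,
                              seed=config.seed)
    log.info("stage images: %d inputs", len(images))

    try:
        stacks = stacks_from_images(images, config)
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"stage stacks failed: {exc}") from exc
    log.info("stage stacks: %d stacks", len(stacks))

    train_set, test_set = grouped_split(stacks, config.training.test_fraction, config.seed)
    log.info("stage split: %d train / %d test", len(train_set), len(test_set))

    X_train, y_train = stacks_to_arrays(train_set)
    # per-channel standardization, fitted on the training side only
    mu = X_train.mean(axis=(0, 1, 2), keepdims=True)
    sd = X_train.std(axis=(0, 1, 2), keepdims=True) + 1e-6
    X_train = (X_train - mu) / sd

    net = build_network(NetworkSpec(gap_mode=config.gap_mode), seed=config.seed)
    trace = train(net, (X_train, y_train), config.training)
    pd.DataFrame({"iteration": np.arange(1, len(trace) + 1), "loss": trace}).to_csv(
        out / "loss_trace.csv", index=False
    )
    cio.save_checkpoint(
        out / "checkpoint", net,
        {"config_hash": config.config_hash(),
         "channel_mean": mu.ravel().tolist(), "channel_std": sd.ravel().tolist()},
    )
    log.info("stage train: final loss %.4f", trace[-1])

    X_test, y_test = stacks_to_arrays(test_set)
    X_test = (X_test - mu) / sd
    if config.classifier == "cnn":
        y_pred = predict_labels(net, X_test)
    else:
        f_train = extract_features(net, X_train)
        f_test = extract_features(net, X_test)
        clf = fit_classical(f_train, y_train, config.classifier, seed=config.seed)
        y_pred = clf.predict(f_test)
    metrics = evaluate_predictions(y_test, y_pred)

    pd.DataFrame([metrics.as_dict()]).to_csv(out / "metrics.csv", index=False)
    pd.DataFrame(
        [[metrics.tn, metrics.fp], [metrics.fn, metrics.tp]],
        index=["true_benign", "true_malignant"],
        columns=["pred_benign", "pred_malignant"],
    ).to_csv(out / "confusion.csv")
    log.info("stage evaluate: accuracy %.4f (%.1f s total)",
             metrics.accuracy, time.time() - t_start)
    return metrics
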