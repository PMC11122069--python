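"""End-to-end orchestration: split, train, evaluate, and run on streams."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .activity_detection import DetectionConfig, detect_segments, extract
from .dtw_classifier import DtwConfig, TemplateSet, build_template_set, classify
from .errors import ConfigError, PipelineError
from .imu_io import GESTURE_CLASSES, ImuSequence, LabeledSegment, Segment
from .preprocessing import PreprocessConfig
from .synthetic import GeneratorConfig

logger = logging.getLogger("headgest")


@dataclass(frozen=True)
class RunConfig:
    """All knobs of the pipeline in one nested object.

    The default train fraction of 0.82 mirrors the conventional roughly
    5:1 train/test partition of a class-balanced gesture corpus.
    """

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detect: DetectionConfig = field(default_factory=DetectionConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    dtw: DtwConfig = field(default_factory=DtwConfig)
    train_fraction: float = 0.82
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ConfigError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(eq=False)
class EvaluationReport:
    """Per-class and overall accuracy plus the full confusion matrix."""

    labels: list[str]
    confusion: np.ndarray  # rows = truth, columns = predicted
    n_train: dict[str, int]
    n_test: dict[str, int]
    accuracy_pct: float
    per_class_pct: dict[str, float]
    config: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": round(self.accuracy_pct, 2),
            "confusion": self.confusion.tolist(),
            "labels": self.labels,
            "per_class": {k: round(v, 2) for k, v in self.per_class_pct.items()},
            "n_train": self.n_train,
            "n_test": self.n_test,
            "config": self.config,
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def split_dataset(
    data: Sequence[LabeledSegment], train_fraction: float, seed: int
) -> tuple[list[LabeledSegment], list[LabeledSegment]]:
    """Stratified random train/test split, reproducible per seed.

    Per class c with n_c members, round(train_fraction * n_c) go to train,
    clamped to [1, n_c - 1] so neither side of any class is ever empty.
    """
    if not (0 < train_fraction < 1):
        raise ConfigError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    if len(data) == 0:
        raise ValueError("cannot split an empty dataset")
    by_label: dict[str, list[int]] = {}
    for i, seg in enumerate(data):
        by_label.setdefault(seg.label, []).append(i)
    for label, idx in by_label.items():
        if len(idx) < 2:
            raise ConfigError(
                f"class {label!r} has {len(idx)} member(s); need >= 2 to stratify"
            )
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(by_label):
        idx = np.array(by_label[label])
        rng.shuffle(idx)
        n_c = len(idx)
        n_train = int(np.clip(round(train_fraction * n_c), 1, n_c - 1))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return [data[i] for i in train_idx], [data[i] for i in test_idx]


def evaluate(
    train: Sequence[LabeledSegment],
    test: Sequence[LabeledSegment],
    cfg: RunConfig,
) -> EvaluationReport:
    """Build templates from the training set only and score the test set."""
    train_labels = {s.label for s in train}
    missing = set(GESTURE_CLASSES) - train_labels
    if missing:
        raise ConfigError(f"training set missing class(es): {sorted(missing)}")

    templates = build_template_set(train, cfg.preprocess)
    logger.info("built %d templates from %d training segments", len(templates), len(train))

    y_true, y_pred = [], []
    for seg in test:
        label, distances = classify(seg.data, templates, cfg.preprocess, cfg.dtw)
        y_true.append(seg.label)
        y_pred.append(label)
        logger.debug("truth=%s pred=%s distances=%s", seg.label, label, distances)

    labels = list(GESTURE_CLASSES)
    conf = _sk_confusion(y_true, y_pred, labels=labels)
    total = conf.sum()
    accuracy = 100.0 * np.trace(conf) / total if total else 0.0
    per_class = {
        lab: (100.0 * conf[i, i] / conf[i].sum() if conf[i].sum() else 0.0)
        for i, lab in enumerate(labels)
    }
    n_train = {lab: sum(1 for s in train if s.label == lab) for lab in labels}
    n_test = {lab: sum(1 for s in test if s.label == lab) for lab in labels}
    logger.info("accuracy %.2f%% on %d test segments", accuracy, total)
    return EvaluationReport(
        labels=labels,
        confusion=conf,
        n_train=n_train,
        n_test=n_test,
        accuracy_pct=accuracy,
        per_class_pct=per_class,
        config=cfg.to_dict(),
        seed=cfg.seed,
    )


def run_pipeline(
    stream: ImuSequence, templates: TemplateSet, cfg: RunConfig
) -> list[tuple[Segment, str, dict[str, float]]]:
    """detect -> extract -> preprocess+classify, one output per detected segment."""
    try:
        segments = detect_segments(stream, cfg.detect, cfg.preprocess)
    except Exception as exc:  # noqa: BLE001 - annotate with stage name
        raise PipelineError(f"detection stage failed: {exc}") from exc
    logger.info("detected %d segment(s)", len(segments))
    try:
        pieces = extract(stream, segments)
    except Exception as exc:
        raise PipelineError(f"extraction stage failed: {exc}") from exc
    results = []
    for seg, piece in zip(segments, pieces):
        try:
            label, distances = classify(piece, templates, cfg.preprocess, cfg.dtw)
        except Exception as exc:
            raise PipelineError(
                f"classification stage failed on segment [{seg.start}, {seg.end}): {exc}"
            ) from exc
        logger.debug("segment [%d, %d) -> %s %s", seg.start, seg.end, label, distances)
        results.append((seg, label, distances))
    return results
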