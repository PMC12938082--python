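"""Repeated-split evaluation protocol and classification metrics.

The dataset of labelled respiratory-cycle items is split 80/10/10 into
train/validation/test at the cycle level, stratified per class with
largest-remainder rounding; the experiment is repeated (default ten times)
with different random partitions, and performance is reported as mean ±
standard deviation of test accuracy over the repeats. Class-wise precision,
recall and F1 plus the confusion matrix come from a representative repeat —
the one whose accuracy is closest to the mean (ties broken toward the lower
repeat index).

Metrics follow the usual one-vs-rest conventions: accuracy = trace / total,
precision_k = TP_k / (TP_k + FP_k), recall_k = TP_k / (TP_k + FN_k),
F1_k = 2 P R / (P + R); a zero denominator yields 0 with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import TrainConfig, get_backbone, predict, train_model
from .synth import SOUND_CLASSES
from .tfr import compute_representation, to_model_input

__all__ = [
    "SplitConfig",
    "ConfusionMatrix",
    "Metrics",
    "EvalReport",
    "PipelineConfig",
    "split_dataset",
    "confusion_matrix",
    "compute_metrics",
    "f1_score",
    "repeat_experiment",
]


@dataclass(frozen=True)
class SplitConfig:
    train_frac: float = 0.8
    val_frac: float = 0.1
    test_frac: float = 0.1
    n_repeats: int = 10
    unit: str = "cycle"  # 'cycle' (protocol default) or 'subject'
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if any(not (0.0 < f < 1.0) for f in fracs):
            raise ValueError("split fractions must lie in (0, 1)")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {sum(fracs)}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.unit not in ("cycle", "subject"):
            raise ValueError("unit must be 'cycle' or 'subject'")


def _largest_remainder(n: int, fracs: tuple[float, ...]) -> list[int]:
    """Integer allocation of n items to proportions (sums exactly to n)."""
    raw = np.asarray(fracs) * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base))
    for k in range(short):
        base[order[k]] += 1
    return base.tolist()


def split_dataset(
    labels: np.ndarray,
    config: SplitConfig,
    repeat_index: int = 0,
    groups: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/val/test index sets, deterministic per (seed, repeat).

    ``labels`` may be any hashable class labels. With ``unit='subject'``,
    ``groups`` assigns each item to a subject and whole subjects are
    allocated to one partition (leakage-safe alternative).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, repeat_index)))
    fracs = (config.train_frac, config.val_frac, config.test_frac)
    train_idx, val_idx, test_idx = [], [], []
    if config.unit == "subject":
        if groups is None:
            raise ValueError("subject-level splitting requires groups")
        groups = np.asarray(groups)
        units = [np.flatnonzero(groups == g) for g in np.unique(groups)]
    else:
        units = [np.array([i]) for i in range(len(labels))]
    unit_labels = np.array([labels[u[0]] for u in units])

    for cls in np.unique(unit_labels):
        members = np.flatnonzero(unit_labels == cls)
        n = len(members)
        n_tr, n_va, n_te = _largest_remainder(n, fracs)
        if min(n_tr, n_va, n_te) < 1:
            raise ValueError(
                f"class {cls!r} has {n} units; fractions {fracs} leave an empty partition"
            )
        perm = rng.permutation(members)
        for dest, count in ((train_idx, n_tr), (val_idx, n_va), (test_idx, n_te)):
            take, perm = perm[:count], perm[count:]
            for u in take:
                dest.extend(units[u].tolist())
    return (np.sort(train_idx).astype(int), np.sort(val_idx).astype(int), np.sort(test_idx).astype(int))


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted."""

    counts: np.ndarray
    class_labels: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match class_labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_labels, columns=self.class_labels)


def confusion_matrix(true_labels, predicted_labels, class_order) -> ConfusionMatrix:
    """counts[i, j] = number of items with true class i predicted as class j."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    k = len(class_order)
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside class_order: true={t!r} pred={p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, list(class_order))


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reporting 0", stacklevel=3)
        return 0.0
    return num / den


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    return _safe_div(2.0 * precision * recall, precision + recall, "F1")


@dataclass
class Metrics:
    accuracy: float
    precision: dict
    recall: dict
    f1: dict


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """Accuracy plus one-vs-rest precision/recall/F1 per class."""
    counts = cm.counts
    if counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    acc = float(np.trace(counts)) / cm.total
    precision, recall, f1 = {}, {}, {}
    for i, cls in enumerate(cm.class_labels):
        tp = float(counts[i, i])
        fp = float(counts[:, i].sum() - tp)
        fn = float(counts[i, :].sum() - tp)
        p = _safe_div(tp, tp + fp, f"precision[{cls}]")
        r = _safe_div(tp, tp + fn, f"recall[{cls}]")
        precision[cls], recall[cls] = p, r
        f1[cls] = f1_score(p, r)
    return Metrics(accuracy=acc, precision=precision, recall=recall, f1=f1)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline choice: representation + classifier + backbone."""

    representation: str = "gammatone"
    model: str = "cnn"
    backbone: str = "tiny"
    train: TrainConfig = field(default_factory=TrainConfig)


@dataclass
class EvalReport:
    per_repeat_accuracy: list[float]
    mean_accuracy: float  # percent
    std_accuracy: float  # percent
    representative_repeat: int
    classwise: Metrics | None
    confusion: ConfusionMatrix | None
    failed_repeats: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "per_repeat_accuracy": self.per_repeat_accuracy,
            "mean_accuracy_percent": round(self.mean_accuracy, 1),
            "std_accuracy_percent": round(self.std_accuracy, 1),
            "representative_repeat": self.representative_repeat,
            "failed_repeats": self.failed_repeats,
        }
        if self.classwise is not None:
            d["classwise"] = {
                "precision": self.classwise.precision,
                "recall": self.classwise.recall,
                "f1": self.classwise.f1,
            }
        if self.confusion is not None:
            d["confusion"] = self.confusion.counts.tolist()
            d["class_labels"] = list(self.confusion.class_labels)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def summarize_repeats(accuracies: list[float]) -> tuple[float, float, int]:
    """Mean %, sample-std % (n-1), and representative index (closest to mean)."""
    arr = np.asarray(accuracies, dtype=float)
    mean = float(arr.mean())
    std = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    rep = int(np.argmin(np.abs(arr - mean)))  # argmin takes the lowest index on ties
    return 100.0 * mean, 100.0 * std, rep


def featurize_corpus(
    corpus, representation: str = "gammatone", backbone=None
) -> tuple[np.ndarray, np.ndarray]:
    """Backbone feature maps + integer labels for a list of recordings.

    The representation and frozen-backbone features do not depend on the data
    split, so they are computed once and shared by all repeats.
    """
    backbone = backbone or get_backbone("tiny")
    fmaps, labels = [], []
    for rec in corpus:
        img = to_model_input(compute_representation(rec.audio, representation))
        fmaps.append(backbone.features(img))
        labels.append(SOUND_CLASSES.index(rec.label))
    return np.stack(fmaps), np.asarray(labels, dtype=int)


def repeat_experiment(
    corpus,
    pipeline: PipelineConfig | None = None,
    split: SplitConfig | None = None,
    features: tuple[np.ndarray, np.ndarray] | None = None,
) -> EvalReport:
    """Run the full split -> featurize -> train -> test protocol.

    ``corpus`` is a list of labelled single-cycle recordings (see
    :func:`lungsounds.synth.generate_cycle_corpus`); ``features`` may carry
    precomputed ``featurize_corpus`` output to skip featurization. Each
    repeat draws its own partition and training seed from the split seed. A
    repeat that raises is recorded in ``failed_repeats`` and excluded, with
    a warning.
    """
    pipeline = pipeline or PipelineConfig()
    split = split or SplitConfig()
    backbone = get_backbone(pipeline.backbone)
    if features is None:
        features = featurize_corpus(corpus, pipeline.representation, backbone)
    fmaps, y = features

    accuracies: list[float] = []
    per_repeat_preds: list[tuple[np.ndarray, np.ndarray]] = []
    failed: list[int] = []
    for rep in range(split.n_repeats):
        try:
            tr, va, te = split_dataset(y, split, repeat_index=rep)
            cfg = TrainConfig(
                **{
                    **pipeline.train.__dict__,
                    "seed": int(np.random.SeedSequence((split.seed, rep, 7)).generate_state(1)[0] % (2**31)),
                }
            )
            model = train_model((fmaps[tr], y[tr]), (fmaps[va], y[va]), pipeline.model, cfg, backbone)
            pred, _ = predict(model, fmaps[te])
            accuracies.append(float((pred == y[te]).mean()))
            per_repeat_preds.append((y[te], pred))
        except Exception as err:  # noqa: BLE001 - protocol requires marking, not dying
            warnings.warn(f"repeat {rep} failed: {err}", stacklevel=2)
            failed.append(rep)
    if not accuracies:
        raise RuntimeError("all repeats failed")

    mean_pct, std_pct, rep_idx = summarize_repeats(accuracies)
    y_true, y_pred = per_repeat_preds[rep_idx]
    names = [SOUND_CLASSES[i] for i in range(int(y.max()) + 1)]
    cm = confusion_matrix(
        [names[i] for i in y_true], [names[i] for i in y_pred], class_order=names
    )
    return EvalReport(
        per_repeat_accuracy=accuracies,
        mean_accuracy=mean_pct,
        std_accuracy=std_pct,
        representative_repeat=rep_idx,
        classwise=compute_metrics(cm),
        confusion=cm,
        failed_repeats=failed,
    )
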