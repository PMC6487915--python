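"""Training protocol: balanced batches, Adam, validation-based selection.

Sleep data is heavily imbalanced (N2 dominates, N1 is rare), so every batch
is resampled to contain an equal number of examples per stage (the
center-epoch label defines the class), sampling with replacement within
class. The network is trained with Adam and the checkpoint with the best
validation selection metric (classification-subtask accuracy by default) is
retained. Two runs with the same seed produce identical histories.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np

from ._nn import AdamState
from .model import MultiTaskCNN, MultiTaskPosterior

__all__ = [
    "TrainConfig",
    "DatasetSplit",
    "TrainHistory",
    "ContextDataset",
    "make_context_samples",
    "fit_standardizer",
    "apply_standardizer",
    "make_balanced_batches",
    "train_model",
    "predict_recording",
]


@dataclass
class TrainConfig:
    """Optimization settings (Adam with conventional moment defaults)."""

    learning_rate: float = 1e-4
    n_train_epochs: int = 200
    batch_size: int = 200
    seed: int = 0
    selection_metric: str = "classification"  # or "aggregated"

    def __post_init__(self) -> None:
        if self.n_train_epochs < 1:
            raise ValueError("n_train_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.selection_metric not in ("classification", "aggregated"):
            raise ValueError(f"unknown selection metric {self.selection_metric!r}")


@dataclass
class ContextDataset:
    """Training examples: images with their output-context label windows.

    ``X`` is (n, P, M, T); ``context`` is (n, 2*tau+1) integer stage codes
    ordered (n-tau, ..., n, ..., n+tau); ``groups`` carries recording
    provenance.
    """

    X: np.ndarray
    context: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.context = np.asarray(self.context, dtype=np.int64)
        self.groups = np.asarray(self.groups)
        if not (len(self.X) == len(self.context) == len(self.groups)):
            raise ValueError("X, context and groups must have equal lengths")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def center_labels(self) -> np.ndarray:
        return self.context[:, self.context.shape[1] // 2]


@dataclass
class DatasetSplit:
    """Subject/recording-disjoint train/validation/test collections."""

    train: ContextDataset
    validation: ContextDataset
    test: Optional[ContextDataset] = None

    def __post_init__(self) -> None:
        tr = set(np.unique(self.train.groups).tolist())
        va = set(np.unique(self.validation.groups).tolist())
        overlap = tr & va
        if overlap:
            raise ValueError(f"train/validation share recordings: {sorted(overlap)}")

    @property
    def N(self) -> int:
        return len(self.train)


@dataclass
class TrainHistory:
    """Per-training-epoch loss and validation accuracies."""

    loss: np.ndarray
    val_subtask_accuracy: np.ndarray  # (n_epochs, 2*tau+1)
    selected_epoch: int

    @property
    def val_classification_accuracy(self) -> np.ndarray:
        return self.val_subtask_accuracy[:, self.val_subtask_accuracy.shape[1] // 2]


def make_context_samples(
    images: np.ndarray,
    codes: np.ndarray,
    tau: int,
    group: str = "rec0",
    drop_boundaries: bool = True,
) -> ContextDataset:
    """Pair each epoch image with the stage codes of its output context.

    Epochs whose context window would leave the recording are dropped when
    ``drop_boundaries`` (the training-set convention); with it off, boundary
    context positions are filled with the nearest valid label.
    """
    images = np.asarray(images, dtype=float)
    codes = np.asarray(codes, dtype=np.int64)
    n = len(codes)
    if len(images) != n:
        raise ValueError("images and codes must align")
    K = 2 * tau + 1
    rows: List[int] = []
    ctx = []
    for i in range(n):
        if drop_boundaries and (i - tau < 0 or i + tau >= n):
            continue
        idx = np.clip(np.arange(i - tau, i + tau + 1), 0, n - 1)
        rows.append(i)
        ctx.append(codes[idx])
    if not rows:
        raise ValueError("recording too short for the requested context radius")
    return ContextDataset(
        X=images[rows],
        context=np.stack(ctx),
        groups=np.array([group] * len(rows)),
    )


def fit_standardizer(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per channel-and-band z-scoring statistics from the training set.

    Returns (mu, sd), each (P, M, 1), computed over examples and frames.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=(0, 3))[..., None]
    sd = X.std(axis=(0, 3))[..., None] + 1e-8
    return mu, sd


def apply_standardizer(X: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - mu) / sd


def make_balanced_batches(
    labels: np.ndarray,
    batch_size: int,
    Y: int,
    seed: int,
    vocab_labels: Optional[Sequence[str]] = None,
) -> Iterator[np.ndarray]:
    """Endless stream of class-balanced index batches.

    Each batch holds ``batch_size // Y`` examples of every class (the
    center-epoch label defines the class), drawn with replacement within
    class; the stream is seeded and deterministic.
    """
    labels = np.asarray(labels)
    if batch_size % Y != 0:
        warnings.warn(
            f"batch_size={batch_size} is not divisible by Y={Y}; "
            f"using {batch_size // Y} examples per class",
            stacklevel=2,
        )
    per_class = batch_size // Y
    if per_class < 1:
        raise ValueError("batch_size must allow at least one example per class")
    pools = []
    for c in range(Y):
        pool = np.nonzero(labels == c)[0]
        if pool.size == 0:
            name = vocab_labels[c] if vocab_labels else str(c)
            raise ValueError(f"class {name!r} has no training examples")
        pools.append(pool)
    rng = np.random.default_rng(seed)
    while True:
        parts = [pool[rng.integers(0, pool.size, size=per_class)] for pool in pools]
        batch = np.concatenate(parts)
        rng.shuffle(batch)
        yield batch


def _subtask_accuracies(model: MultiTaskCNN, ds: ContextDataset) -> np.ndarray:
    """Per-subtask accuracy of the model on a dataset (inference mode)."""
    probs = _predict_in_chunks(model, ds.X)
    pred = probs.argmax(axis=2)  # (n, K)
    return (pred == ds.context).mean(axis=0)


def _predict_in_chunks(
    model: MultiTaskCNN, X: np.ndarray, chunk: int = 512
) -> np.ndarray:
    outs = [model.predict_proba(X[i : i + chunk]) for i in range(0, len(X), chunk)]
    return np.concatenate(outs, axis=0)


def train_model(
    model: MultiTaskCNN,
    split: DatasetSplit,
    tc: TrainConfig = TrainConfig(),
) -> Tuple[MultiTaskCNN, TrainHistory]:
    """Train with balanced batches; return the best-validation checkpoint.

    One training epoch is ceil(N / batch_size) balanced batches, reshuffled
    every epoch. The checkpoint maximizing the validation selection metric
    (classification-subtask accuracy by default) is returned together with
    the full history. NaN loss aborts with a diagnostic.
    """
    cfg = model.cfg
    Y = cfg.Y
    if len(split.train) == 0 or len(split.validation) == 0:
        raise ValueError("train and validation sets must be non-empty")
    onehot = np.eye(Y)
    steps_per_epoch = max(1, math.ceil(split.N / tc.batch_size))
    batches = make_balanced_batches(
        split.train.center_labels, tc.batch_size, Y, seed=tc.seed
    )
    drop_rng = np.random.default_rng(tc.seed + 1)
    adam = AdamState(model.params, learning_rate=tc.learning_rate)

    losses = np.empty(tc.n_train_epochs)
    val_acc = np.empty((tc.n_train_epochs, cfg.n_subtasks))
    best_metric, best_epoch, best_params = -np.inf, -1, None
    for epoch in range(tc.n_train_epochs):
        epoch_loss = 0.0
        for _ in range(steps_per_epoch):
            idx = next(batches)
            Xb = split.train.X[idx]
            tb = onehot[split.train.context[idx]]  # (B, K, Y)
            loss, grads = model.loss_and_grads(Xb, tb, rng=drop_rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss ({loss}) at training epoch {epoch}; "
                    "check learning rate / input scaling"
                )
            adam.step(model.params, grads)
            epoch_loss += loss
        losses[epoch] = epoch_loss / steps_per_epoch
        val_acc[epoch] = _subtask_accuracies(model, split.validation)
        if tc.selection_metric == "classification":
            metric = val_acc[epoch, cfg.tau]
        else:
            metric = val_acc[epoch].mean()
        if metric > best_metric:
            best_metric, best_epoch = metric, epoch
            best_params = {k: v.copy() for k, v in model.params.items()}
    best = model.clone()
    best.params = best_params
    history = TrainHistory(
        loss=losses, val_subtask_accuracy=val_acc, selected_epoch=best_epoch
    )
    return best, history


def predict_recording(
    model: MultiTaskCNN, images: np.ndarray
) -> List[MultiTaskPosterior]:
    """One multi-task posterior per epoch of a recording, order preserved."""
    images = np.asarray(images, dtype=float)
    if images.ndim != 4 or len(images) == 0:
        raise ValueError("images must be a non-empty (n, P, M, T) array")
    probs = _predict_in_chunks(model, images)
    return [MultiTaskPosterior(probs=p, tau=model.cfg.tau) for p in probs]
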