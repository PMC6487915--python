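"""Scikit-learn estimators wrapping the staging pipeline.

``SpectrogramTransformer`` turns raw (n, P, samples) epoch signals into
(n, P, M, T) filtered log-power time-frequency images; ``MultiTaskSleepStager``
fits the multi-task CNN on such images and predicts per-epoch stages after
decision-ensemble aggregation. Both compose with sklearn pipelines and model
selection; recording membership is carried by a ``groups`` array (epochs of a
group are assumed consecutive and in temporal order).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .ensemble import aggregate_recording
from .model import ModelConfig, build_model
from .spectral import (
    SpectralConfig,
    pretrain_filterbank,
    stft_logpower,
    triangular_filterbank,
)
from .train import (
    ContextDataset,
    DatasetSplit,
    TrainConfig,
    apply_standardizer,
    fit_standardizer,
    make_context_samples,
    predict_recording,
    train_model,
)

__all__ = ["SpectrogramTransformer", "MultiTaskSleepStager"]


class SpectrogramTransformer(TransformerMixin, BaseEstimator):
    """Raw epochs -> multi-channel filtered log-power time-frequency images.

    Parameters
    ----------
    fs : sampling rate of the input epochs (Hz).
    win_sec, overlap, nfft, log_floor, M : STFT / filter-bank settings
        (defaults give a 20 x 29 image per channel for a 30-s 100 Hz epoch).
    filterbank : "triangular" or "learned"; the learned bank is pretrained
        discriminatively per channel and requires ``y`` at fit time.
    pretrain_steps, pretrain_lr : optimization settings of the learned bank.
    random_state : seed for the learned-bank pretraining.
    """

    def __init__(
        self,
        fs: float = 100.0,
        win_sec: float = 2.0,
        overlap: float = 0.5,
        nfft: int = 256,
        log_floor: float = 1e-10,
        M: int = 20,
        filterbank: str = "triangular",
        pretrain_steps: int = 50,
        pretrain_lr: float = 1e-3,
        random_state: int = 0,
    ) -> None:
        self.fs = fs
        self.win_sec = win_sec
        self.overlap = overlap
        self.nfft = nfft
        self.log_floor = log_floor
        self.M = M
        self.filterbank = filterbank
        self.pretrain_steps = pretrain_steps
        self.pretrain_lr = pretrain_lr
        self.random_state = random_state

    def _cfg(self) -> SpectralConfig:
        return SpectralConfig(
            win_sec=self.win_sec,
            overlap=self.overlap,
            nfft=self.nfft,
            log_floor=self.log_floor,
            M=self.M,
        )

    def _spectrograms(self, X: np.ndarray, channel: int):
        return [stft_logpower(x[channel], self.fs, self._cfg()) for x in X]

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, None, :]
        if X.ndim != 3:
            raise ValueError("X must be (n_epochs, n_channels, n_samples)")
        F = self.nfft // 2 + 1
        if self.filterbank == "triangular":
            self.banks_ = [
                triangular_filterbank(self.M, F, self.fs) for _ in range(X.shape[1])
            ]
        elif self.filterbank == "learned":
            if y is None:
                raise ValueError("filterbank='learned' requires stage labels y")
            self.banks_ = []
            for c in range(X.shape[1]):
                specs = np.stack(
                    [s.values for s in self._spectrograms(X, c)]
                )
                codes = _encode_labels(np.asarray(y))[1]
                self.banks_.append(
                    pretrain_filterbank(
                        specs,
                        codes,
                        M=self.M,
                        n_steps=self.pretrain_steps,
                        learning_rate=self.pretrain_lr,
                        seed=self.random_state + c,
                    )
                )
        else:
            raise ValueError(f"unknown filterbank kind {self.filterbank!r}")
        self.n_channels_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "banks_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, None, :]
        if X.shape[1] != self.n_channels_:
            raise ValueError(
                f"fitted on {self.n_channels_} channels, got {X.shape[1]}"
            )
        cfg = self._cfg()
        out = []
        for x in X:
            slabs = [
                self.banks_[c].weights @ stft_logpower(x[c], self.fs, cfg).values
                for c in range(self.n_channels_)
            ]
            out.append(np.stack(slabs))
        return np.stack(out)


def _encode_labels(y: np.ndarray):
    classes = np.unique(y)
    codes = np.searchsorted(classes, y)
    return classes, codes.astype(np.int64)


def _iter_groups(groups: np.ndarray):
    """Yield (group value, index array) preserving order of first appearance."""
    seen = []
    for g in groups:
        if g not in seen:
            seen.append(g)
    for g in seen:
        yield g, np.nonzero(groups == g)[0]


def _context_input(images: np.ndarray, context: int) -> np.ndarray:
    """Concatenate each epoch with its neighbors along time (edge-replicated)."""
    n = len(images)
    half = context // 2
    out = []
    for i in range(n):
        idx = np.clip(np.arange(i - half, i - half + context), 0, n - 1)
        out.append(np.concatenate([images[j] for j in idx], axis=2))
    return np.stack(out)


class MultiTaskSleepStager(ClassifierMixin, BaseEstimator):
    """Joint classification-and-prediction sleep stager (one-to-many CNN).

    Fits the multi-task 1-max CNN on (n, P, M, T) time-frequency images whose
    temporal order within each ``groups`` value is the epoch order of a
    recording, then predicts stages by aggregating each epoch's decision
    ensemble (its own classification plus its neighbors' predictions).

    Parameters mirror the network and training protocol: Q filters per
    temporal width, output-context radius ``tau``, dropout and L2 ``lambda_reg``
    regularization, Adam with ``learning_rate``, class-balanced batches of
    ``batch_size``, ``n_train_epochs`` passes with best-validation selection,
    and ``vote`` in {"additive", "multiplicative", "none"} for aggregation.

    Attributes (after fit): ``classes_``, ``model_``, ``history_``,
    ``standardizer_``.
    """

    def __init__(
        self,
        Q: int = 100,
        widths: tuple = (3, 5, 7),
        tau: int = 1,
        dropout: float = 0.2,
        lambda_reg: float = 1e-3,
        arch: str = "one_max",
        scheme: str = "one_to_many",
        input_context: int = 3,
        learning_rate: float = 1e-4,
        n_train_epochs: int = 200,
        batch_size: int = 200,
        validation_fraction: float = 0.2,
        selection_metric: str = "classification",
        vote: str = "multiplicative",
        standardize: bool = True,
        random_state: int = 0,
    ) -> None:
        self.Q = Q
        self.widths = widths
        self.tau = tau
        self.dropout = dropout
        self.lambda_reg = lambda_reg
        self.arch = arch
        self.scheme = scheme
        self.input_context = input_context
        self.learning_rate = learning_rate
        self.n_train_epochs = n_train_epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.selection_metric = selection_metric
        self.vote = vote
        self.standardize = standardize
        self.random_state = random_state

    # ----- helpers -----------------------------------------------------
    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 4:
            raise ValueError("X must be (n_epochs, P, M, T) time-frequency images")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    def _split_groups(self, groups: np.ndarray):
        """Recording-disjoint train/validation partition of group values."""
        uniq = [g for g, _ in _iter_groups(groups)]
        rng = np.random.default_rng(self.random_state)
        if len(uniq) >= 2:
            n_val = max(1, int(round(self.validation_fraction * len(uniq))))
            n_val = min(n_val, len(uniq) - 1)
            perm = rng.permutation(len(uniq))
            val = {uniq[i] for i in perm[:n_val]}
            return [g for g in uniq if g not in val], sorted(val)
        return uniq, []

    def _build_datasets(self, X, codes, groups, tau, drop_boundaries=True):
        parts = []
        for g, idx in _iter_groups(groups):
            imgs = X[idx]
            if self.scheme == "many_to_one":
                imgs = _context_input(imgs, self.input_context)
            ds = make_context_samples(
                imgs, codes[idx], tau, group=str(g),
                drop_boundaries=drop_boundaries,
            )
            parts.append(ds)
        return ContextDataset(
            X=np.concatenate([p.X for p in parts]),
            context=np.concatenate([p.context for p in parts]),
            groups=np.concatenate([p.groups for p in parts]),
        )

    # ----- sklearn API -------------------------------------------------
    def fit(self, X, y, groups: Optional[Sequence] = None):
        X = self._check_X(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y must have equal lengths")
        self.classes_, codes = _encode_labels(y)
        if self.classes_.size < 2:
            raise ValueError("need at least two stage classes in y")
        groups = (
            np.zeros(len(X), dtype=int) if groups is None else np.asarray(groups)
        )
        if len(groups) != len(X):
            raise ValueError("groups must align with X")

        train_groups, val_groups = self._split_groups(groups)
        if val_groups:
            tr_mask = np.isin(groups, train_groups)
            va_mask = np.isin(groups, val_groups)
            Xtr, ctr, gtr = X[tr_mask], codes[tr_mask], groups[tr_mask]
            Xva, cva, gva = X[va_mask], codes[va_mask], groups[va_mask]
        else:
            # single recording: contiguous front/back split
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            Xtr, ctr = X[:-n_val], codes[:-n_val]
            Xva, cva = X[-n_val:], codes[-n_val:]
            gtr = np.array(["train"] * len(Xtr))
            gva = np.array(["val"] * len(Xva))

        if self.standardize:
            mu, sd = fit_standardizer(Xtr)
            self.standardizer_ = (mu, sd)
            Xtr = apply_standardizer(Xtr, mu, sd)
            Xva = apply_standardizer(Xva, mu, sd)
        else:
            self.standardizer_ = None

        train_ds = self._build_datasets(Xtr, ctr, gtr, self.tau)
        val_ds = self._build_datasets(Xva, cva, gva, self.tau)
        split = DatasetSplit(train=train_ds, validation=val_ds)

        P, M, T = X.shape[1:]
        cfg = ModelConfig(
            P=P, M=M, T=T, Y=int(self.classes_.size), tau=self.tau, Q=self.Q,
            widths=tuple(self.widths), dropout=self.dropout,
            lambda_reg=self.lambda_reg, arch=self.arch, scheme=self.scheme,
            input_context=self.input_context,
        )
        self.config_ = cfg
        model = build_model(cfg, seed=self.random_state)
        tc = TrainConfig(
            learning_rate=self.learning_rate,
            n_train_epochs=self.n_train_epochs,
            batch_size=self.batch_size,
            seed=self.random_state,
            selection_metric=self.selection_metric,
        )
        self.model_, self.history_ = train_model(model, split, tc)
        return self

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = self._check_X(X)
        if self.standardizer_ is not None:
            X = apply_standardizer(X, *self.standardizer_)
        return X

    def posteriors(self, X, groups: Optional[Sequence] = None):
        """Per-epoch multi-task posteriors, grouped by recording."""
        check_is_fitted(self, "model_")
        X = self._prepare(X)
        groups = (
            np.zeros(len(X), dtype=int) if groups is None else np.asarray(groups)
        )
        out = {}
        for g, idx in _iter_groups(groups):
            imgs = X[idx]
            if self.scheme == "many_to_one":
                imgs = _context_input(imgs, self.input_context)
            out[g] = (idx, predict_recording(self.model_, imgs))
        return out

    def predict(self, X, groups: Optional[Sequence] = None) -> np.ndarray:
        """Aggregated stage labels for every epoch."""
        pred_codes = np.empty(len(np.asarray(X)), dtype=np.int64)
        for _, (idx, posts) in self.posteriors(X, groups).items():
            seq = aggregate_recording(
                posts, tau=self.model_.cfg.tau, scheme=self._scheme_tag(),
                vocab=_CodeVocab(self.classes_.size),
            )
            pred_codes[idx] = seq.codes()
        return self.classes_[pred_codes]

    def _scheme_tag(self) -> str:
        if self.vote in ("additive", "multiplicative", "none"):
            return self.vote
        raise ValueError(f"unknown vote {self.vote!r}")

    def predict_proba(self, X, groups: Optional[Sequence] = None) -> np.ndarray:
        """Classification-subtask probabilities (no ensemble), classes_ order."""
        check_is_fitted(self, "model_")
        Xp = self._prepare(X)
        probs = self.model_.predict_proba(Xp) if self.scheme != "many_to_one" else None
        if probs is None:
            rows = []
            for _, (idx, posts) in self.posteriors(X, groups).items():
                for p in posts:
                    rows.append(p.classification_row)
            return np.stack(rows)
        return probs[:, self.model_.cfg.tau, :]


def _CodeVocab(Y: int):
    from .stages import StageVocabulary

    return StageVocabulary(labels=tuple(str(i) for i in range(Y)))
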