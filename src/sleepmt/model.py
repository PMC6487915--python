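"""Multi-task CNN for joint classification and neighbor prediction.

Given one epoch's P x M x T time-frequency image, the network jointly emits
2*tau + 1 stage distributions: one for the epoch itself (classification) and
one for each neighbor in the output context (prediction). The default
architecture is deliberately shallow:

    R filter sets of Q over-time filters (temporal widths w, each filter
    spanning all P channels and M bands) -> ReLU -> 1-max pooling -> dropout
    -> multi-task softmax (2*tau+1 independent Y-way heads).

Convolution + 1-max pooling acts as learned template matching: each filter is
a time-frequency template and the retained maximum is its best matching score
anywhere in the epoch. A conventional deep CNN (two 3x3 conv/pool stages and
two 1024-unit dense layers) is available as ``arch="deep_baseline"``, and the
standard one-to-one and contextual-input many-to-one schemes are available as
configuration variants.

Training minimizes the multi-task loss: the mean over examples of the summed
per-subtask cross-entropies plus an L2 penalty (lambda/2)*||theta||^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._nn import (
    conv2d_same,
    conv2d_same_backward,
    conv_over_time,
    conv_over_time_batch,
    maxpool2d,
    maxpool2d_backward,
    one_max_pool,
    softmax,
)

__all__ = [
    "ModelConfig",
    "MultiTaskPosterior",
    "MultiTaskCNN",
    "build_model",
    "forward",
    "multitask_loss",
    "conv_over_time",
    "one_max_pool",
]

PROB_CLIP = 1e-12  # floor inside log to tolerate clipped softmax zeros


@dataclass
class ModelConfig:
    """Architecture and scheme configuration.

    tau is the output-context radius: the network emits 2*tau+1 stage
    distributions (tau=1 -> context size 3). ``scheme`` selects between the
    one-to-many multi-task setup, the standard one-to-one classifier
    (tau forced to 0), and the contextual-input many-to-one classifier whose
    input is ``input_context`` epochs concatenated along time.
    """

    P: int = 3
    M: int = 20
    T: int = 29
    Y: int = 5
    tau: int = 1
    Q: int = 100
    widths: tuple[int, ...] = (3, 5, 7)
    dropout: float = 0.2
    lambda_reg: float = 1e-3
    arch: str = "one_max"
    scheme: str = "one_to_many"
    input_context: int = 3

    def __post_init__(self) -> None:
        if self.arch not in ("one_max", "deep_baseline"):
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.scheme not in ("one_to_many", "one_to_one", "many_to_one"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.scheme in ("one_to_one", "many_to_one") and self.tau != 0:
            raise ValueError(
                f"scheme {self.scheme!r} produces a single decision; tau must be 0"
            )
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.scheme == "many_to_one" and self.input_context < 1:
            raise ValueError("input_context must be >= 1")
        if self.arch == "one_max" and any(w >= self.effective_T for w in self.widths):
            raise ValueError(
                f"all filter widths {self.widths} must be < effective T "
                f"({self.effective_T})"
            )

    @property
    def effective_T(self) -> int:
        """Time extent of the network input (widened for many_to_one)."""
        return self.T * self.input_context if self.scheme == "many_to_one" else self.T

    @property
    def n_subtasks(self) -> int:
        return 2 * self.tau + 1

    @property
    def R(self) -> int:
        return len(self.widths)


@dataclass
class MultiTaskPosterior:
    """(2*tau+1) x Y probability rows, subtask order (n-tau, ..., n, ..., n+tau)."""

    probs: np.ndarray
    tau: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 2 * self.tau + 1:
            raise ValueError(
                f"expected (2*tau+1={2 * self.tau + 1}) x Y probs, got {self.probs.shape}"
            )
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("every subtask row must sum to 1")

    @property
    def classification_row(self) -> np.ndarray:
        """The epoch's own (center) stage distribution."""
        return self.probs[self.tau]

    def row_for_offset(self, offset: int) -> np.ndarray:
        """Distribution the network assigns to the neighbor at ``offset``."""
        if abs(offset) > self.tau:
            raise IndexError(f"offset {offset} outside context radius {self.tau}")
        return self.probs[self.tau + offset]


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


class MultiTaskCNN:
    """The network: parameter container plus forward/backward passes.

    Parameters live in ``self.params`` (a dict of named arrays) so the whole
    model serializes to an .npz checkpoint. Dropout is active only when a
    random generator is passed to the training pass; inference is
    deterministic.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0) -> None:
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        p: Dict[str, np.ndarray] = {}
        K, Y = cfg.n_subtasks, cfg.Y
        if cfg.arch == "one_max":
            for w in cfg.widths:
                fan_in = cfg.P * cfg.M * w
                p[f"conv_w{w}"] = _uniform_init(rng, (cfg.Q, cfg.P, cfg.M, w), fan_in)
            D = cfg.Q * cfg.R
        else:  # deep_baseline, per the published parameterization
            p["c1_W"] = _uniform_init(rng, (96, cfg.P, 3, 3), cfg.P * 9)
            p["c1_b"] = np.zeros(96)
            p["c2_W"] = _uniform_init(rng, (96, 96, 3, 3), 96 * 9)
            p["c2_b"] = np.zeros(96)
            h1 = cfg.M // 2
            h2, w2 = h1 // 2, cfg.effective_T // 2
            self._flat_dim = 96 * h2 * w2
            p["fc1_W"] = _uniform_init(rng, (1024, self._flat_dim), self._flat_dim)
            p["fc1_b"] = np.zeros(1024)
            p["fc2_W"] = _uniform_init(rng, (1024, 1024), 1024)
            p["fc2_b"] = np.zeros(1024)
            D = 1024
        p["out_W"] = _uniform_init(rng, (K * Y, D), D)
        p["out_b"] = np.zeros(K * Y)
        self.params = p
        self._feat_dim = D

    # ----- bookkeeping -------------------------------------------------
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def clone(self) -> "MultiTaskCNN":
        other = MultiTaskCNN.__new__(MultiTaskCNN)
        other.cfg = self.cfg
        other.seed = self.seed
        other.params = {k: v.copy() for k, v in self.params.items()}
        other._feat_dim = self._feat_dim
        if hasattr(self, "_flat_dim"):
            other._flat_dim = self._flat_dim
        return other

    def l2_norm_sq(self) -> float:
        return float(sum(np.sum(v * v) for v in self.params.values()))

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X[None]
        cfg = self.cfg
        expect = (cfg.P, cfg.M, cfg.effective_T)
        if X.ndim != 4 or X.shape[1:] != expect:
            raise ValueError(f"input must be (B,) + {expect}, got {X.shape}")
        return X

    # ----- forward -----------------------------------------------------
    def _features(self, X: np.ndarray, cache: Optional[dict] = None) -> np.ndarray:
        """Pooled feature vectors (B, D); fills ``cache`` for backward."""
        cfg = self.cfg
        if cfg.arch == "one_max":
            feats = []
            for w in cfg.widths:
                fmap = conv_over_time_batch(X, self.params[f"conv_w{w}"])  # (B,Q,L)
                relu = np.maximum(fmap, 0.0)
                idx = np.argmax(relu, axis=2)  # (B, Q)
                pooled = np.take_along_axis(relu, idx[:, :, None], axis=2)[:, :, 0]
                if cache is not None:
                    cache[f"idx_{w}"] = idx
                    cache[f"pooled_{w}"] = pooled
                feats.append(pooled)
            return np.concatenate(feats, axis=1)
        # deep baseline
        c1, X1p = conv2d_same(X, self.params["c1_W"], self.params["c1_b"])
        r1 = np.maximum(c1, 0.0)
        p1, i1 = maxpool2d(r1, (2, 1))
        c2, X2p = conv2d_same(p1, self.params["c2_W"], self.params["c2_b"])
        r2 = np.maximum(c2, 0.0)
        p2, i2 = maxpool2d(r2, (2, 2))
        flat = p2.reshape(X.shape[0], -1)
        z1 = flat @ self.params["fc1_W"].T + self.params["fc1_b"]
        h1 = np.maximum(z1, 0.0)
        z2 = h1 @ self.params["fc2_W"].T + self.params["fc2_b"]
        h2 = np.maximum(z2, 0.0)
        if cache is not None:
            cache.update(
                X=X, X1p=X1p, c1=c1, r1_shape=r1.shape, i1=i1, p1=p1, X2p=X2p,
                c2=c2, r2_shape=r2.shape, i2=i2, p2_shape=p2.shape, flat=flat,
                z1=z1, h1=h1, z2=z2, h2=h2,
            )
        return h2

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Inference pass (dropout off): (B, 2*tau+1, Y) probabilities."""
        X = self._check_input(X)
        h = self._features(X)
        K, Y = self.cfg.n_subtasks, self.cfg.Y
        logits = h @ self.params["out_W"].T + self.params["out_b"]
        return softmax(logits.reshape(X.shape[0], K, Y), axis=2)

    def forward(self, x: np.ndarray) -> MultiTaskPosterior:
        """Posterior for a single epoch image."""
        probs = self.predict_proba(np.asarray(x)[None] if np.asarray(x).ndim == 3 else x)
        return MultiTaskPosterior(probs=probs[0], tau=self.cfg.tau)

    # ----- training pass ----------------------------------------------
    def loss_and_grads(
        self,
        X: np.ndarray,
        targets: np.ndarray,
        rng: Optional[np.random.Generator] = None,
    ) -> Tuple[float, Dict[str, np.ndarray]]:
        """Multi-task loss and parameter gradients on a batch.

        ``targets`` is (B, 2*tau+1, Y) one-hot. Dropout masks are drawn from
        ``rng`` when given (training mode); otherwise dropout is off.
        """
        cfg = self.cfg
        X = self._check_input(X)
        B = X.shape[0]
        K, Y = cfg.n_subtasks, cfg.Y
        targets = _validate_onehot(targets, (B, K, Y))
        cache: dict = {}
        h = self._features(X, cache)
        drop_mask = None
        if rng is not None and cfg.dropout > 0:
            drop_mask = (rng.random(h.shape) >= cfg.dropout) / (1 - cfg.dropout)
            h = h * drop_mask
        logits = (h @ self.params["out_W"].T + self.params["out_b"]).reshape(B, K, Y)
        probs = softmax(logits, axis=2)
        ce = -np.sum(targets * np.log(np.clip(probs, PROB_CLIP, None))) / B
        loss = ce + 0.5 * cfg.lambda_reg * self.l2_norm_sq()

        grads: Dict[str, np.ndarray] = {}
        dlogits = ((probs - targets) / B).reshape(B, K * Y)
        grads["out_W"] = dlogits.T @ h
        grads["out_b"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params["out_W"]
        if drop_mask is not None:
            dh = dh * drop_mask
        self._backward_features(dh, cache, grads, X)
        for k, v in self.params.items():
            grads[k] = grads[k] + cfg.lambda_reg * v
        return float(loss), grads

    def _backward_features(
        self, dh: np.ndarray, cache: dict, grads: Dict[str, np.ndarray], X: np.ndarray
    ) -> None:
        cfg = self.cfg
        if cfg.arch == "one_max":
            off = 0
            for w in cfg.widths:
                dpool = dh[:, off : off + cfg.Q]  # (B, Q)
                off += cfg.Q
                # gradient flows only where the pooled (post-ReLU) max is > 0
                dpool = dpool * (cache[f"pooled_{w}"] > 0)
                idx = cache[f"idx_{w}"]  # (B, Q) winning time offsets
                windows = sliding_window_view(X, w, axis=3)  # (B,P,M,L,w)
                Bn = X.shape[0]
                gathered = windows[np.arange(Bn)[:, None], :, :, idx, :]  # (B,Q,P,M,w)
                grads[f"conv_w{w}"] = np.einsum("bq,bqpmw->qpmw", dpool, gathered)
            return
        # deep baseline
        dz2 = dh * (cache["z2"] > 0)
        grads["fc2_W"] = dz2.T @ cache["h1"]
        grads["fc2_b"] = dz2.sum(axis=0)
        dh1 = dz2 @ self.params["fc2_W"]
        dz1 = dh1 * (cache["z1"] > 0)
        grads["fc1_W"] = dz1.T @ cache["flat"]
        grads["fc1_b"] = dz1.sum(axis=0)
        dflat = dz1 @ self.params["fc1_W"]
        dp2 = dflat.reshape(cache["p2_shape"])
        dr2 = maxpool2d_backward(dp2, cache["i2"], cache["r2_shape"], (2, 2))
        dc2 = dr2 * (cache["c2"] > 0)
        dp1, grads["c2_W"], grads["c2_b"] = conv2d_same_backward(
            dc2, cache["X2p"], self.params["c2_W"], cache["p1"].shape
        )
        dr1 = maxpool2d_backward(dp1, cache["i1"], cache["r1_shape"], (2, 1))
        dc1 = dr1 * (cache["c1"] > 0)
        _, grads["c1_W"], grads["c1_b"] = conv2d_same_backward(
            dc1, cache["X1p"], self.params["c1_W"], cache["X"].shape
        )


def _validate_onehot(targets: np.ndarray, shape: Tuple[int, int, int]) -> np.ndarray:
    targets = np.asarray(targets, dtype=float)
    if targets.shape != shape:
        raise ValueError(f"targets must have shape {shape}, got {targets.shape}")
    is01 = np.all((targets == 0) | (targets == 1))
    if not is01 or not np.allclose(targets.sum(axis=2), 1.0):
        raise ValueError("targets must be one-hot rows over the stage set")
    return targets


def build_model(cfg: ModelConfig, seed: int = 0) -> MultiTaskCNN:
    """Initialize a network for ``cfg`` (variance-scaled uniform init, seeded)."""
    return MultiTaskCNN(cfg, seed=seed)


def forward(model: MultiTaskCNN, x) -> MultiTaskPosterior:
    """Posterior of a single epoch image (dropout off)."""
    from .spectral import TFImage

    values = x.values if isinstance(x, TFImage) else np.asarray(x)
    return model.forward(values)


def multitask_loss(
    posteriors: np.ndarray,
    targets: np.ndarray,
    params: Optional[Dict[str, np.ndarray] | MultiTaskCNN] = None,
    lambda_reg: float = 0.0,
) -> float:
    """Multi-task loss of a batch of posteriors against one-hot targets.

    Mean over examples of the summed per-subtask cross-entropies, plus
    (lambda/2)*||theta||^2 when parameters are supplied. Probabilities are
    clipped at 1e-12 inside the log, so the value is always finite and
    nonnegative (up to the clip).
    """
    P = np.asarray(posteriors, dtype=float)
    if P.ndim != 3:
        raise ValueError("posteriors must be (B, n_subtasks, Y)")
    targets = _validate_onehot(np.asarray(targets), P.shape)
    if P.shape[0] < 1:
        raise ValueError("need at least one example")
    ce = -np.sum(targets * np.log(np.clip(P, PROB_CLIP, None))) / P.shape[0]
    if lambda_reg and params is not None:
        if isinstance(params, MultiTaskCNN):
            sq = params.l2_norm_sq()
        else:
            sq = float(sum(np.sum(v * v) for v in params.values()))
        ce += 0.5 * lambda_reg * sq
    return float(ce)
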