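"""Low-level numpy neural-network primitives.

Shared by the multi-task CNN and the filter-bank pretrainer: over-time
convolution, 1-max pooling, 2-D convolution/pooling (for the deep CNN
baseline), softmax and an Adam optimizer. Gradients are hand-derived; the
test suite checks them against finite differences.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "softmax",
    "conv_over_time",
    "one_max_pool",
    "conv_over_time_batch",
    "AdamState",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def conv_over_time(image: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Valid cross-correlation of a P x M x w filter over the time axis.

    The filter covers the channel and frequency axes entirely and slides over
    time with stride 1, producing a feature map of length T - w + 1.
    """
    image = np.asarray(image, dtype=float)
    filt = np.asarray(filt, dtype=float)
    if image.ndim != 3 or filt.ndim != 3:
        raise ValueError("image and filter must be 3-D (P, M, w/T)")
    P, M, T = image.shape
    Pf, Mf, w = filt.shape
    if (Pf, Mf) != (P, M):
        raise ValueError(
            f"filter must cover channels and frequency: image {image.shape}, "
            f"filter {filt.shape}"
        )
    if w > T:
        raise ValueError(f"filter width w={w} exceeds T={T}")
    windows = sliding_window_view(image, w, axis=2)  # (P, M, L, w)
    return np.einsum("pmlw,pmw->l", windows, filt)


def one_max_pool(feature_map: np.ndarray) -> float:
    """Retain the most prominent feature: the maximum of the map."""
    fm = np.asarray(feature_map, dtype=float)
    if fm.size == 0:
        raise ValueError("cannot 1-max pool an empty feature map")
    return float(np.max(fm))


def conv_over_time_batch(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Batched over-time convolution: (B,P,M,T) x (Q,P,M,w) -> (B,Q,L)."""
    w = W.shape[-1]
    windows = sliding_window_view(X, w, axis=3)  # (B, P, M, L, w)
    return np.einsum("bpmlw,qpmw->bql", windows, W)


def conv2d_same(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """'same'-padded 2-D convolution: (B,C,H,Wd) x (K,C,kh,kw) -> (B,K,H,Wd).

    Returns (output, padded input) — the padded input is reused by backward.
    """
    K, C, kh, kw = W.shape
    ph, pw = kh // 2, kw // 2
    Xp = np.pad(X, ((0, 0), (0, 0), (ph, kh - 1 - ph), (pw, kw - 1 - pw)))
    win = sliding_window_view(Xp, (kh, kw), axis=(2, 3))  # (B,C,H,Wd,kh,kw)
    out = np.einsum("bchwij,kcij->bkhw", win, W) + b[None, :, None, None]
    return out, Xp


def conv2d_same_backward(
    dout: np.ndarray, Xp: np.ndarray, W: np.ndarray, x_shape: Tuple[int, ...]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of conv2d_same w.r.t. (X, W, b)."""
    K, C, kh, kw = W.shape
    ph, pw = kh // 2, kw // 2
    win = sliding_window_view(Xp, (kh, kw), axis=(2, 3))
    dW = np.einsum("bkhw,bchwij->kcij", dout, win)
    db = dout.sum(axis=(0, 2, 3))
    # full correlation of dout with flipped W gives dX
    dpad = np.pad(dout, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
    dwin = sliding_window_view(dpad, (kh, kw), axis=(2, 3))
    Wf = W[:, :, ::-1, ::-1]
    dXp = np.einsum("bkhwij,kcij->bchw", dwin, Wf)
    dX = dXp[:, :, ph : ph + x_shape[2], pw : pw + x_shape[3]]
    return dX, dW, db


def maxpool2d(X: np.ndarray, pool: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    """Non-overlapping max pooling; trailing rows/cols that do not fill a
    window are dropped. Returns (output, argmax indices for backward)."""
    B, C, H, W = X.shape
    ph, pw = pool
    Ho, Wo = H // ph, W // pw
    Xc = X[:, :, : Ho * ph, : Wo * pw].reshape(B, C, Ho, ph, Wo, pw)
    Xc = Xc.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, ph * pw)
    idx = np.argmax(Xc, axis=-1)
    out = np.take_along_axis(Xc, idx[..., None], axis=-1)[..., 0]
    return out, idx


def maxpool2d_backward(
    dout: np.ndarray, idx: np.ndarray, x_shape: Tuple[int, ...], pool: Tuple[int, int]
) -> np.ndarray:
    B, C, H, W = x_shape
    ph, pw = pool
    Ho, Wo = H // ph, W // pw
    dXc = np.zeros((B, C, Ho, Wo, ph * pw))
    np.put_along_axis(dXc, idx[..., None], dout[..., None], axis=-1)
    dXc = dXc.reshape(B, C, Ho, Wo, ph, pw).transpose(0, 1, 2, 4, 3, 5)
    dX = np.zeros(x_shape)
    dX[:, :, : Ho * ph, : Wo * pw] = dXc.reshape(B, C, Ho * ph, Wo * pw)
    return dX


class AdamState:
    """Adam optimizer over a dict of named parameter arrays.

    Conventional moment defaults (beta1=0.9, beta2=0.999, eps=1e-8); only the
    learning rate is typically varied.
    """

    def __init__(
        self,
        params: Dict[str, np.ndarray],
        learning_rate: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
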