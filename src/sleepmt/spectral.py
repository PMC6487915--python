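"""Time-frequency image representation of signal epochs.

A 30-s epoch is transformed channel-by-channel into a log-power spectrogram
(2-s symmetric Hamming windows, 50% overlap, 256-point FFT, giving an
F x T = 129 x 29 image at 100 Hz), then smoothed/reduced by a nonnegative
frequency-domain filter bank to M x T. The per-channel images are stacked
into the multi-channel time-frequency image X in R^{P x M x T} that the
multi-task CNN consumes.

The filter bank is either the regular triangular bank or a bank pretrained
discriminatively: a small softmax network whose first layer is a
nonnegativity-constrained linear M x F map, trained on single-epoch stage
classification so that weight mass concentrates on stage-informative bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import hamming

from ._nn import AdamState, softmax
from .stages import StageSequence
from .synthetic import EpochSignal

__all__ = [
    "SpectralConfig",
    "LogPowerSpectrogram",
    "FilterBank",
    "TFImage",
    "stft_logpower",
    "triangular_filterbank",
    "apply_filterbank",
    "make_tfimage",
    "pretrain_filterbank",
]


@dataclass
class SpectralConfig:
    """STFT / filter-bank settings.

    win_sec=2, overlap=0.5, Hamming taper and a 256-point FFT give the
    129 x 29 log-power image for a 30-s epoch at 100 Hz.
    """

    win_sec: float = 2.0
    overlap: float = 0.5
    nfft: int = 256
    window: str = "hamming"
    log_floor: float = 1e-10
    M: int = 20
    filter_before_log: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")
        if self.M < 1:
            raise ValueError("M must be >= 1")

    def win_length(self, fs: float) -> int:
        return int(round(fs * self.win_sec))

    def hop(self, fs: float) -> int:
        return max(1, int(round(self.win_length(fs) * (1 - self.overlap))))


@dataclass
class LogPowerSpectrogram:
    """F x T log-power image with frequency-bin and frame-time axes."""

    values: np.ndarray
    freqs_hz: np.ndarray
    frame_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("spectrogram values must be 2-D (F x T)")
        if self.values.shape != (len(self.freqs_hz), len(self.frame_times_s)):
            raise ValueError("axis lengths inconsistent with values shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrogram contains non-finite values")

    @property
    def F(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]


@dataclass
class FilterBank:
    """Nonnegative M x F matrix mapping spectrogram bins to M sub-bands."""

    weights: np.ndarray
    kind: str = "triangular"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("filter-bank weights must be 2-D (M x F)")
        if np.any(self.weights < 0):
            raise ValueError("filter-bank weights must be nonnegative")
        if np.any(self.weights.sum(axis=1) <= 0):
            raise ValueError("every filter row must have positive sum")

    @property
    def M(self) -> int:
        return self.weights.shape[0]

    @property
    def F(self) -> int:
        return self.weights.shape[1]


@dataclass
class TFImage:
    """Multi-channel filtered time-frequency image, P x M x T."""

    values: np.ndarray
    channels: tuple[str, ...]
    epoch_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != len(self.channels):
            raise ValueError(
                f"values must be (P, M, T) matching channels; got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TF image contains non-finite values")

    @property
    def shape(self):
        return self.values.shape


def stft_logpower(
    signal: np.ndarray, fs: float, cfg: SpectralConfig = SpectralConfig()
) -> LogPowerSpectrogram:
    """Short-time Fourier log-power spectrogram of a single-channel epoch.

    Frames are hop-spaced windows fully inside the signal (no padding), so
    T = floor((len - win) / hop) + 1, and values = log(|STFT|^2 + log_floor).
    """
    x = np.asarray(signal, dtype=float).ravel()
    win = cfg.win_length(fs)
    hop = cfg.hop(fs)
    if len(x) < win:
        raise ValueError(
            f"signal of {len(x)} samples is shorter than one {win}-sample window"
        )
    if cfg.nfft < win:
        raise ValueError(f"nfft={cfg.nfft} must be >= window length {win}")
    if cfg.window != "hamming":
        raise ValueError("only the Hamming taper is supported")
    taper = hamming(win, sym=True)
    frames = sliding_window_view(x, win)[::hop] * taper  # (T, win)
    spec = rfft(frames, n=cfg.nfft, axis=1)  # (T, F)
    power = np.abs(spec) ** 2
    values = np.log(power + cfg.log_floor).T  # (F, T)
    freqs = rfftfreq(cfg.nfft, d=1.0 / fs)
    t0 = (np.arange(frames.shape[0]) * hop + win / 2) / fs
    return LogPowerSpectrogram(values=values, freqs_hz=freqs, frame_times_s=t0)


def triangular_filterbank(M: int, F: int, fs: float) -> FilterBank:
    """Regular triangular bank: M linearly spaced triangles over [0, fs/2].

    Adjacent triangles overlap by 50% (each triangle's foot sits at the
    neighbors' peaks).
    """
    if M >= F:
        raise ValueError(f"need M < F, got M={M}, F={F}")
    freqs = np.linspace(0.0, fs / 2, F)
    edges = np.linspace(0.0, fs / 2, M + 2)  # feet and peaks
    weights = np.zeros((M, F))
    for m in range(M):
        lo, center, hi = edges[m], edges[m + 1], edges[m + 2]
        up = (freqs - lo) / (center - lo)
        down = (hi - freqs) / (hi - center)
        weights[m] = np.clip(np.minimum(up, down), 0.0, None)
        if weights[m].sum() == 0:  # guarantee a positive row on coarse grids
            weights[m, int(np.argmin(np.abs(freqs - center)))] = 1.0
    return FilterBank(weights=weights, kind="triangular")


def apply_filterbank(spec: LogPowerSpectrogram, fb: FilterBank) -> np.ndarray:
    """Filter an F x T spectrogram down to M x T (matrix product per frame)."""
    if fb.F != spec.F:
        raise ValueError(f"filter bank has F={fb.F} but spectrogram has F={spec.F}")
    return fb.weights @ spec.values


def make_tfimage(
    epoch: EpochSignal,
    banks: Sequence[FilterBank],
    cfg: SpectralConfig = SpectralConfig(),
    epoch_index: Optional[int] = None,
) -> TFImage:
    """Stack per-channel filtered spectrograms into a P x M x T image."""
    if len(banks) != len(epoch.channels):
        raise ValueError(
            f"{len(epoch.channels)} channels but {len(banks)} filter banks"
        )
    Ms = {fb.M for fb in banks}
    if len(Ms) != 1:
        raise ValueError(f"all banks must share M; got {sorted(Ms)}")
    slabs = []
    for c in range(len(epoch.channels)):
        spec = stft_logpower(epoch.samples[c], epoch.fs, cfg)
        if cfg.filter_before_log:
            power = np.exp(spec.values)  # undo log, filter, re-log
            filtered = np.log(banks[c].weights @ power + cfg.log_floor)
        else:
            filtered = apply_filterbank(spec, banks[c])
        slabs.append(filtered)
    return TFImage(
        values=np.stack(slabs), channels=epoch.channels, epoch_index=epoch_index
    )


def pretrain_filterbank(
    images: Sequence[LogPowerSpectrogram] | np.ndarray,
    labels: StageSequence | Sequence[int],
    M: int = 20,
    hidden: int = 256,
    n_steps: int = 50,
    learning_rate: float = 1e-3,
    seed: int = 0,
) -> FilterBank:
    """Learn a discriminative nonnegative filter bank from labelled spectrograms.

    A small network [nonneg linear M x F -> flatten -> ReLU hidden -> softmax]
    is trained with Adam on single-epoch stage classification; the constrained
    first layer (clamped to >= 0 after every step) is returned as the bank.
    Deterministic given ``seed``.
    """
    if isinstance(images, np.ndarray):
        S = np.asarray(images, dtype=float)
    else:
        S = np.stack([im.values for im in images])
    if S.ndim != 3:
        raise ValueError("images must stack to (n, F, T)")
    if isinstance(labels, StageSequence):
        y = labels.codes()
    else:
        y = np.asarray(labels, dtype=np.int64)
    if len(y) != S.shape[0]:
        raise ValueError("number of labels must match number of images")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("pretraining needs at least 2 distinct stage labels")
    y = np.searchsorted(classes, y)
    Yn = classes.size
    n, F, T = S.shape
    # standardize per frequency bin for optimization conditioning
    mu = S.mean(axis=(0, 2), keepdims=True)
    sd = S.std(axis=(0, 2), keepdims=True) + 1e-8
    Sz = (S - mu) / sd

    rng = np.random.default_rng(seed)
    params = {
        "fb": rng.uniform(0.0, np.sqrt(2.0 / F), size=(M, F)),
        "W1": rng.uniform(-1, 1, size=(hidden, M * T)) * np.sqrt(6.0 / (M * T)),
        "b1": np.zeros(hidden),
        "W2": rng.uniform(-1, 1, size=(Yn, hidden)) * np.sqrt(6.0 / hidden),
        "b2": np.zeros(Yn),
    }
    onehot = np.eye(Yn)[y]
    adam = AdamState(params, learning_rate=learning_rate)
    for _ in range(n_steps):
        # forward
        filt = np.einsum("mf,nft->nmt", params["fb"], Sz)  # (n, M, T)
        flat = filt.reshape(n, M * T)
        pre1 = flat @ params["W1"].T + params["b1"]
        h1 = np.maximum(pre1, 0.0)
        logits = h1 @ params["W2"].T + params["b2"]
        probs = softmax(logits, axis=1)
        # backward (mean cross-entropy)
        dlogits = (probs - onehot) / n
        grads = {
            "W2": dlogits.T @ h1,
            "b2": dlogits.sum(axis=0),
        }
        dh1 = dlogits @ params["W2"]
        dpre1 = dh1 * (pre1 > 0)
        grads["W1"] = dpre1.T @ flat
        grads["b1"] = dpre1.sum(axis=0)
        dflat = dpre1 @ params["W1"]
        dfilt = dflat.reshape(n, M, T)
        grads["fb"] = np.einsum("nmt,nft->mf", dfilt, Sz)
        adam.step(params, grads)
        np.clip(params["fb"], 0.0, None, out=params["fb"])
    # rows must keep positive sum for a valid bank
    rowsum = params["fb"].sum(axis=1)
    for m in np.nonzero(rowsum <= 0)[0]:
        params["fb"][m, int(rng.integers(F))] = 1e-6
    return FilterBank(weights=params["fb"], kind="learned")


def featurize_recording(
    recording,
    banks: Optional[Sequence[FilterBank]] = None,
    cfg: SpectralConfig = SpectralConfig(),
) -> np.ndarray:
    """Featurize a whole recording into an (n, P, M, T) tensor.

    With ``banks=None`` a triangular bank is built per channel.
    """
    if len(recording) == 0:
        raise ValueError("empty recording")
    if banks is None:
        F = cfg.nfft // 2 + 1
        banks = [
            triangular_filterbank(cfg.M, F, recording.fs)
            for _ in recording.channels
        ]
    return np.stack(
        [
            make_tfimage(ep, banks, cfg, epoch_index=i).values
            for i, ep in enumerate(recording.epochs)
        ]
    )
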