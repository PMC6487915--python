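"""Fusion of the multi-task decision ensemble.

For epoch n, the one-to-many model supplies up to 2*tau+1 stage
distributions: its own classification P(y_n | X_n) and the predictions
P(y_n | X_i) made by each neighbor i in [n-tau, n+tau]. Additive voting
averages the rows; multiplicative voting multiplies them (in the log domain
with a probability floor), which suppresses stages with diverging decisions
more strongly. The final label is the score argmax, ties broken to the
lowest stage index. Boundary epochs aggregate over the contributors that
exist, so every epoch of a recording receives a label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .model import MultiTaskPosterior
from .stages import AASM5, StageSequence, StageVocabulary

__all__ = [
    "DecisionEnsemble",
    "AggregatedDecision",
    "gather_decisions",
    "additive_vote",
    "multiplicative_vote",
    "aggregate_recording",
]

PROB_FLOOR = 1e-12  # before log-domain products


@dataclass
class DecisionEnsemble:
    """The decisions available for target epoch ``n`` (0-based index).

    ``contributors`` holds (source epoch index i, probability row P(y_n|X_i))
    pairs with unique indices inside [n-tau, n+tau] clipped to the recording.
    """

    n: int
    contributors: List[Tuple[int, np.ndarray]]

    def __post_init__(self) -> None:
        if not self.contributors:
            raise ValueError("a decision ensemble needs at least one contributor")
        idx = [i for i, _ in self.contributors]
        if len(set(idx)) != len(idx):
            raise ValueError("contributor indices must be unique")
        for i, row in self.contributors:
            row = np.asarray(row, dtype=float)
            if abs(row.sum() - 1.0) > 1e-6:
                raise ValueError(f"contributor {i} row does not sum to 1")

    def rows(self) -> np.ndarray:
        return np.stack([np.asarray(r, dtype=float) for _, r in self.contributors])

    def __len__(self) -> int:
        return len(self.contributors)


@dataclass
class AggregatedDecision:
    """Fused stage scores and the chosen label (argmax, lowest index on ties)."""

    scores: np.ndarray
    label_index: int
    scheme: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.label_index != int(np.argmax(self.scores)):
            raise ValueError("chosen label must be the argmax of the scores")


def gather_decisions(
    posteriors: Sequence[MultiTaskPosterior], n: int, tau: int
) -> DecisionEnsemble:
    """Collect every decision that targets epoch ``n``.

    From the posterior of each neighbor i in [n-tau, n+tau] (clipped to the
    recording) the subtask row aiming at epoch n is extracted: neighbor i's
    posterior row at offset n - i.
    """
    N = len(posteriors)
    if not 0 <= n < N:
        raise IndexError(f"epoch index {n} outside recording of length {N}")
    contributors = []
    for i in range(max(0, n - tau), min(N - 1, n + tau) + 1):
        contributors.append((i, posteriors[i].row_for_offset(n - i)))
    return DecisionEnsemble(n=n, contributors=contributors)


def additive_vote(e: DecisionEnsemble) -> AggregatedDecision:
    """Arithmetic mean of the contributor rows (a valid probability row)."""
    scores = e.rows().mean(axis=0)
    return AggregatedDecision(
        scores=scores, label_index=int(np.argmax(scores)), scheme="additive"
    )


def multiplicative_vote(e: DecisionEnsemble) -> AggregatedDecision:
    """Product of the contributor rows, scaled by 1/count.

    Rows are floored at 1e-12; realistic-size ensembles use a direct product
    (exact tie-break symmetry), very large ones the log domain. The 1/count
    factor is kept for fidelity with the additive form; it does not affect
    the argmax.
    """
    rows = np.clip(e.rows(), PROB_FLOOR, None)
    if len(e) <= 20:
        # direct product: exactly symmetric across stages, so exact ties
        # resolve deterministically to the lowest index; cannot underflow
        # at realistic context sizes (worst case (1e-12)^20 = 1e-240)
        scores = np.prod(rows, axis=0) / len(e)
    else:
        scores = np.exp(np.sum(np.log(rows), axis=0)) / len(e)
    return AggregatedDecision(
        scores=scores, label_index=int(np.argmax(scores)), scheme="multiplicative"
    )


def aggregate_recording(
    posteriors: Sequence[MultiTaskPosterior],
    tau: int,
    scheme: str = "multiplicative",
    vocab: StageVocabulary = AASM5,
) -> StageSequence:
    """Fuse the decision ensembles of a whole recording into a hypnogram.

    ``scheme="none"`` uses each epoch's own classification row only; with
    tau=0 all three schemes coincide exactly.
    """
    if len(posteriors) == 0:
        raise ValueError("empty posterior sequence")
    if scheme not in ("additive", "multiplicative", "none"):
        raise ValueError(f"unknown aggregation scheme {scheme!r}")
    codes = []
    for n in range(len(posteriors)):
        if scheme == "none":
            codes.append(int(np.argmax(posteriors[n].classification_row)))
            continue
        e = gather_decisions(posteriors, n, tau)
        vote = additive_vote(e) if scheme == "additive" else multiplicative_vote(e)
        codes.append(vote.label_index)
    return StageSequence.from_codes(codes, vocab=vocab)
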