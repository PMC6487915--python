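"""Sleep-stage vocabularies and per-epoch label sequences.

The atomic scoring unit is a 30-second *epoch*; a night of sleep is scored
as an ordered sequence of stage labels (a hypnogram). The default vocabulary
is the five-stage AASM set {W, N1, N2, N3, REM}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = ["StageVocabulary", "StageSequence", "AASM5"]


@dataclass(frozen=True)
class StageVocabulary:
    """An ordered set of stage names; index of a label is 0-based and stable."""

    labels: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"stage labels must be unique, got {self.labels}")
        if len(self.labels) < 2:
            raise ValueError("a stage vocabulary needs at least 2 stages")

    @property
    def Y(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown stage {label!r}; valid stages are {list(self.labels)}"
            ) from None

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __len__(self) -> int:
        return self.Y


#: The five-stage AASM vocabulary used throughout by default.
AASM5 = StageVocabulary()


@dataclass
class StageSequence:
    """Ordered per-epoch stage labels over a recording (a hypnogram).

    Parameters
    ----------
    labels : sequence of str
        One stage token per epoch, each a member of ``vocab``.
    vocab : StageVocabulary
    epoch_sec : float
        Duration of one scoring epoch in seconds (30 by convention).
    recording_id : str, optional
    """

    labels: tuple[str, ...]
    vocab: StageVocabulary = field(default_factory=StageVocabulary)
    epoch_sec: float = 30.0
    recording_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        for lab in self.labels:
            if lab not in self.vocab:
                raise KeyError(
                    f"unknown stage {lab!r}; valid stages are {list(self.vocab.labels)}"
                )

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i):
        return self.labels[i]

    def __iter__(self):
        return iter(self.labels)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, StageSequence)
            and self.labels == other.labels
            and self.vocab.labels == other.vocab.labels
        )

    def codes(self) -> np.ndarray:
        """Integer stage codes (0-based vocabulary indices)."""
        return np.array([self.vocab.index(lab) for lab in self.labels], dtype=np.int64)

    @classmethod
    def from_codes(
        cls,
        codes: Iterable[int],
        vocab: StageVocabulary = AASM5,
        epoch_sec: float = 30.0,
        recording_id: Optional[str] = None,
    ) -> "StageSequence":
        labels = tuple(vocab.labels[int(c)] for c in codes)
        return cls(labels, vocab=vocab, epoch_sec=epoch_sec, recording_id=recording_id)

    def adjacent_agreement(self, step: int = 1) -> float:
        """Fraction of label pairs ``step`` epochs apart that agree."""
        if len(self) <= step:
            raise ValueError("sequence too short for the requested step")
        c = self.codes()
        return float(np.mean(c[:-step] == c[step:]))
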