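"""Published benchmark confusion matrices for multi-task 1-max CNN staging.

Integer epoch counts reported for the one-to-many multi-task framework on
the Sleep-EDF Expanded (20 subjects, leave-one-subject-out) and MASS
(200 subjects, 20-fold) cohorts. Rows are the reference (ground-truth)
stage, columns the predicted stage, in vocabulary order (W, N1, N2, N3,
REM). They serve as worked examples for the metrics suite: overall accuracy
evaluates to 82.3% (Sleep-EDF) and 83.6% (MASS), kappa to 0.75 and 0.77, and
the MASS counts total 228,870 epochs.
"""

from __future__ import annotations

import numpy as np

from .metrics import ConfusionMatrix
from .stages import AASM5

__all__ = [
    "SLEEP_EDF_CONFUSION",
    "MASS_CONFUSION",
    "sleep_edf_confusion",
    "mass_confusion",
]

SLEEP_EDF_CONFUSION = np.array(
    [
        [3403, 322, 230, 32, 522],
        [441, 880, 725, 9, 707],
        [230, 263, 15263, 795, 1026],
        [65, 0, 658, 4850, 18],
        [154, 114, 457, 3, 6983],
    ],
    dtype=np.int64,
)

MASS_CONFUSION = np.array(
    [
        [26261, 2148, 1450, 72, 1112],
        [2924, 7948, 5498, 22, 2965],
        [759, 3429, 95486, 4849, 3395],
        [30, 13, 6098, 24223, 18],
        [466, 872, 1353, 6, 37473],
    ],
    dtype=np.int64,
)


def sleep_edf_confusion() -> ConfusionMatrix:
    """The Sleep-EDF benchmark matrix as a ConfusionMatrix."""
    return ConfusionMatrix(counts=SLEEP_EDF_CONFUSION.copy(), vocab=AASM5)


def mass_confusion() -> ConfusionMatrix:
    """The MASS benchmark matrix as a ConfusionMatrix."""
    return ConfusionMatrix(counts=MASS_CONFUSION.copy(), vocab=AASM5)
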