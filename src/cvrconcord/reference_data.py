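"""Published per-subject voxel-classification percentages.

These tables come from a published nine-subject comparison of breath-hold
and resting-state cerebrovascular-reactivity maps in healthy adults.  Each
row gives the TP/TN/FP/FN voxel percentages at the subject's optimal
threshold(s), together with the accuracy and Dice values as printed
(percentages, rounded).  They serve as a worked example: feeding the four
cell percentages through :func:`cvrconcord.overlap.accuracy` and
:func:`cvrconcord.overlap.dice` reproduces the printed summary columns.

Three comparisons are tabulated:

- resting-state CVRe vs. gray matter (GWM-VOI),
- breath-hold CVR vs. gray matter (GWM-VOI),
- resting-state CVRe vs. breath-hold CVR (GM-VOI, resting as predictor).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "resting_vs_gray",
    "breathhold_vs_gray",
    "resting_vs_breathhold",
]

_COLUMNS = ["subject", "tp", "tn", "fp", "fn", "acc_printed", "dice_printed"]

_RESTING_VS_GRAY = [
    (1, 45, 32, 15, 8, 77, 79.7),
    (2, 41, 35, 17, 7, 76, 77.4),
    (3, 39, 33, 13, 15, 72, 73.6),
    (4, 37, 30, 22, 11, 67, 69.2),
    (5, 38, 35, 15, 12, 73, 73.8),
    (6, 42, 32, 18, 8, 74, 76.4),
    (7, 45, 26, 22, 7, 71, 75.6),
    (8, 41, 27, 21, 11, 68, 71.9),
    (9, 39, 28, 22, 11, 67, 70.3),
]

_BREATHHOLD_VS_GRAY = [
    (1, 36, 31, 17, 16, 67, 68.6),
    (2, 37, 33, 19, 11, 70, 71.2),
    (3, 36, 28, 19, 17, 64, 66.7),
    (4, 29, 28, 24, 19, 57, 57.4),
    (5, 34, 30, 20, 16, 64, 65.4),
    (6, 35, 31, 19, 15, 66, 67.3),
    (7, 41, 24, 24, 11, 65, 70.1),
    (8, 34, 23, 25, 18, 57, 61.3),
    (9, 38, 20, 30, 12, 58, 64.4),
]

_RESTING_VS_BREATHHOLD = [
    (1, 65, 9, 20, 6, 74, 83.3),
    (2, 72, 9, 13, 6, 81, 88.3),
    (3, 59, 14, 17, 10, 73, 81.4),
    (4, 52, 17, 25, 6, 69, 77.0),
    (5, 56, 18, 18, 8, 74, 81.2),
    (6, 62, 11, 23, 4, 73, 82.1),
    (7, 65, 9, 22, 4, 74, 83.3),
    (8, 62, 13, 19, 6, 75, 83.2),
    (9, 60, 10, 18, 12, 70, 80.0),
]


def _frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=_COLUMNS)


def resting_vs_gray() -> pd.DataFrame:
    """Per-subject resting-state CVRe vs. gray matter classification (%)."""
    return _frame(_RESTING_VS_GRAY)


def breathhold_vs_gray() -> pd.DataFrame:
    """Per-subject breath-hold CVR vs. gray matter classification (%)."""
    return _frame(_BREATHHOLD_VS_GRAY)


def resting_vs_breathhold() -> pd.DataFrame:
    """Per-subject cross-metric classification within gray matter (%)."""
    return _frame(_RESTING_VS_BREATHHOLD)
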