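"""ROC screening of MCI against cognitively normal participants.

A continuous score (the HRMG mean-total game score, an out-of-fold
classifier probability, or a clinical screen such as MMSE / MoCA) is swept
over every distinct threshold to produce the ROC curve and its trapezoidal
AUC. For game and clinical scores impairment means *lower* values, so the
default direction flags low scores as positive; cut-off screening at the
conventional clinical thresholds (MoCA < 26, MMSE < 27) yields confusion
counts, sensitivity, specificity and raw accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn import metrics as _skmetrics

#: conventional screening cut-offs: score strictly below flags positive
DEFAULT_CUTOFFS = {"mmse": 27.0, "moca": 26.0}


@dataclass
class ROCResult:
    score_name: str
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    direction: str


@dataclass
class ScreenResult:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float  # fraction in [0, 1]


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[int],
    direction: str = "higher_is_positive",
    score_name: str = "",
) -> ROCResult:
    """ROC curve with thresholds at every distinct score.

    ``labels`` are 1 for the positive class. Ties contribute diagonal
    segments and the AUC is the trapezoidal area, which equals the
    tie-corrected Mann–Whitney concordance U/(n_pos·n_neg).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if direction == "lower_is_positive":
        oriented = -s
    elif direction == "higher_is_positive":
        oriented = s
    else:
        raise ValueError(f"unknown direction: {direction!r}")
    fpr, tpr, thr = _skmetrics.roc_curve(y, oriented, drop_intermediate=False)
    if direction == "lower_is_positive":
        thr = -thr
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        score_name=score_name,
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
        direction=direction,
    )


def screen_at_cutoff(
    scores: Sequence[float],
    labels: Sequence[int],
    cutoff: float,
    direction: str = "lower_is_positive",
) -> ScreenResult:
    """Confusion counts and rates for a single hard cut-off.

    ``lower_is_positive`` flags scores strictly below the cut-off as
    positive (the convention for MMSE/MoCA/game scores, where impairment
    lowers the score); ``higher_is_positive`` flags scores strictly above.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.sum(y == 1) == 0 or np.sum(y == 0) == 0:
        raise ValueError("both classes must be present")
    if direction == "lower_is_positive":
        pred = s < cutoff
    elif direction == "higher_is_positive":
        pred = s > cutoff
    else:
        raise ValueError(f"unknown direction: {direction!r}")
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return ScreenResult(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / (tp + tn + fp + fn),
    )
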