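"""Classifier-style evaluation of scores against easy/hard synthesis labels.

Higher score means predicted harder to synthesize, so the hard class (HS)
is the positive class.  ROC-AUC is computed as the pairwise rank
statistic with ties counted half; PR-AUC as the interpolation-free step
integration of precision over recall (average precision).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["LabeledScore", "EvaluationError", "roc_auc", "pr_auc", "evaluate_scores", "LABEL_POSITIVE"]

LABEL_POSITIVE = "HS"
LABEL_NEGATIVE = "ES"


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class LabeledScore:
    molecule_id: str
    score: float
    label: str  # "ES" or "HS"


def _split(data: Sequence[LabeledScore]) -> tuple[list[float], list[float]]:
    pos, neg = [], []
    for item in data:
        if item.label == LABEL_POSITIVE:
            pos.append(item.score)
        elif item.label == LABEL_NEGATIVE:
            neg.append(item.score)
        else:
            raise EvaluationError(f"unknown label {item.label!r} (expected ES or HS)")
    if not pos or not neg:
        raise EvaluationError("both ES and HS labels are required to compute curves")
    return pos, neg


def roc_auc(data: Sequence[LabeledScore]) -> float:
    """Probability that a random HS outranks a random ES; ties count half."""
    pos, neg = _split(data)
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pr_auc(data: Sequence[LabeledScore]) -> float:
    """Step-integrated precision over recall, thresholding at each unique score."""
    pos, neg = _split(data)
    n_pos = len(pos)
    scored = sorted(
        [(s, 1) for s in pos] + [(s, 0) for s in neg], key=lambda t: t[0], reverse=True
    )
    auc = 0.0
    tp = fp = 0
    prev_tp = 0
    i = 0
    while i < len(scored):
        j = i
        # consume the whole tie group before evaluating the operating point
        while j < len(scored) and scored[j][0] == scored[i][0]:
            tp += scored[j][1]
            fp += 1 - scored[j][1]
            j += 1
        precision = tp / (tp + fp)
        auc += (tp - prev_tp) / n_pos * precision
        prev_tp = tp
        i = j
    return min(auc, 1.0)  # guard against float drift in the step sum


def evaluate_scores(data: Iterable[LabeledScore]) -> tuple[float, float]:
    """Return (PR-AUC, ROC-AUC) for labeled scores."""
    data = list(data)
    return pr_auc(data), roc_auc(data)
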