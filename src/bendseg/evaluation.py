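"""Segmentation scoring: confusion counts, Accuracy/JSC/DSC, paired tests.

Positive = tumor = mask value 1.  The Jaccard (JSC) and Dice (DSC)
coefficients obey the algebraic identity DSC = 2*JSC / (1 + JSC).

Empty-truth convention: when both prediction and truth are empty the
overlap scores are 1 (perfect agreement); when only one is empty they are
0.  Accuracy is always well defined from the counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts between two binary masks."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    for name, m in (("pred", pred), ("truth", truth)):
        if m.dtype != bool and not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        TP=int(np.sum(p & t)),
        FP=int(np.sum(p & ~t)),
        TN=int(np.sum(~p & ~t)),
        FN=int(np.sum(~p & t)),
    )


def metrics(counts: ConfusionCounts) -> Tuple[float, float, float]:
    """(accuracy, jsc, dsc) from confusion counts."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    acc = (counts.TP + counts.TN) / counts.total
    denom_j = counts.TP + counts.FP + counts.FN
    if denom_j == 0:  # truth and prediction both empty
        return float(acc), 1.0, 1.0
    jsc = counts.TP / denom_j
    dsc = 2 * counts.TP / (counts.FP + 2 * counts.TP + counts.FN)
    return float(acc), float(jsc), float(dsc)


def dice_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """Convenience: DSC straight from two masks."""
    return metrics(confusion(pred, truth))[2]


def paired_ttest(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Two-sided paired t-test p-value on per-image score differences."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equally sized 1D score lists, length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0) and not np.allclose(d, 0.0):
        raise ValueError("zero-variance nonzero differences: t undefined")
    if np.allclose(d, 0.0):
        return 1.0
    return float(stats.ttest_rel(a, b).pvalue)


def evaluate_batch(rows: Iterable[Tuple[str, np.ndarray, np.ndarray]]):
    """Per-image metric rows plus means, as a pandas DataFrame.

    ``rows`` yields (name, predicted mask, truth mask) triples.
    """
    import pandas as pd

    records = []
    for name, pred, truth in rows:
        acc, jsc, dsc = metrics(confusion(pred, truth))
        records.append({"image": name, "accuracy": acc, "jsc": jsc, "dsc": dsc})
    df = pd.DataFrame.from_records(records)
    if len(df):
        mean = df[["accuracy", "jsc", "dsc"]].mean()
        df = pd.concat(
            [df, pd.DataFrame([{"image": "mean", **mean.to_dict()}])],
            ignore_index=True,
        )
    return df
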