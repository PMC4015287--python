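"""ROC/AUC evaluation and method comparison.

AUC is used as the single accuracy measure: it summarises ranking quality
over all thresholds and equals the probability that a random true
interaction outscores a random non-interaction (with half credit for
ties).  ``compare_methods`` evaluates several named score vectors against
one validated positive/negative test set and reports a ranked table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .score_data import LabeledTestSet, PUDataset

__all__ = ["RocResult", "UndefinedAUCError", "roc_auc", "compare_methods"]


class UndefinedAUCError(ValueError):
    """Truth vector contains a single class; the ROC curve is undefined."""


@dataclass
class RocResult:
    """One ROC curve: descending thresholds, FPR/TPR arrays and the AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_auc(scores, truth) -> RocResult:
    """ROC curve and trapezoidal AUC; ties earn half steps.

    Equivalent to ``P(score_pos > score_neg) + 0.5 * P(score_pos == score_neg)``
    over all positive/negative pairs.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValueError("scores and truth must be 1-D vectors of equal length")
    n_pos = int(truth.sum())
    if n_pos == 0 or n_pos == truth.size:
        raise UndefinedAUCError(
            f"need both classes in truth (got {n_pos} positives of {truth.size})"
        )
    fpr, tpr, thr = roc_curve(truth.astype(int), scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def compare_methods(
    data: PUDataset,
    test: LabeledTestSet,
    methods: dict[str, np.ndarray],
) -> tuple[pd.DataFrame, dict[str, RocResult]]:
    """AUC of each method's score vector on a validated test set.

    Each method supplies one score per row of ``data.table``.  Test pairs
    the table does not score receive that method's minimum score (they
    were "not predicted"); the count of such pairs is reported per method.

    Returns
    -------
    (table, curves)
        A DataFrame with columns (method, auc, n_test, n_unscored), sorted
        by descending AUC, and the full ROC curve per method.
    """
    if len(test) == 0:
        raise ValueError("empty test set")
    idx = np.array(
        [data.table.row_index(k) if k in data.table else -1 for k in test.keys]
    )
    if (idx < 0).all():
        raise ValueError("no test key is present in the score table")
    rows, curves = [], {}
    for name, scores in methods.items():
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (data.table.n_rows,):
            raise ValueError(
                f"method {name!r}: expected {data.table.n_rows} scores, "
                f"got shape {scores.shape}"
            )
        s = np.where(idx >= 0, scores[np.clip(idx, 0, None)], scores.min())
        res = roc_auc(s, test.truth)
        curves[name] = res
        rows.append(
            {
                "method": name,
                "auc": res.auc,
                "n_test": len(test),
                "n_unscored": int((idx < 0).sum()),
            }
        )
    table = pd.DataFrame(rows).sort_values("auc", ascending=False, ignore_index=True)
    return table, curves
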