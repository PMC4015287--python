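"""Score-averaging baseline combiners.

Three simple combiners against which the PU ensemble is compared:

- **SA** — score averaging: the unweighted mean of all algorithm columns.
- **SA-3B** — the unweighted mean of a named "best three" subset
  (historically TargetScan Conserved, PITA Top Targets and picTar 5-way).
- **WSA-3B** — a weighted mean of the same subset, with user-supplied
  nonnegative weights summing to one (reliability-derived in the original
  comparison).

All combiners consume standardized, higher-is-stronger scores; absent
entries contribute the table's fill value (the column mean under the
default policy), or can be dropped per row with ``renormalize``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .score_data import ScoreTable

__all__ = ["CombinerMode", "CombinerSpec", "combine_scores"]


class CombinerMode(str, Enum):
    SA = "sa"
    SA_3B = "sa3b"
    WSA_3B = "wsa3b"


@dataclass
class CombinerSpec:
    """Which columns to combine and with what weights."""

    mode: CombinerMode
    selected_columns: list[str] | None = None
    weights: list[float] | None = None
    renormalize: bool = False  # drop absent cells and renormalize per row

    def __post_init__(self):
        self.mode = CombinerMode(self.mode)
        if self.mode is CombinerMode.SA:
            if self.selected_columns is not None or self.weights is not None:
                raise ValueError("SA uses all columns with equal weight; no selection")
        else:
            if not self.selected_columns:
                raise ValueError(f"{self.mode.value} requires selected_columns")
        if self.mode is CombinerMode.WSA_3B:
            if self.weights is None or len(self.weights) != len(self.selected_columns):
                raise ValueError("wsa3b needs one weight per selected column")
            w = np.asarray(self.weights, dtype=float)
            if (w < 0).any():
                raise ValueError("weights must be nonnegative")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
        elif self.weights is not None:
            raise ValueError("weights are only meaningful for wsa3b")


def combine_scores(table: ScoreTable, spec: CombinerSpec) -> np.ndarray:
    """Per-row (weighted) mean of the selected score columns."""
    if spec.mode is CombinerMode.SA:
        cols = list(range(table.n_algorithms))
        w = np.full(len(cols), 1.0 / len(cols))
    else:
        missing = [c for c in spec.selected_columns if c not in table.algorithm_names]
        if missing:
            raise ValueError(f"columns not in table: {missing}")
        cols = [table.algorithm_names.index(c) for c in spec.selected_columns]
        if spec.mode is CombinerMode.SA_3B:
            w = np.full(len(cols), 1.0 / len(cols))
        else:
            w = np.asarray(spec.weights, dtype=float)
    S = table.scores[:, cols]
    if spec.renormalize:
        M = table.present[:, cols].astype(float)
        denom = M @ w
        out = (S * M) @ w
        np.divide(out, denom, out=out, where=denom > 0)
        out[denom == 0] = 0.0
        return out
    return S @ w
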