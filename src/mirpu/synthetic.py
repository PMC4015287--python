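"""Synthetic PU score-table generator with known ground truth.

Emulates the statistical structure of an integrated miRNA-target
prediction database as the PU learner sees it:

- ``s_informative`` partially redundant score columns: equicorrelated
  Gaussian noise (pairwise correlation ``collinearity``) plus a mean shift
  of ``effect`` standard deviations for true interactions;
- ``s_noise`` columns carrying no signal;
- per-algorithm missingness: each cell is reported with probability
  ``1 - missing_rate`` independently (optionally likelier to be absent for
  non-interactions, since predictors only publish putative targets);
- SCAR labeling: each true interaction is labeled (validated) with a
  fixed probability ``label_freq``, independent of its scores, so the
  labeling constant c is known exactly.

The hidden truth vector is returned for evaluation only; learners never
see it.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace

import numpy as np

from .score_data import (
    InteractionKey,
    PUDataset,
    LabeledTestSet,
    ScoreTable,
    write_positives,
    write_score_table,
    write_test_set,
)

__all__ = ["SyntheticSpec", "generate", "make_benchmark", "PRESETS"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; defaults give the standard benchmark regime."""

    n_pos: int = 2500
    n_neg: int = 47500
    s_informative: int = 6
    s_noise: int = 4
    collinearity: float = 0.3
    effect: float = 3.0
    missing_rate: float | tuple = 0.2
    label_freq: float = 0.5
    seed: int = 0
    informative_missingness: bool = False
    distort: bool = False

    def __post_init__(self):
        if self.n_pos < 1 or self.s_informative < 1:
            raise ValueError("need n_pos >= 1 and s_informative >= 1")
        s = self.s_informative
        if self.collinearity >= 1.0 or (s > 1 and self.collinearity < -1.0 / (s - 1)):
            raise ValueError(
                f"equicorrelation {self.collinearity} infeasible for {s} columns "
                f"(must lie in [-1/(s-1), 1))"
            )
        if self.collinearity < 0:
            raise ValueError("negative equicorrelation is not supported by the generator")
        if not 0.0 < self.label_freq <= 1.0:
            raise ValueError("label_freq must lie in (0, 1]")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")

    @property
    def s_total(self) -> int:
        return self.s_informative + self.s_noise


def _missing_rates(spec: SyntheticSpec) -> np.ndarray:
    r = np.asarray(spec.missing_rate, dtype=float)
    if r.ndim == 0:
        r = np.full(spec.s_total, float(r))
    if r.shape != (spec.s_total,):
        raise ValueError("missing_rate must be a scalar or one rate per column")
    if (r < 0).any() or (r >= 1).any():
        raise ValueError("missing rates must lie in [0, 1)")
    return r


def _monotone_distortion(x: np.ndarray, j: int) -> np.ndarray:
    # strictly increasing, column-dependent; AUC-based evaluation is
    # invariant to it, score magnitudes are not
    a = 0.2 + 0.1 * (j % 3)
    return x + a * x**3


def generate(spec: SyntheticSpec) -> tuple[PUDataset, np.ndarray, float]:
    """Draw one PU dataset.

    Returns
    -------
    (dataset, truth, true_c)
        The PU dataset (raw, unstandardized scores), the hidden truth
        vector ``f(x)`` and the true labeling constant (= ``label_freq``).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_pos + spec.n_neg
    truth = np.zeros(n, dtype=bool)
    truth[rng.permutation(n)[: spec.n_pos]] = True

    rho = spec.collinearity
    common = rng.standard_normal(n)
    X = np.empty((n, spec.s_total))
    for j in range(spec.s_informative):
        X[:, j] = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * rng.standard_normal(n)
    X[:, : spec.s_informative] += spec.effect * truth[:, None]
    for j in range(spec.s_informative, spec.s_total):
        X[:, j] = rng.standard_normal(n)
    if spec.distort:
        for j in range(spec.s_total):
            X[:, j] = _monotone_distortion(X[:, j], j)

    rates = _missing_rates(spec)
    if spec.informative_missingness:
        # predictors preferentially report putative targets: absence is
        # likelier for non-interactions
        rate_matrix = np.where(
            truth[:, None], 0.5 * rates[None, :], np.minimum(1.25 * rates[None, :], 0.95)
        )
    else:
        rate_matrix = np.broadcast_to(rates[None, :], (n, spec.s_total))
    present = rng.random((n, spec.s_total)) >= rate_matrix
    # every row must keep at least one reported score
    empty = ~present.any(axis=1)
    if empty.any():
        cols = rng.integers(0, spec.s_total, size=int(empty.sum()))
        present[np.flatnonzero(empty), cols] = True

    labeled = truth & (rng.random(n) < spec.label_freq)

    keys = [
        InteractionKey(f"miR-{rng_id % 600:04d}", f"GENE{rng_id:07d}")
        for rng_id in range(n)
    ]
    scores = X.copy()
    for j in range(spec.s_total):
        m = present[:, j]
        fill = scores[m, j].mean() if m.any() else 0.0
        scores[~m, j] = fill
    table = ScoreTable(
        keys,
        [f"alg{j + 1:02d}" for j in range(spec.s_total)],
        scores,
        present,
        missing_policy="mean",
    )
    return PUDataset(table, labeled), truth, spec.label_freq


#: Benchmark presets: (spec overrides, n_test_pos, n_test_neg).
PRESETS: dict[str, tuple[dict, int, int]] = {
    "tiny": (
        dict(n_pos=200, n_neg=1800, s_informative=4, s_noise=2),
        60,
        120,
    ),
    "default": (dict(), 1000, 1000),
    "imbalanced": (
        # |L| = 0.5*500 = 250 vs |U| ~ 500,250: the ~1/2000 regime of a
        # full integrated prediction database
        dict(n_pos=500, n_neg=500_000),
        200,
        400,
    ),
}


def benchmark_split(
    data: PUDataset, truth: np.ndarray, n_test_pos: int, n_test_neg: int, seed: int
) -> LabeledTestSet:
    """Carve a validated test set out of the unlabeled rows.

    Test positives are *unlabeled* true interactions (training positives
    are excluded, mirroring the removal of training-set pairs from an
    independent validation database); test negatives are non-interactions.
    The test rows stay inside the score table — and hence inside U during
    training — matching the setting where the validation pairs are a
    subset of the predicted universe.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(17,)))
    pos_pool = np.flatnonzero(truth & ~data.labeled)
    neg_pool = np.flatnonzero(~truth)
    if pos_pool.size < n_test_pos or neg_pool.size < n_test_neg:
        raise ValueError("not enough unlabeled positives/negatives for the test split")
    pos = rng.choice(pos_pool, size=n_test_pos, replace=False)
    neg = rng.choice(neg_pool, size=n_test_neg, replace=False)
    idx = np.concatenate([pos, neg])
    keys = [data.table.keys[i] for i in idx]
    t = np.concatenate([np.ones(n_test_pos, bool), np.zeros(n_test_neg, bool)])
    return LabeledTestSet(keys, t)


def make_benchmark(preset: str, seed: int, out_dir) -> dict[str, str]:
    """Write one benchmark to disk: scores, positives, test set, truth.

    Files (TSV): ``scores.tsv`` (empty cell = missing), ``positives.tsv``
    (labeled pairs), ``test.tsv`` (validated positives and negatives),
    ``truth.tsv`` (hidden ground truth — for evaluation only) and
    ``spec.json`` (the resolved generator parameters).
    Byte-identical for the same preset and seed.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {sorted(PRESETS)}")
    overrides, n_test_pos, n_test_neg = PRESETS[preset]
    spec = replace(SyntheticSpec(seed=seed), **overrides)
    data, truth, true_c = generate(spec)
    test = benchmark_split(data, truth, n_test_pos, n_test_neg, seed)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "scores": os.path.join(out_dir, "scores.tsv"),
        "positives": os.path.join(out_dir, "positives.tsv"),
        "test": os.path.join(out_dir, "test.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "spec": os.path.join(out_dir, "spec.json"),
    }
    write_score_table(data.table, paths["scores"])
    write_positives([data.table.keys[i] for i in data.labeled_indices], paths["positives"])
    write_test_set(test, paths["test"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("mirna\tmrna\ttruth\n")
        for k, t in zip(data.table.keys, truth):
            fh.write(f"{k.mirna_id}\t{k.mrna_id}\t{1 if t else 0}\n")
    with open(paths["spec"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "preset": preset,
                "true_c": true_c,
                "n_test_pos": n_test_pos,
                "n_test_neg": n_test_neg,
                **{k: getattr(spec, k) for k in spec.__dataclass_fields__},
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
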