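"""Data model and I/O for miRNA:mRNA interaction score tables.

An interaction is a pair ``x = <m, g>`` of a miRNA and a candidate target
mRNA.  Each of ``s`` target-prediction algorithms may report a numeric score
``p_k(x)`` for the pair; the vector ``p(x)`` of per-algorithm scores is the
feature representation every learner in this package consumes.  Because each
algorithm scores only a subset of all pairs, the table carries an explicit
presence mask alongside the (filled) score matrix.

Labels are positive-only: a pair is either *labeled* (experimentally
validated, ``l(x) = 1``) or *unlabeled*; no verified negatives exist at
training time.  :class:`PUDataset` bundles a :class:`ScoreTable` with that
indicator.  A :class:`LabeledTestSet` (validated positives *and* negatives)
is used for evaluation only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InteractionKey",
    "ScoreTable",
    "PUDataset",
    "LabeledTestSet",
    "ScoreTableFormatError",
    "DuplicateKeyError",
    "ScoreParseError",
    "MISSING_POLICIES",
    "load_score_table",
    "write_score_table",
    "standardize_scores",
    "assemble_pu_dataset",
    "load_positives",
    "write_positives",
    "load_test_set",
    "write_test_set",
]


class ScoreTableFormatError(ValueError):
    """Malformed score-table header or row."""


class DuplicateKeyError(ValueError):
    """The same (mirna, mrna) pair appears more than once."""


class ScoreParseError(ValueError):
    """A score cell could not be parsed as a number."""


class InteractionKey(NamedTuple):
    """One candidate miRNA:mRNA interaction, identified by its two ids.

    Identifiers are opaque, case-sensitive strings; no alias resolution or
    case folding is performed (silently merging distinct transcripts is
    worse than keeping near-duplicates apart).
    """

    mirna_id: str
    mrna_id: str

    def validate(self) -> "InteractionKey":
        if not self.mirna_id or not self.mrna_id:
            raise ValueError("InteractionKey ids must be non-empty strings")
        return self


#: Recognised fill policies for absent scores.
#:
#: - ``"mean"`` (default): absent cells hold the column mean of the present
#:   values, which becomes exactly 0 after standardization — "no evidence".
#: - ``"min"``: absent cells hold the column minimum — "weakest evidence".
#: - ``"zero-raw"``: absent cells hold a literal 0.0 on the raw scale.
MISSING_POLICIES = ("mean", "min", "zero-raw")


def _fill_value(col: np.ndarray, present: np.ndarray, policy: str) -> float:
    vals = col[present]
    if policy == "mean":
        return float(vals.mean()) if vals.size else 0.0
    if policy == "min":
        return float(vals.min()) if vals.size else 0.0
    if policy == "zero-raw":
        return 0.0
    raise ValueError(f"unknown missing policy {policy!r}; expected one of {MISSING_POLICIES}")


@dataclass
class ScoreTable:
    """Matrix of per-algorithm prediction scores with a missingness mask.

    Parameters
    ----------
    keys
        Ordered, duplicate-free list of interactions (the rows).
    algorithm_names
        Ordered list of the ``s`` score columns.
    scores
        ``(len(keys), s)`` float matrix.  Where ``present`` is False the
        stored value is the fill implied by ``missing_policy``.
    present
        Boolean mask, True where the algorithm actually reported a score.
    missing_policy
        One of :data:`MISSING_POLICIES`.
    standardized
        True once :func:`standardize_scores` has been applied.
    """

    keys: list[InteractionKey]
    algorithm_names: list[str]
    scores: np.ndarray
    present: np.ndarray
    missing_policy: str = "mean"
    standardized: bool = False
    _index: dict[InteractionKey, int] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        n, s = self.scores.shape
        if s < 1:
            raise ScoreTableFormatError("a ScoreTable needs at least one algorithm column")
        if len(self.keys) != n or self.present.shape != (n, s):
            raise ValueError("keys / scores / present shapes are inconsistent")
        if len(self.algorithm_names) != s:
            raise ValueError("algorithm_names length does not match score columns")
        if self._index is None:
            self._index = {}
            for i, k in enumerate(self.keys):
                if k in self._index:
                    raise DuplicateKeyError(f"duplicate interaction {k.mirna_id}:{k.mrna_id}")
                self._index[k] = i
        if n and not self.present.any(axis=1).all():
            bad = int(np.flatnonzero(~self.present.any(axis=1))[0])
            k = self.keys[bad]
            raise ScoreTableFormatError(
                f"row {k.mirna_id}:{k.mrna_id} has no present score in any column"
            )

    @property
    def n_rows(self) -> int:
        return len(self.keys)

    @property
    def n_algorithms(self) -> int:
        return len(self.algorithm_names)

    def row_index(self, key: InteractionKey) -> int:
        return self._index[key]

    def __contains__(self, key: InteractionKey) -> bool:
        return key in self._index

    def to_dataframe(self) -> pd.DataFrame:
        """Scores as a DataFrame (absent cells as NaN) indexed by (mirna, mrna)."""
        idx = pd.MultiIndex.from_tuples(self.keys, names=["mirna", "mrna"])
        vals = self.scores.copy()
        vals[~self.present] = np.nan
        return pd.DataFrame(vals, index=idx, columns=list(self.algorithm_names))


def load_score_table(
    path,
    missing_policy: str = "mean",
    invert: Sequence[str] = (),
) -> ScoreTable:
    """Read a TSV score table: header ``mirna<TAB>mrna<TAB><alg>...``.

    Empty cells denote missing scores.  Columns named in ``invert`` are
    negated on load, so that after loading every column obeys the
    "higher score = stronger evidence" orientation the learners require.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "mirna" or cols[1] != "mrna":
        raise ScoreTableFormatError(
            f"expected header 'mirna\\tmrna\\t<alg>...', got {cols[:3]!r}..."
        )
    alg_names = cols[2:]
    unknown = set(invert) - set(alg_names)
    if unknown:
        raise ValueError(f"invert names not in table: {sorted(unknown)}")
    keys = [
        InteractionKey(m, g).validate()
        for m, g in zip(df["mirna"].tolist(), df["mrna"].tolist())
    ]
    raw = df[alg_names].to_numpy(dtype=object)
    present = np.array([[cell != "" for cell in row] for row in raw], dtype=bool)
    scores = np.zeros(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            if present[i, j]:
                try:
                    scores[i, j] = float(raw[i, j])
                except ValueError as exc:
                    raise ScoreParseError(
                        f"non-numeric score {raw[i, j]!r} at row {i + 1} "
                        f"({keys[i].mirna_id}:{keys[i].mrna_id}), column {alg_names[j]!r}"
                    ) from exc
    for name in invert:
        scores[:, alg_names.index(name)] *= -1.0
    for j in range(scores.shape[1]):
        fv = _fill_value(scores[:, j], present[:, j], missing_policy)
        scores[~present[:, j], j] = fv
    return ScoreTable(keys, alg_names, scores, present, missing_policy=missing_policy)


def write_score_table(table: ScoreTable, path) -> None:
    """Write a ScoreTable back to TSV (absent cells as empty strings)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna\tmrna\t" + "\t".join(table.algorithm_names) + "\n")
        for i, k in enumerate(table.keys):
            cells = [
                repr(float(table.scores[i, j])) if table.present[i, j] else ""
                for j in range(table.n_algorithms)
            ]
            fh.write(f"{k.mirna_id}\t{k.mrna_id}\t" + "\t".join(cells) + "\n")


def standardize_scores(table: ScoreTable) -> ScoreTable:
    """Z-score each column over its *present* values (population std).

    Absent cells are refilled per the table's missing policy on the new
    scale (the default "mean" policy therefore fills exactly 0).  Columns
    with fewer than two present values or zero spread pass through
    unchanged with a warning.
    """
    scores = table.scores.copy()
    for j, name in enumerate(table.algorithm_names):
        mask = table.present[:, j]
        vals = scores[mask, j]
        if vals.size < 2 or np.ptp(vals) == 0.0:
            warnings.warn(
                f"column {name!r} has no spread ({vals.size} present values); "
                "left unstandardized",
                stacklevel=2,
            )
            continue
        mu = vals.mean()
        sd = vals.std()  # population std
        scores[mask, j] = (vals - mu) / sd
        if table.missing_policy == "zero-raw":
            fv = (0.0 - mu) / sd
        else:
            fv = _fill_value(scores[:, j], mask, table.missing_policy)
        scores[~mask, j] = fv
    return replace(table, scores=scores, standardized=True, _index=table._index)


@dataclass
class PUDataset:
    """A score table plus the positive-only label indicator ``l(x)``.

    ``L`` (labeled rows) and ``U`` (unlabeled rows) partition the table.
    """

    table: ScoreTable
    labeled: np.ndarray

    def __post_init__(self):
        self.labeled = np.asarray(self.labeled, dtype=bool)
        if self.labeled.shape != (self.table.n_rows,):
            raise ValueError("labeled vector length must match table rows")

    @property
    def labeled_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labeled)

    @property
    def unlabeled_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.labeled)

    @property
    def n_labeled(self) -> int:
        return int(self.labeled.sum())

    @property
    def n_unlabeled(self) -> int:
        return int((~self.labeled).sum())

    @property
    def X(self) -> np.ndarray:
        return self.table.scores


def assemble_pu_dataset(
    table: ScoreTable, positives: Iterable[InteractionKey]
) -> tuple[PUDataset, list[InteractionKey]]:
    """Mark table rows found in ``positives`` as labeled.

    Mirrors the construction "validated interactions are the labeled set;
    predicted-but-unvalidated interactions are unlabeled".  Positives not
    present in the table are returned (not an error: validation databases
    routinely contain pairs outside any predictor's coverage).

    Returns
    -------
    (dataset, unmatched)
        The PU dataset and the list of positive keys absent from the table.
    """
    labeled = np.zeros(table.n_rows, dtype=bool)
    unmatched: list[InteractionKey] = []
    seen = set()
    for key in positives:
        key = InteractionKey(*key)
        if key in seen:
            continue
        seen.add(key)
        if key in table:
            labeled[table.row_index(key)] = True
        else:
            unmatched.append(key)
    return PUDataset(table, labeled), unmatched


def load_positives(path) -> list[InteractionKey]:
    """Read a two-column ``mirna<TAB>mrna`` positive-pair list."""
    out: list[InteractionKey] = []
    with open(path, encoding="utf-8") as fh:
        first = True
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ScoreTableFormatError(f"expected 2 columns, got {len(parts)}: {line!r}")
            if first and parts == ["mirna", "mrna"]:
                first = False
                continue
            first = False
            out.append(InteractionKey(parts[0], parts[1]).validate())
    return out


def write_positives(keys: Iterable[InteractionKey], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna\tmrna\n")
        for k in keys:
            fh.write(f"{k.mirna_id}\t{k.mrna_id}\n")


@dataclass
class LabeledTestSet:
    """Validated positive *and* negative pairs, for held-out evaluation."""

    keys: list[InteractionKey]
    truth: np.ndarray
    n_inconsistent_removed: int = 0
    n_excluded: int = 0

    def __post_init__(self):
        self.truth = np.asarray(self.truth, dtype=bool)
        if self.truth.shape != (len(self.keys),):
            raise ValueError("truth vector length must match keys")
        if len(set(self.keys)) != len(self.keys):
            raise DuplicateKeyError("LabeledTestSet keys must be unique")

    def __len__(self) -> int:
        return len(self.keys)


def load_test_set(path, exclude: Iterable[InteractionKey] = ()) -> LabeledTestSet:
    """Read a ``mirna<TAB>mrna<TAB>label`` test set, label in {1, 0}.

    Pairs listed with *both* labels are inconsistent and dropped (their
    count is recorded on the result).  Keys in ``exclude`` — typically the
    training positives — are removed before returning, so the test set
    cannot reward a method for memorising its training labels.
    """
    labels: dict[InteractionKey, set[bool]] = {}
    order: list[InteractionKey] = []
    with open(path, encoding="utf-8") as fh:
        first = True
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ScoreTableFormatError(
                    f"line {lineno}: expected 3 columns, got {len(parts)}"
                )
            if first and parts == ["mirna", "mrna", "label"]:
                first = False
                continue
            first = False
            if parts[2] not in ("0", "1"):
                raise ScoreParseError(f"line {lineno}: unknown label token {parts[2]!r}")
            key = InteractionKey(parts[0], parts[1]).validate()
            if key not in labels:
                labels[key] = set()
                order.append(key)
            labels[key].add(parts[2] == "1")
    inconsistent = {k for k, v in labels.items() if len(v) > 1}
    excl = {InteractionKey(*k) for k in exclude}
    keys, truth = [], []
    n_excluded = 0
    for k in order:
        if k in inconsistent:
            continue
        if k in excl:
            n_excluded += 1
            continue
        keys.append(k)
        truth.append(next(iter(labels[k])))
    return LabeledTestSet(
        keys,
        np.asarray(truth, dtype=bool),
        n_inconsistent_removed=len(inconsistent),
        n_excluded=n_excluded,
    )


def write_test_set(test: LabeledTestSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna\tmrna\tlabel\n")
        for k, t in zip(test.keys, test.truth):
            fh.write(f"{k.mirna_id}\t{k.mrna_id}\t{1 if t else 0}\n")
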