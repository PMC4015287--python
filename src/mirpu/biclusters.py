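"""Quality metrics for miRNA:mRNA biclusters.

A bicluster is a pair (set of miRNAs, set of mRNAs) proposed as a
co-regulation module by a downstream biclustering step.  Two families of
measures are implemented:

- **cohesiveness** q(C, A): the mean interaction score over all
  miRNA x mRNA cross pairs of the bicluster — the weighted percentage of
  realised interactions, normalised by the maximum possible number — and
  its size-weighted average over a hierarchy level;
- **functional-similarity statistics**: the mean pairwise gene similarity
  among a bicluster's mRNAs (intra), the mean similarity between the
  exclusive mRNA sets of bicluster pairs (inter), and a Welch two-sample
  t-test of intra vs inter, whose one-sided p-value measures how much more
  functionally coherent genes are within biclusters than across them.

Gene similarity is a pluggable symmetric function in [0, 1] with
sim(x, x) = 1 (a GO-based semantic similarity in real analyses);
:class:`SyntheticGeneSimilarity` is a module-structured synthetic stand-in.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy import stats

from .score_data import ScoreTable

__all__ = [
    "Bicluster",
    "BiclusterLevel",
    "PairScores",
    "SyntheticGeneSimilarity",
    "cohesiveness",
    "avg_cohesiveness",
    "intra_similarity",
    "inter_similarity",
    "level_ttest",
    "load_bicluster_levels",
]

#: A gene-similarity function: symmetric, in [0, 1], sim(x, x) = 1.
GeneSimilarity = Callable[[str, str], float]


@dataclass(frozen=True)
class Bicluster:
    """One candidate co-regulation module."""

    mirnas: frozenset[str]
    mrnas: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "mirnas", frozenset(self.mirnas))
        object.__setattr__(self, "mrnas", frozenset(self.mrnas))
        if not self.mirnas or not self.mrnas:
            raise ValueError("both sides of a bicluster must be non-empty")

    @property
    def size(self) -> int:
        return len(self.mirnas) + len(self.mrnas)


class PairScores:
    """Interaction-score accessor ``A(x, y)`` backed by a mapping or ScoreTable.

    Unresolvable pairs score 0 (no evidence of interaction) and are
    counted in ``n_unresolved``.  ``normalize=True`` min-max rescales the
    provided scores into [0, 1], as cohesiveness expects.
    """

    def __init__(
        self,
        source: Mapping[tuple[str, str], float] | ScoreTable,
        column: str | None = None,
        normalize: bool = False,
    ):
        if isinstance(source, ScoreTable):
            if column is None:
                raise ValueError("a score column name is required with a ScoreTable")
            j = source.algorithm_names.index(column)
            pairs = {
                (k.mirna_id, k.mrna_id): float(source.scores[i, j])
                for i, k in enumerate(source.keys)
                if source.present[i, j]
            }
        else:
            pairs = {k: float(v) for k, v in source.items()}
        if normalize and pairs:
            vals = np.array(list(pairs.values()))
            lo, hi = vals.min(), vals.max()
            if hi > lo:
                pairs = {k: (v - lo) / (hi - lo) for k, v in pairs.items()}
            else:
                pairs = {k: 1.0 for k in pairs}
        self._pairs = pairs
        self.n_unresolved = 0

    def __call__(self, mirna: str, mrna: str) -> float:
        try:
            return self._pairs[(mirna, mrna)]
        except KeyError:
            self.n_unresolved += 1
            return 0.0


@dataclass
class BiclusterLevel:
    """The biclusters of one hierarchy level plus their score accessor."""

    biclusters: list[Bicluster]
    scores: PairScores

    def __post_init__(self):
        if not self.biclusters:
            raise ValueError("a level needs at least one bicluster")


def cohesiveness(c: Bicluster, a: Callable[[str, str], float]) -> float:
    """q(C, A): mean interaction score over all miRNA x mRNA cross pairs."""
    total = sum(a(x, y) for x in c.mirnas for y in c.mrnas)
    return total / (len(c.mirnas) * len(c.mrnas))


def avg_cohesiveness(level: BiclusterLevel) -> float:
    """Size-weighted mean cohesiveness over the level's biclusters."""
    sizes = np.array([c.size for c in level.biclusters], dtype=float)
    qs = np.array([cohesiveness(c, level.scores) for c in level.biclusters])
    return float((sizes * qs).sum() / sizes.sum())


def intra_similarity(c: Bicluster, sim: GeneSimilarity) -> float:
    """Mean gene similarity over distinct mRNA pairs within one bicluster.

    Defined over ordered pairs; by symmetry of ``sim`` the unordered mean
    is identical, so unordered pairs are enumerated.  Undefined for fewer
    than two mRNAs.
    """
    genes = sorted(c.mrnas)
    if len(genes) < 2:
        raise ValueError("intra-similarity needs at least two mRNAs")
    vals = [
        sim(g1, g2) for i, g1 in enumerate(genes) for g2 in genes[i + 1 :]
    ]
    return float(np.mean(vals))


def _pair_inter(c1: Bicluster, c2: Bicluster, sim: GeneSimilarity) -> float | None:
    """Mean similarity between the exclusive mRNA sets of two biclusters.

    None when either exclusive set is empty (e.g. nested biclusters): the
    pair carries no between-module contrast and is skipped rather than
    counted as 0, which would spuriously deflate the inter average.
    """
    only1 = sorted(c1.mrnas - c2.mrnas)
    only2 = sorted(c2.mrnas - c1.mrnas)
    if not only1 or not only2:
        return None
    return float(np.mean([sim(x1, x2) for x1 in only1 for x2 in only2]))


def inter_similarity(level: BiclusterLevel, sim: GeneSimilarity) -> float:
    """Mean over bicluster pairs of the exclusive-set similarity means.

    Written over ordered pairs of distinct biclusters; symmetric in the
    two biclusters, so unordered pairs are enumerated.
    """
    vals, _ = _inter_sample(level, sim)
    if not vals:
        raise ValueError("no bicluster pair with non-empty exclusive mRNA sets")
    return float(np.mean(vals))


def _inter_sample(level: BiclusterLevel, sim: GeneSimilarity) -> tuple[list[float], int]:
    bcs = level.biclusters
    if len(bcs) < 2:
        raise ValueError("inter-similarity needs at least two biclusters")
    vals, skipped = [], 0
    for i, c1 in enumerate(bcs):
        for c2 in bcs[i + 1 :]:
            v = _pair_inter(c1, c2, sim)
            if v is None:
                skipped += 1
            else:
                vals.append(v)
    return vals, skipped


def level_ttest(
    level: BiclusterLevel,
    sim: GeneSimilarity,
    pooled_intra: bool = False,
) -> dict:
    """Welch two-sample t-test of intra- vs inter-bicluster similarity.

    The intra sample holds one mean per bicluster with >= 2 mRNAs (or,
    with ``pooled_intra=True``, every within-bicluster gene-pair
    similarity); the inter sample holds one mean per bicluster pair with
    non-empty exclusive mRNA sets.  Reports the t statistic, the
    two-sided p-value and the one-sided p-value for the alternative
    "intra exceeds inter" — the smaller it is, the more functionally
    coherent the biclusters are relative to their surroundings.
    """
    intra, n_skipped_small = [], 0
    for c in level.biclusters:
        if len(c.mrnas) < 2:
            n_skipped_small += 1
            continue
        if pooled_intra:
            genes = sorted(c.mrnas)
            intra.extend(
                sim(g1, g2) for i, g1 in enumerate(genes) for g2 in genes[i + 1 :]
            )
        else:
            intra.append(intra_similarity(c, sim))
    inter, n_skipped_pairs = _inter_sample(level, sim)
    intra_a, inter_a = np.asarray(intra), np.asarray(inter)
    if len(intra) < 2 or len(inter) < 1:
        raise ValueError(
            f"degenerate samples: {len(intra)} intra, {len(inter)} inter values"
        )
    if intra_a.std() == 0 and inter_a.std() == 0:
        if intra_a.size and inter_a.size and intra_a[0] == inter_a[0]:
            t, p_two = 0.0, 1.0
        else:
            raise ValueError("zero variance in both samples; t-test undefined")
    else:
        t, p_two = stats.ttest_ind(intra_a, inter_a, equal_var=False)
        t, p_two = float(t), float(p_two)
    p_one = p_two / 2.0 if t > 0 else 1.0 - p_two / 2.0
    return {
        "t": t,
        "p_two_sided": p_two,
        "p_one_sided": p_one,
        "n_intra": len(intra),
        "n_inter": len(inter),
        "mean_intra": float(intra_a.mean()),
        "mean_inter": float(inter_a.mean()),
        "n_biclusters_skipped": n_skipped_small,
        "n_pairs_skipped": n_skipped_pairs,
    }


class SyntheticGeneSimilarity:
    """Module-structured synthetic gene similarity (labelled synthetic stand-in).

    Genes are hashed into ``n_modules`` functional modules; same-module
    pairs score ``beta_in``, cross-module pairs ``beta_out``, plus a small
    symmetric pair-specific jitter.  Identity pairs score exactly 1.
    Deterministic for a given seed; symmetric by construction.
    """

    def __init__(
        self,
        module_of: Mapping[str, int] | None = None,
        n_modules: int = 8,
        beta_in: float = 0.6,
        beta_out: float = 0.2,
        jitter: float = 0.05,
        seed: int = 0,
    ):
        if not 0 <= beta_out <= beta_in <= 1:
            raise ValueError("need 0 <= beta_out <= beta_in <= 1")
        self.module_of = dict(module_of) if module_of is not None else None
        self.n_modules = n_modules
        self.beta_in = beta_in
        self.beta_out = beta_out
        self.jitter = jitter
        self.seed = seed

    @staticmethod
    def _stable_hash(text: str) -> int:
        # process-independent (unlike builtin hash, which is salted)
        return zlib.crc32(text.encode("utf-8"))

    def _module(self, gene: str) -> int:
        if self.module_of is not None:
            return self.module_of[gene]
        h = np.random.SeedSequence(entropy=self.seed, spawn_key=(self._stable_hash(gene),))
        return int(h.generate_state(1)[0] % self.n_modules)

    def __call__(self, g1: str, g2: str) -> float:
        if g1 == g2:
            return 1.0
        base = self.beta_in if self._module(g1) == self._module(g2) else self.beta_out
        if self.jitter == 0:
            return base
        a, b = sorted((g1, g2))
        ss = np.random.SeedSequence(
            entropy=self.seed, spawn_key=(self._stable_hash(a + "\x00" + b), 3)
        )
        u = np.random.default_rng(ss).random()
        return float(np.clip(base + self.jitter * (2 * u - 1), 0.0, 1.0))


def load_bicluster_levels(path, scores: PairScores) -> dict[int, BiclusterLevel]:
    """Read a ``level<TAB>bicluster_id<TAB>kind<TAB>id`` TSV into levels."""
    raw: dict[int, dict[str, dict[str, set]]] = {}
    with open(path, encoding="utf-8") as fh:
        first = True
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"line {lineno}: expected 4 columns")
            if first and parts == ["level", "bicluster_id", "kind", "id"]:
                first = False
                continue
            first = False
            lev, bid, kind, ident = parts
            if kind not in ("miRNA", "mRNA"):
                raise ValueError(f"line {lineno}: kind must be miRNA or mRNA")
            d = raw.setdefault(int(lev), {}).setdefault(bid, {"miRNA": set(), "mRNA": set()})
            d[kind].add(ident)
    out = {}
    for lev, bcs in sorted(raw.items()):
        out[lev] = BiclusterLevel(
            [Bicluster(frozenset(d["miRNA"]), frozenset(d["mRNA"])) for _, d in sorted(bcs.items())],
            scores,
        )
    return out
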