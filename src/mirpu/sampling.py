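"""Closed-form sampling math and sample construction for bagging over U.

With |L| labeled and |U| unlabeled examples at a ratio as extreme as
~1/2000, a single classifier trained on everything degenerates to the
majority class.  The remedy is to train K classifiers, each on all of L
plus a with-replacement sample of n examples drawn from U.  Two parameters
control the scheme: the per-sample size ``n`` and the target coverage
``gamma`` — the fraction of U that should appear in at least one sample.

The probability that a given unlabeled example lands in the union of the
K samples is ``1 - (1 - 1/|U|)^(n*K)``; inverting for K gives the number
of samples needed to reach coverage gamma.  At ``K = |U|/n`` and large
|U| the coverage approaches ``1 - e^-1 = 0.632``, the familiar bootstrap
coverage constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["SamplingPlan", "expected_coverage", "required_samples", "draw_samples"]


def expected_coverage(n: int, k: int, u_size: int) -> float:
    """Probability that a given unlabeled example is in the union of samples.

    ``1 - (1 - 1/u_size)^(n*k)``, computed in log space for precision.
    """
    if u_size < 1:
        raise ValueError("u_size must be >= 1")
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    if u_size == 1:
        return 1.0
    return -math.expm1(n * k * math.log1p(-1.0 / u_size))


def required_samples(n: int, gamma: float, u_size: int) -> int:
    """Number of size-n samples needed to cover a gamma fraction of U.

    Ceil of ``(1/n) * log(1-gamma) / log(1 - 1/u_size)``, floored at 1 so
    coverage never undershoots gamma.  Diverges as gamma -> 1: near-total
    coverage requires an unbounded number of samples, so gamma must
    balance effectiveness against efficiency.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError(
            "gamma must lie strictly in (0,1): coverage 1 requires infinitely "
            "many samples (lim gamma->1 K = +inf)"
        )
    if u_size < 2:
        raise ValueError("u_size must be >= 2")
    if n < 1:
        raise ValueError("n must be >= 1")
    k = math.log1p(-gamma) / (n * math.log1p(-1.0 / u_size))
    return max(1, math.ceil(k - 1e-12))


@dataclass(frozen=True)
class SamplingPlan:
    """Resolved bagging plan: (n, gamma, |U|) with the derived sample count k."""

    n: int
    gamma: float
    u_size: int
    k: int

    @classmethod
    def from_coverage(cls, n: int, gamma: float, u_size: int) -> "SamplingPlan":
        return cls(n=int(n), gamma=gamma, u_size=int(u_size),
                   k=required_samples(int(n), gamma, u_size))

    def __post_init__(self):
        if self.n < 1 or self.k < 1 or self.u_size < 1:
            raise ValueError("n, k and u_size must all be positive")

    @property
    def coverage(self) -> float:
        return expected_coverage(self.n, self.k, self.u_size)


def sample_seeds(master_seed: int, count: int) -> list[np.random.SeedSequence]:
    """Derive per-sample substreams from a master seed.

    Sample j's stream depends only on (master_seed, j), so extending a plan
    with more samples never perturbs earlier ones.
    """
    return [np.random.SeedSequence(entropy=master_seed, spawn_key=(j,)) for j in range(count)]


def draw_samples(u_indices: np.ndarray, plan: SamplingPlan, seed: int) -> list[np.ndarray]:
    """Draw the plan's k with-replacement samples of size n from ``u_indices``.

    Duplicates within a sample are retained (true bootstrap sampling); the
    samples are neither mutually exclusive nor exhaustive.
    """
    u_indices = np.asarray(u_indices)
    if u_indices.size == 0:
        raise ValueError("cannot sample from an empty unlabeled set")
    if u_indices.size != plan.u_size:
        raise ValueError(
            f"plan.u_size={plan.u_size} does not match |u_indices|={u_indices.size}"
        )
    out = []
    for ss in sample_seeds(seed, plan.k):
        rng = np.random.default_rng(ss)
        out.append(u_indices[rng.integers(0, u_indices.size, size=plan.n)])
    return out
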