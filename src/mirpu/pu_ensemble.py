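"""Two-stage bagged positive-unlabeled ensemble learner.

Setting: a table of per-algorithm prediction scores ``p(x)`` for candidate
miRNA:mRNA interactions, of which only a small set L is labeled (validated
positives); everything else, U, is unlabeled — a mixture of unknown
positives and negatives.  The goal is a calibrated probability
``f'(p(x)) ~ P(f(x) = 1)`` that the interaction is real.

Under the "selected completely at random" (SCAR) assumption — validated
positives are a uniform random subset of all positives — the labeling
frequency ``c = P(l(x)=1 | f(x)=1)`` is a constant, and

    P(f(x) = 1) = P(l(x) = 1) / c.

Both quantities are estimated with a *nontraditional* classifier g trained
to separate labeled from unlabeled examples, so that
``g(p(x)) ~ P(l(x)=1)``; c is then the mean of g over the labeled set.
Because L and U are extremely unbalanced (ratios around 1/2000 in real
integrated prediction databases), g is learned as a bagged ensemble: K
classifiers, each trained on all of L plus a with-replacement sample of n
unlabeled examples, with K chosen so the samples jointly cover a target
fraction gamma of U (see :mod:`mirpu.sampling`).

Stage two converts g and c into a posterior for each unlabeled example,

    P(f=1 | l=0) = ((1-c)/c) * g/(1-g),

assigns each row a single training label ('+' if that posterior >= 1/2,
'-' otherwise; labeled rows are always '+') and a confidence weight, and
trains a second bagged ensemble of cost-sensitive classifiers on the
re-labeled, weighted data.  That *traditional* ensemble is the final
predictor f'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import joblib
import numpy as np

from .classifiers import ProbabilisticClassifier, base_factory
from .sampling import SamplingPlan, draw_samples
from .score_data import PUDataset, ScoreTable

__all__ = [
    "InsufficientPositivesError",
    "DegenerateLabelsError",
    "NontraditionalEnsemble",
    "WeightedTrainingSet",
    "PUEnsembleModel",
    "PUEnsemble",
    "PUEnsembleResults",
    "fit_nontraditional",
    "predict_g",
    "estimate_c",
    "posterior_unlabeled",
    "build_weighted_training_set",
    "fit_traditional",
    "predict_f",
]

_C_EPS = 1e-6
_G_EPS = 1e-12


class InsufficientPositivesError(ValueError):
    """Fewer labeled positives than the stage requires."""


class DegenerateLabelsError(ValueError):
    """A training stage received a single-class training set."""


def _member_seed(master: int, j: int, stage: int) -> int:
    """Deterministic per-member seed; member j is independent of k."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(stage, j))
    return int(ss.generate_state(1)[0] % (2**31))


def _stage_seeds(master: int) -> tuple[int, int]:
    s = np.random.SeedSequence(master).generate_state(2) % (2**31)
    return int(s[0]), int(s[1])


def _member_matrix(members: Sequence[ProbabilisticClassifier], X: np.ndarray) -> np.ndarray:
    """(k, m) matrix of member probabilities for the rows of X."""
    return np.vstack([m.predict_prob(X) for m in members])


def _membership_average(P: np.ndarray, memberships: np.ndarray | None) -> np.ndarray:
    """Average member predictions; membership-aware where membership exists.

    Rows contained in at least one sample average only over the members
    that saw them; all other rows average over every member.
    """
    if memberships is None:
        return P.mean(axis=0)
    W = memberships.astype(float)
    counts = W.sum(axis=0)
    out = P.mean(axis=0)
    covered = counts > 0
    with np.errstate(invalid="ignore"):
        out[covered] = (P * W).sum(axis=0)[covered] / counts[covered]
    return out


# ---------------------------------------------------------------------------
# Stage 1: the nontraditional ensemble g(.)
# ---------------------------------------------------------------------------


@dataclass
class NontraditionalEnsemble:
    """K classifiers separating labeled from unlabeled, plus the constant c.

    ``memberships[j, i]`` is True when training row i was drawn into the
    j-th unlabeled sample (defined for unlabeled rows only).
    """

    members: list
    memberships: np.ndarray
    plan: SamplingPlan
    n_features: int
    g_train: np.ndarray
    c_hat: float = field(default=np.nan)

    @property
    def k(self) -> int:
        return len(self.members)


def fit_nontraditional(
    data: PUDataset,
    plan: SamplingPlan,
    base: Callable[[int], ProbabilisticClassifier],
    seed: int,
) -> NontraditionalEnsemble:
    """Train the K-member labeled-vs-unlabeled ensemble and estimate c.

    Each member j is trained on all of L (class 1) together with the j-th
    with-replacement sample of n unlabeled rows (class 0).
    """
    L = data.labeled_indices
    U = data.unlabeled_indices
    if L.size < 2:
        raise InsufficientPositivesError(
            f"need at least 2 labeled positives, got {L.size}"
        )
    if plan.u_size != U.size:
        raise ValueError(f"plan.u_size={plan.u_size} but |U|={U.size}")
    X = data.X
    samples = draw_samples(U, plan, seed)
    members = []
    memberships = np.zeros((plan.k, data.table.n_rows), dtype=bool)
    y = np.concatenate([np.ones(L.size, dtype=int), np.zeros(plan.n, dtype=int)])
    for j, sample in enumerate(samples):
        rows = np.concatenate([L, sample])
        clf = base(_member_seed(seed, j, stage=1))
        clf.fit(X[rows], y)
        members.append(clf)
        memberships[j, sample] = True
    P = _member_matrix(members, X)
    g_train = _membership_average(P, memberships)
    ens = NontraditionalEnsemble(
        members=members,
        memberships=memberships,
        plan=plan,
        n_features=X.shape[1],
        g_train=g_train,
    )
    ens.c_hat = estimate_c(ens, data)
    return ens


def predict_g(
    ens: NontraditionalEnsemble,
    rows: np.ndarray,
    row_memberships: np.ndarray | None = None,
) -> np.ndarray:
    """Ensemble estimate of P(l(x)=1) for the given score rows.

    Unlabeled training rows average only the members whose sample contains
    them; labeled, uncovered and novel rows average over all members.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[1] != ens.n_features:
        raise ValueError(
            f"expected rows of arity {ens.n_features}, got shape {rows.shape}"
        )
    P = _member_matrix(ens.members, rows)
    return np.clip(_membership_average(P, row_memberships), 0.0, 1.0)


def estimate_c(ens: NontraditionalEnsemble, data: PUDataset) -> float:
    """Labeling-frequency constant: mean of g over the labeled positives.

    Under SCAR this estimates ``c = P(l=1 | f=1)``.  Clamped into
    (1e-6, 1] so downstream odds ratios stay finite.
    """
    L = data.labeled_indices
    if L.size == 0:
        raise InsufficientPositivesError("cannot estimate c without labeled positives")
    c = float(np.mean(ens.g_train[L]))
    if c <= 0.0:
        warnings.warn("g is zero on every labeled positive; clamping c to 1e-6")
        return _C_EPS
    return min(c, 1.0)


# ---------------------------------------------------------------------------
# Stage 2: posterior, relabeling, and the traditional ensemble f'(.)
# ---------------------------------------------------------------------------


def posterior_unlabeled(g_value, c: float):
    """P(f=1 | l=0) from the nontraditional estimate g and the constant c.

    ``((1-c)/c) * g/(1-g)``, clamped to [0, 1] (the raw odds ratio exceeds
    1 whenever g > c).  Monotone increasing in g, decreasing in c.
    Accepts scalars or arrays.
    """
    if c <= 0.0:
        raise ValueError("c must be positive")
    c = min(float(c), 1.0)
    g = np.clip(np.asarray(g_value, dtype=float), 0.0, 1.0 - _G_EPS)
    post = ((1.0 - c) / c) * (g / (1.0 - g))
    post = np.clip(post, 0.0, 1.0)
    return float(post) if np.isscalar(g_value) else post


@dataclass
class WeightedTrainingSet:
    """Single-label, confidence-weighted training data for stage two.

    Labeled rows are ('+', 1.0).  An unlabeled row is '+' with weight equal
    to its posterior when the posterior reaches 1/2, else '-' with weight
    one minus the posterior.  The weight is the confidence that the
    assigned label is correct and is passed to the cost-sensitive
    classifier as a per-example misclassification cost.
    """

    is_positive: np.ndarray
    weight: np.ndarray
    posterior: np.ndarray  # NaN for labeled rows
    labeled: np.ndarray

    @property
    def positive_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_positive)

    @property
    def negative_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_positive)


def build_weighted_training_set(
    data: PUDataset,
    ens: NontraditionalEnsemble | None = None,
    *,
    g: np.ndarray | None = None,
    c: float | None = None,
) -> WeightedTrainingSet:
    """Relabel and weight every row from the stage-1 ensemble.

    ``g`` and ``c`` may be supplied directly (overriding the ensemble),
    which is convenient for analysing the weighting rule in isolation.
    """
    if g is None or c is None:
        if ens is None:
            raise ValueError("provide either a fitted ensemble or explicit g and c")
        g = ens.g_train if g is None else g
        c = ens.c_hat if c is None else c
    g = np.asarray(g, dtype=float)
    labeled = data.labeled
    post = posterior_unlabeled(g, c)
    post = np.asarray(post, dtype=float)
    is_positive = labeled | (post >= 0.5)
    weight = np.where(is_positive, post, 1.0 - post)
    weight[labeled] = 1.0
    post_out = post.copy()
    post_out[labeled] = np.nan
    return WeightedTrainingSet(
        is_positive=is_positive, weight=weight, posterior=post_out, labeled=labeled
    )


@dataclass
class TraditionalEnsemble:
    members: list
    memberships: np.ndarray  # over all training rows; True where row sampled
    plan: SamplingPlan
    n_features: int


@dataclass
class PUEnsembleModel:
    """The full fitted two-stage model: g-ensemble, c, and f'-ensemble."""

    nontraditional: NontraditionalEnsemble
    traditional: TraditionalEnsemble
    config: dict

    @property
    def c_hat(self) -> float:
        return self.nontraditional.c_hat

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "PUEnsembleModel":
        return joblib.load(path)


def fit_traditional(
    wts: WeightedTrainingSet,
    X: np.ndarray,
    base: Callable[[int], ProbabilisticClassifier],
    neg_plan: SamplingPlan | None = None,
    seed: int = 0,
    gamma: float = 0.9,
) -> TraditionalEnsemble:
    """Train the K' cost-sensitive members of the final predictor.

    The '+' vs '-' sets of the relabeled data are themselves unbalanced
    (true interactions are far rarer than non-interactions), so the same
    bagging scheme is reused: each member sees every '+' row plus a
    with-replacement sample of '-' rows, with per-example weights passed
    as misclassification costs.
    """
    pos = wts.positive_indices
    neg = wts.negative_indices
    if pos.size == 0 or neg.size == 0:
        raise DegenerateLabelsError(
            f"stage-2 training set has {pos.size} '+' and {neg.size} '-' rows"
        )
    if neg_plan is None:
        neg_plan = SamplingPlan.from_coverage(
            n=max(pos.size, min(1000, neg.size)), gamma=gamma, u_size=neg.size
        )
    if neg_plan.u_size != neg.size:
        raise ValueError(f"neg_plan.u_size={neg_plan.u_size} but |'-'|={neg.size}")
    samples = draw_samples(neg, neg_plan, seed)
    members = []
    memberships = np.zeros((neg_plan.k, X.shape[0]), dtype=bool)
    for j, sample in enumerate(samples):
        rows = np.concatenate([pos, sample])
        y = np.concatenate([np.ones(pos.size, dtype=int), np.zeros(sample.size, dtype=int)])
        w = np.concatenate([wts.weight[pos], wts.weight[sample]])
        clf = base(_member_seed(seed, j, stage=2))
        clf.fit(X[rows], y, sample_weight=w)
        members.append(clf)
        memberships[j, sample] = True
    return TraditionalEnsemble(
        members=members, memberships=memberships, plan=neg_plan, n_features=X.shape[1]
    )


def predict_f(
    model: PUEnsembleModel,
    rows: np.ndarray,
    row_memberships: np.ndarray | None = None,
) -> np.ndarray:
    """Final interaction probability f'(p(x)) for the given score rows."""
    rows = np.asarray(rows, dtype=float)
    trad = model.traditional
    if rows.ndim != 2 or rows.shape[1] != trad.n_features:
        raise ValueError(
            f"expected rows of arity {trad.n_features}, got shape {rows.shape}"
        )
    P = _member_matrix(trad.members, rows)
    return np.clip(_membership_average(P, row_memberships), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Model / Results porcelain
# ---------------------------------------------------------------------------


class PUEnsemble:
    """Positive-unlabeled bagged ensemble model for an interaction score table.

    Parameters
    ----------
    data
        The PU dataset (score table plus positive-only labels).
    n, gamma
        Stage-1 sampling plan: per-sample size and target coverage of U.
        By default ``n = |U|`` (classic full-size bootstrap), which keeps
        each member's labeled:unlabeled ratio equal to the population's —
        the regime in which the constant-c estimator is consistent.
        Smaller ``n`` (the subsample-to-balance regime appropriate when a
        single member cannot be trained on all of U) is fully supported.
    neg_n, neg_gamma
        Stage-2 plan over the '-' rows; defaults to
        ``n = max(#positives, 1000)`` with the stage-1 gamma.
    base
        'svc' (RBF margin classifier with Platt-style sigmoid calibration;
        default) or 'logistic', or any callable ``seed -> classifier``
        satisfying the :class:`~mirpu.classifiers.ProbabilisticClassifier`
        contract.

    Examples
    --------
    >>> model = PUEnsemble(dataset, base="logistic")          # doctest: +SKIP
    >>> res = model.fit(seed=7)                               # doctest: +SKIP
    >>> probs = res.predict(dataset.table)                    # doctest: +SKIP
    """

    def __init__(
        self,
        data: PUDataset,
        n: int | None = None,
        gamma: float = 0.9,
        neg_n: int | None = None,
        neg_gamma: float | None = None,
        base="svc",
        base_kwargs: dict | None = None,
    ):
        self.data = data
        u = data.n_unlabeled
        self.n = int(n) if n is not None else u
        self.gamma = float(gamma)
        self.neg_n = neg_n
        self.neg_gamma = float(neg_gamma) if neg_gamma is not None else self.gamma
        if callable(base):
            self._factory = base
            self.base = getattr(base, "__name__", "custom")
        else:
            self._factory = base_factory(base, **(base_kwargs or {}))
            self.base = base
        self.plan = SamplingPlan.from_coverage(self.n, self.gamma, u)

    @classmethod
    def from_files(cls, scores_path, positives_path, standardize: bool = True, **kwargs):
        """Build the model straight from a score TSV and a positive-pair TSV."""
        from .score_data import (
            assemble_pu_dataset,
            load_positives,
            load_score_table,
            standardize_scores,
        )

        table = load_score_table(scores_path)
        if standardize:
            table = standardize_scores(table)
        positives = load_positives(positives_path)
        data, unmatched = assemble_pu_dataset(table, positives)
        model = cls(data, **kwargs)
        model.unmatched_positives_ = unmatched
        return model

    def fit(self, seed: int = 0) -> "PUEnsembleResults":
        s1, s2 = _stage_seeds(seed)
        ens = fit_nontraditional(self.data, self.plan, self._factory, seed=s1)
        wts = build_weighted_training_set(self.data, ens)
        neg_plan = None
        if self.neg_n is not None:
            neg_plan = SamplingPlan.from_coverage(
                self.neg_n, self.neg_gamma, wts.negative_indices.size
            )
        trad = fit_traditional(
            wts, self.data.X, self._factory, neg_plan=neg_plan, seed=s2,
            gamma=self.neg_gamma,
        )
        config = {
            "n": self.plan.n,
            "gamma": self.plan.gamma,
            "k": self.plan.k,
            "neg_n": trad.plan.n,
            "neg_gamma": trad.plan.gamma,
            "k_prime": trad.plan.k,
            "base": self.base,
            "seed": seed,
        }
        model = PUEnsembleModel(nontraditional=ens, traditional=trad, config=config)
        return PUEnsembleResults(self, model, wts)


class PUEnsembleResults:
    """Fitted-model container: estimates, diagnostics and prediction."""

    def __init__(self, model_spec: PUEnsemble, model: PUEnsembleModel, wts: WeightedTrainingSet):
        self.model_spec = model_spec
        self.model = model
        self.weighted_training_set = wts
        self.c_hat = model.c_hat
        self.g_train = model.nontraditional.g_train
        self.posterior = wts.posterior
        self.config = model.config

    def predict(self, rows) -> np.ndarray:
        """Interaction probabilities for a ScoreTable or raw score matrix."""
        if isinstance(rows, ScoreTable):
            rows = rows.scores
        return predict_f(self.model, np.asarray(rows, dtype=float))

    def predict_training(self) -> np.ndarray:
        """Membership-aware probabilities for the rows the model was fit on."""
        return predict_f(
            self.model, self.model_spec.data.X, self.model.traditional.memberships
        )

    def save(self, path) -> None:
        self.model.save(path)

    def summary(self) -> str:
        d = self.model_spec.data
        wts = self.weighted_training_set
        cfg = self.config
        lines = [
            "Positive-Unlabeled Bagged Ensemble",
            "=" * 42,
            f"rows                 {d.table.n_rows:>12}",
            f"score columns        {d.table.n_algorithms:>12}",
            f"|L| (labeled)        {d.n_labeled:>12}",
            f"|U| (unlabeled)      {d.n_unlabeled:>12}",
            "-" * 42,
            f"stage 1   n={cfg['n']}  gamma={cfg['gamma']}  K={cfg['k']}",
            f"c-hat (label freq)   {self.c_hat:>12.4f}",
            f"stage 2   n={cfg['neg_n']}  gamma={cfg['neg_gamma']}  K'={cfg['k_prime']}",
            f"'+' rows             {wts.positive_indices.size:>12}",
            f"'-' rows             {wts.negative_indices.size:>12}",
            f"base classifier      {cfg['base']:>12}",
            f"seed                 {cfg['seed']:>12}",
            "=" * 42,
        ]
        return "\n".join(lines)
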