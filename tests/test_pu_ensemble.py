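import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_table
from mirpu.classifiers import base_factory
from mirpu.pu_ensemble import (
    DegenerateLabelsError,
    InsufficientPositivesError,
    NontraditionalEnsemble,
    PUEnsemble,
    build_weighted_training_set,
    estimate_c,
    fit_nontraditional,
    fit_traditional,
    posterior_unlabeled,
    predict_f,
    predict_g,
)
from mirpu.sampling import SamplingPlan
from mirpu.score_data import PUDataset


class ConstantClassifier:
    """Stub member returning a fixed probability everywhere."""

    def __init__(self, p):
        self.p = p

    def fit(self, X, y, sample_weight=None):
        return self

    def predict_prob(self, X):
        return np.full(len(X), self.p)


def stub_ensemble(probs, memberships, n_features=2, g_train=None):
    memberships = np.asarray(memberships, dtype=bool)
    k, n_rows = memberships.shape
    ens = NontraditionalEnsemble(
        members=[ConstantClassifier(p) for p in probs],
        memberships=memberships,
        plan=SamplingPlan(n=1, gamma=0.5, u_size=max(n_rows, 2), k=k),
        n_features=n_features,
        g_train=g_train if g_train is not None else np.zeros(n_rows),
    )
    return ens


class TestPosterior:
    def test_c_one_means_labeled_iff_positive(self):
        assert posterior_unlabeled(0.3, 1.0) == 0.0
        assert posterior_unlabeled(0.9, 1.0) == 0.0

    def test_half_c_quarter_g(self):
        assert posterior_unlabeled(0.25, 0.5) == pytest.approx(1.0 / 3.0)

    def test_overflow_clamped_to_one(self):
        # raw odds ratio (0.8/0.2)*(0.5/0.5) = 4
        assert posterior_unlabeled(0.5, 0.2) == 1.0

    def test_nonpositive_c_rejected(self):
        with pytest.raises(ValueError):
            posterior_unlabeled(0.5, 0.0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        g1=st.floats(0, 0.999),
        g2=st.floats(0, 0.999),
        c=st.floats(0.01, 1.0),
    )
    def test_monotone_in_g(self, g1, g2, c):
        lo, hi = sorted((g1, g2))
        assert posterior_unlabeled(lo, c) <= posterior_unlabeled(hi, c) + 1e-12

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(g=st.floats(0, 0.999), c1=st.floats(0.01, 1.0), c2=st.floats(0.01, 1.0))
    def test_antitone_in_c(self, g, c1, c2):
        lo, hi = sorted((c1, c2))
        assert posterior_unlabeled(g, hi) <= posterior_unlabeled(g, lo) + 1e-12


class TestPredictG:
    def test_membership_average(self):
        # row belongs to samples {1, 3}: average g_1 and g_3 only
        ens = stub_ensemble(
            [0.9, 0.2, 0.9, 0.4],
            memberships=np.array([[False], [True], [False], [True]]),
        )
        X = np.zeros((1, 2))
        assert predict_g(ens, X, ens.memberships) == pytest.approx(0.3)

    def test_uncovered_row_averages_all_members(self):
        ens = stub_ensemble([0.1, 0.2, 0.3], memberships=np.zeros((3, 1)))
        assert predict_g(ens, np.zeros((1, 2)), ens.memberships) == pytest.approx(0.2)

    def test_constant_members_give_constant(self):
        ens = stub_ensemble([0.7, 0.7], memberships=np.array([[True], [False]]))
        assert predict_g(ens, np.zeros((1, 2)), ens.memberships) == pytest.approx(0.7)

    def test_arity_mismatch_rejected(self):
        ens = stub_ensemble([0.5], memberships=np.ones((1, 1)), n_features=3)
        with pytest.raises(ValueError, match="arity 3"):
            predict_g(ens, np.zeros((1, 2)))


class TestEstimateC:
    def data_with_labels(self, labeled):
        labeled = np.asarray(labeled, bool)
        t = make_table(np.zeros((labeled.size, 2)))
        return PUDataset(t, labeled)

    def test_mean_over_labeled(self):
        data = self.data_with_labels([True, True, False, False])
        ens = stub_ensemble([0.5], np.ones((1, 4)), g_train=np.array([0.2, 0.4, 0.9, 0.9]))
        assert estimate_c(ens, data) == pytest.approx(0.3)

    def test_constant_g(self):
        data = self.data_with_labels([True, True, True, False])
        ens = stub_ensemble([0.3], np.ones((1, 4)), g_train=np.full(4, 0.3))
        assert estimate_c(ens, data) == pytest.approx(0.3)

    def test_zero_g_clamped_with_warning(self):
        data = self.data_with_labels([True, False])
        ens = stub_ensemble([0.0], np.ones((1, 2)), g_train=np.zeros(2))
        with pytest.warns(UserWarning):
            assert estimate_c(ens, data) == pytest.approx(1e-6)

    def test_no_positives_rejected(self):
        data = self.data_with_labels([False, False])
        ens = stub_ensemble([0.5], np.ones((1, 2)))
        with pytest.raises(InsufficientPositivesError):
            estimate_c(ens, data)


class TestWeightedTrainingSet:
    def toy_data(self):
        t = make_table(np.zeros((6, 2)))
        return PUDataset(t, np.array([True, True, False, False, False, False]))

    def test_relabeling_rule_exact(self):
        data = self.toy_data()
        # with c = 0.5 the posterior equals the odds g/(1-g)
        g = np.array([0.9, 0.1, 7 / 17, 3 / 13, 0.5, 0.05])
        wts = build_weighted_training_set(data, g=g, c=0.5)
        # labeled rows: always ('+', 1.0) whatever their g
        assert wts.is_positive[:2].all() and (wts.weight[:2] == 1.0).all()
        assert np.isnan(wts.posterior[:2]).all()
        # posterior 0.7 -> ('+', 0.7); posterior 0.3 -> ('-', 0.7)
        assert wts.is_positive[2] and wts.weight[2] == pytest.approx(0.7)
        assert not wts.is_positive[3] and wts.weight[3] == pytest.approx(0.7)
        # posterior saturating at 1 -> ('+', 1.0); low posterior -> '-'
        assert wts.is_positive[4] and wts.weight[4] == pytest.approx(1.0)
        assert not wts.is_positive[5]

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        g=st.lists(st.floats(0, 0.99), min_size=4, max_size=4),
        c=st.floats(0.05, 1.0),
    )
    def test_label_weight_consistency(self, g, c):
        """weights in (0,1]; '+' iff posterior >= 1/2 on unlabeled rows."""
        t = make_table(np.zeros((4, 2)))
        data = PUDataset(t, np.array([True, False, False, False]))
        wts = build_weighted_training_set(data, g=np.asarray(g), c=c)
        assert ((wts.weight > 0) & (wts.weight <= 1)).all()
        post = wts.posterior[1:]
        np.testing.assert_array_equal(wts.is_positive[1:], post >= 0.5)
        np.testing.assert_allclose(
            wts.weight[1:], np.where(post >= 0.5, post, 1 - post)
        )


@pytest.fixture(scope="module")
def separable_data():
    rng = np.random.default_rng(7)
    n_pos, n_neg = 120, 1200
    X = np.vstack(
        [
            rng.normal(3.0, 1.0, size=(n_pos, 3)),
            rng.normal(0.0, 1.0, size=(n_neg, 3)),
        ]
    )
    truth = np.arange(n_pos + n_neg) < n_pos
    labeled = truth & (rng.random(n_pos + n_neg) < 0.5)
    return PUDataset(make_table(X), labeled), truth


class TestFitNontraditional:
    def test_structure_and_c_range(self, separable_data):
        data, _ = separable_data
        plan = SamplingPlan.from_coverage(data.n_unlabeled, 0.8, data.n_unlabeled)
        ens = fit_nontraditional(data, plan, base_factory("logistic"), seed=0)
        assert ens.k == plan.k == len(ens.members)
        assert ens.memberships.shape == (plan.k, data.table.n_rows)
        assert not ens.memberships[:, data.labeled_indices].any()
        assert 0 < ens.c_hat <= 1

    def test_uninformative_scores_recover_member_prior(self):
        """Identical L/U distributions: c-hat ~ |L| / (|L| + n)."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((1200, 4))
        labeled = np.zeros(1200, bool)
        labeled[:200] = True
        data = PUDataset(make_table(X), labeled)
        plan = SamplingPlan.from_coverage(600, 0.8, 1000)
        ens = fit_nontraditional(data, plan, base_factory("logistic"), seed=2)
        assert ens.c_hat == pytest.approx(200 / 800, abs=0.05)

    def test_too_few_positives_rejected(self):
        data = PUDataset(make_table(np.zeros((5, 2))), np.array([True] + [False] * 4))
        plan = SamplingPlan.from_coverage(4, 0.5, 4)
        with pytest.raises(InsufficientPositivesError):
            fit_nontraditional(data, plan, base_factory("logistic"), seed=0)

    def test_plan_size_mismatch_rejected(self, separable_data):
        data, _ = separable_data
        plan = SamplingPlan.from_coverage(10, 0.5, 99)
        with pytest.raises(ValueError, match="u_size"):
            fit_nontraditional(data, plan, base_factory("logistic"), seed=0)


class TestFitTraditional:
    def test_member_count_follows_plan(self, separable_data):
        data, _ = separable_data
        plan = SamplingPlan.from_coverage(data.n_unlabeled, 0.8, data.n_unlabeled)
        ens = fit_nontraditional(data, plan, base_factory("logistic"), seed=0)
        wts = build_weighted_training_set(data, ens)
        neg_plan = SamplingPlan.from_coverage(
            100, 0.8, wts.negative_indices.size
        )
        trad = fit_traditional(
            wts, data.X, base_factory("logistic"), neg_plan=neg_plan, seed=1
        )
        assert len(trad.members) == neg_plan.k

    def test_separable_positives_score_high_held_in(self, separable_data):
        data, truth = separable_data
        res = PUEnsemble(data, base="logistic", gamma=0.8).fit(seed=4)
        preds = res.predict_training()
        wts = res.weighted_training_set
        assert np.median(preds[wts.positive_indices]) >= 0.5
        assert preds[truth].mean() > preds[~truth].mean()

    def test_single_class_rejected(self):
        data = PUDataset(make_table(np.zeros((4, 2))), np.ones(4, bool))
        wts = build_weighted_training_set(data, g=np.full(4, 0.5), c=0.5)
        with pytest.raises(DegenerateLabelsError):
            fit_traditional(wts, data.X, base_factory("logistic"), seed=0)


class TestEndToEnd:
    def test_same_seed_reproduces_predictions(self, tiny_benchmark):
        data, _, _ = tiny_benchmark
        a = PUEnsemble(data, base="logistic").fit(seed=13)
        b = PUEnsemble(data, base="logistic").fit(seed=13)
        X = data.X[:50]
        np.testing.assert_array_equal(a.predict(X), b.predict(X))
        assert a.c_hat == b.c_hat
        c = PUEnsemble(data, base="logistic").fit(seed=14)
        assert not np.array_equal(a.predict(X), c.predict(X))

    def test_predictions_bounded_for_adversarial_rows(self, tiny_benchmark):
        data, _, _ = tiny_benchmark
        res = PUEnsemble(data, base="logistic").fit(seed=0)
        s = data.table.n_algorithms
        X = np.vstack([np.zeros(s), np.full(s, 1e6), np.full(s, -1e6)])
        p = res.predict(X)
        assert ((p >= 0) & (p <= 1)).all()
        # duplicate rows get identical outputs
        p2 = res.predict(np.vstack([X, X]))
        np.testing.assert_array_equal(p2[:3], p2[3:])

    def test_svc_default_base_end_to_end(self, tiny_benchmark):
        data, truth, _ = tiny_benchmark
        res = PUEnsemble(data, base="svc", gamma=0.8).fit(seed=5)
        p = res.predict_training()
        assert ((p >= 0) & (p <= 1)).all()
        assert p[truth].mean() > p[~truth].mean()

    def test_model_round_trip(self, tiny_benchmark, tmp_path):
        data, _, _ = tiny_benchmark
        res = PUEnsemble(data, base="logistic").fit(seed=2)
        path = tmp_path / "model.joblib"
        res.save(path)
        from mirpu.pu_ensemble import PUEnsembleModel

        loaded = PUEnsembleModel.load(path)
        np.testing.assert_array_equal(
            predict_f(loaded, data.X[:40]), res.predict(data.X[:40])
        )
        assert loaded.c_hat == res.c_hat

    def test_summary_reports_key_quantities(self, tiny_benchmark):
        data, _, _ = tiny_benchmark
        res = PUEnsemble(data, base="logistic").fit(seed=0)
        s = res.summary()
        for token in ("|L|", "|U|", "c-hat", "stage 1", "stage 2"):
            assert token in s
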