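"""Base-learner construction, meta-feature building, stacking and voting."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.tree import DecisionTreeClassifier

from selfstack import (
    BaseLearnerSpec,
    EncodedMatrix,
    StackConfig,
    build_meta_features,
    fit_self_stack,
    fit_self_vote,
    make_model,
    vote_hard,
    vote_soft,
)
from conftest import ConstantStub, MemorizingStub


def small_matrix(n=100, n_classes=5, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, n_classes, size=n)
    X = rng.normal(size=(n, 4))
    if informative:
        X[:, 0] += 3.0 * y
    return EncodedMatrix.from_arrays(X, y)


class TestMakeModel:
    def test_rf_defaults(self):
        m = make_model(BaseLearnerSpec("RF"))
        assert m.n_estimators == 200 and m.max_depth == 50

    def test_adaboost_defaults(self):
        m = make_model(BaseLearnerSpec("AdaBoost"))
        assert m.n_estimators == 300
        assert m.learning_rate == 0.8
        assert m.random_state == 5

    def test_gbm_defaults(self):
        m = make_model(BaseLearnerSpec("GBM"))
        assert m.n_estimators == 50 and m.learning_rate == 0.2
        assert m.max_depth == 200 and m.random_state == 52

    def test_lr_and_svc_defaults(self):
        lr = make_model(BaseLearnerSpec("LR"))
        assert lr.solver == "saga" and lr.C == 3.0
        svc = make_model(BaseLearnerSpec("SVC"))
        assert svc.kernel == "linear" and svc.C == 1.0

    def test_seed_overrides_random_state(self):
        m = make_model(BaseLearnerSpec("GBM", seed=7))
        assert m.random_state == 7

    def test_unknown_family(self):
        with pytest.raises(ValueError, match="family"):
            BaseLearnerSpec("XGB")

    def test_unknown_hyperparameter(self):
        with pytest.raises(ValueError, match="hyperparameter"):
            make_model(BaseLearnerSpec("RF", {"n_trees": 10}))


class TestVoteHard:
    def test_strict_majority(self):
        assert vote_hard(np.array([[0], [0], [1]]))[0] == 0

    def test_three_way_tie_lowest_index(self):
        assert vote_hard(np.array([[0], [1], [2]]))[0] == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vote_hard(np.empty((0, 0)))

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_matches_count_and_argmax_oracle(self, seed):
        rng = np.random.default_rng(seed)
        preds = rng.integers(0, 5, size=(3, 40))
        got = vote_hard(preds, n_classes=5)
        for s in range(preds.shape[1]):
            tally = [int((preds[:, s] == c).sum()) for c in range(5)]
            best = max(range(5), key=lambda c: (tally[c], -c))
            assert got[s] == best


class TestVoteSoft:
    def test_hand_summed_example(self):
        probas = np.array([
            [[0.6, 0.4]], [[0.6, 0.4]], [[0.2, 0.8]],
        ])
        # column sums (1.4, 1.6) -> class 1
        assert vote_soft(probas)[0] == 1

    def test_uniform_tie_lowest_index(self):
        probas = np.full((3, 4, 5), 0.2)
        assert vote_soft(probas).tolist() == [0, 0, 0, 0]

    def test_malformed_simplex_rejected(self):
        bad = np.array([[[0.7, 0.7]]])
        with pytest.raises(ValueError, match="sum to 1"):
            vote_soft(bad)

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_sum_equals_mean_argmax(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.random((3, 25, 4))
        probas = raw / raw.sum(axis=2, keepdims=True)
        got = vote_soft(probas)
        assert np.array_equal(got, probas.mean(axis=0).argmax(axis=1))

    def test_one_hot_members_agree_with_hard_vote(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 4, size=(5, 30))
        probas = np.zeros((5, 30, 4))
        for m in range(5):
            probas[m, np.arange(30), labels[m]] = 1.0
        assert np.array_equal(vote_soft(probas), vote_hard(labels, n_classes=4))


class TestMetaFeatures:
    def test_label_and_proba_shapes(self):
        data = small_matrix(n=100, n_classes=5)
        factory = lambda j: DecisionTreeClassifier(random_state=j)
        cfg = StackConfig(m=4, k=5, meta_mode="label")
        assert build_meta_features(data, cfg, factory).Z.shape == (100, 4)
        cfg = StackConfig(m=4, k=5, meta_mode="proba")
        assert build_meta_features(data, cfg, factory).Z.shape == (100, 20)

    def test_constant_stub_gives_constant_meta_features(self):
        data = small_matrix()
        meta = build_meta_features(
            data, StackConfig(m=3, k=5), model_factory=lambda j: ConstantStub(0)
        )
        assert (meta.Z == 0).all()

    def test_out_of_fold_rows_never_seen_by_their_model(self):
        """A memorizing stub must never find a held-out row in its memory:
        any hit would mean the meta-features leak training fits."""
        data = small_matrix(n=120, informative=False)
        leaks = [0]
        meta = build_meta_features(
            data,
            StackConfig(m=2, k=4),
            model_factory=lambda j: MemorizingStub(leak_counter=leaks),
        )
        assert leaks[0] == 0
        # all predictions fall back to the arbitrary class: chance quality
        acc = (meta.Z[:, 0] == data.y).mean()
        assert acc == pytest.approx((data.y == 0).mean())

    def test_deterministic_given_master_seed(self):
        data = small_matrix()
        cfg = StackConfig(
            m=2, k=4, base_spec=BaseLearnerSpec("RF", {"n_estimators": 15})
        )
        a = build_meta_features(data, cfg)
        b = build_meta_features(data, cfg)
        assert np.array_equal(a.Z, b.Z)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_meta_features(small_matrix(n=4), StackConfig(k=5))

    def test_fold_assignment_is_a_partition(self):
        data = small_matrix(n=53)
        meta = build_meta_features(
            data, StackConfig(m=1, k=5), model_factory=lambda j: ConstantStub()
        )
        sizes = np.bincount(meta.fold_assignment, minlength=5)
        assert sizes.sum() == 53 and sizes.max() - sizes.min() <= 1


class _IdentityMeta:
    """Meta learner that echoes the (single) one-hot base prediction."""

    def fit(self, Z, y):
        self.C = Z.shape[1]
        return self

    def predict(self, Z):
        return Z.argmax(axis=1) % self.C


class TestSelfStack:
    def test_separable_accuracy(self, separable_split, fast_stack_config):
        split, encoded = separable_split
        stack = fit_self_stack(split.train, fast_stack_config)
        acc = (stack.predict(split.test.X) == split.test.y).mean()
        assert acc >= 0.95

    def test_single_base_with_identity_meta_reduces_to_base(self):
        data = small_matrix(n=80, n_classes=3)
        cfg = StackConfig(m=1, k=4)
        factory = lambda j: DecisionTreeClassifier(random_state=0)
        stack = fit_self_stack(
            data, cfg, model_factory=factory, meta_factory=lambda: _IdentityMeta()
        )
        base = DecisionTreeClassifier(random_state=0).fit(data.X, data.y)
        # identity meta maps the one-hot encoding back to the base label
        pred = stack.predict(data.X)
        assert np.array_equal(pred % 3, base.predict(data.X))

    def test_single_class_rejected(self):
        data = EncodedMatrix.from_arrays(np.random.default_rng(0).normal(size=(20, 3)),
                                         np.zeros(20, dtype=int))
        with pytest.raises(ValueError, match="single class"):
            fit_self_stack(data, StackConfig())

    def test_empty_and_wrong_width_inputs(self, separable_split,
                                          fast_stack_config):
        split, _ = separable_split
        stack = fit_self_stack(split.train, fast_stack_config)
        assert stack.predict(np.empty((0, split.train.X.shape[1]))).size == 0
        with pytest.raises(ValueError, match="columns"):
            stack.predict(split.test.X[:, :3])

    def test_seed_determinism_end_to_end(self, separable_split):
        split, _ = separable_split
        spec = BaseLearnerSpec("RF", {"n_estimators": 15})
        cfg = StackConfig(base_spec=spec, meta_spec=spec, master_seed=42)
        a = fit_self_stack(split.train, cfg).predict(split.test.X)
        b = fit_self_stack(split.train, cfg).predict(split.test.X)
        assert np.array_equal(a, b)

    def test_proba_mode(self, separable_split, fast_rf_spec):
        split, _ = separable_split
        cfg = StackConfig(meta_mode="proba", base_spec=fast_rf_spec,
                          meta_spec=fast_rf_spec)
        stack = fit_self_stack(split.train, cfg)
        acc = (stack.predict(split.test.X) == split.test.y).mean()
        assert acc >= 0.95


class TestSelfVote:
    def test_three_member_ensembles(self, separable_split, fast_rf_spec):
        split, _ = separable_split
        for criterion in ("hard", "soft"):
            ens = fit_self_vote(split.train, spec=fast_rf_spec,
                                criterion=criterion)
            assert len(ens.base_models) == 3
            acc = (ens.predict(split.test.X) == split.test.y).mean()
            assert acc >= 0.95

    def test_members_have_distinct_seeds(self, separable_split, fast_rf_spec):
        split, _ = separable_split
        ens = fit_self_vote(split.train, spec=fast_rf_spec, master_seed=9)
        seeds = [m.random_state for m in ens.base_models]
        assert seeds == [9, 10, 11]

    def test_single_member_reduces_to_member(self, separable_split,
                                             fast_rf_spec):
        split, _ = separable_split
        ens = fit_self_vote(split.train, n_base=1, spec=fast_rf_spec)
        member = ens.base_models[0]
        assert np.array_equal(ens.predict(split.test.X),
                              member.predict(split.test.X))

    def test_identical_members_vote_like_one(self, separable_split):
        split, _ = separable_split
        factory = lambda j: DecisionTreeClassifier(random_state=1)
        ens = fit_self_vote(split.train, model_factory=factory)
        single = DecisionTreeClassifier(random_state=1).fit(
            split.train.X, split.train.y
        )
        assert np.array_equal(ens.predict(split.test.X),
                              single.predict(split.test.X))
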