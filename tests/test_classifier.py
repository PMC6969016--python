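import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scentmark import (
    BehaviourClass,
    KnnClassifier,
    TrainingSet,
    build_testing_set,
    build_training_set,
    cross_individual_matrix,
    evaluate,
    tune_k,
)
from scentmark.classifier import _auc_rank, _stratified_folds
from scentmark.synthetic import SimConfig, simulate_accel

from conftest import toy_three_class

CLASSES = [
    BehaviourClass.LEFT_LEG,
    BehaviourClass.RIGHT_LEG,
    BehaviourClass.SQUAT_URINATE,
    BehaviourClass.OTHER,
]


# ---------------------------------------------------------------------------
# Independent brute-force oracle: exhaustive distance sort, same tie rules
# ---------------------------------------------------------------------------


def oracle_knn(train_x, train_y, k, query):
    dists = sorted(
        (float(np.linalg.norm(np.asarray(query) - np.asarray(tx))), i)
        for i, tx in enumerate(train_x)
    )
    neigh = dists[:k]
    counts = {}
    for _d, i in neigh:
        counts[train_y[i]] = counts.get(train_y[i], 0) + 1
    best = max(counts.values())
    tied = {c for c, n in counts.items() if n == best}
    if len(tied) == 1:
        return tied.pop()
    for _d, i in neigh:  # nearest tied class wins
        if train_y[i] in tied:
            return train_y[i]


def make_training(rng, n, n_classes=3):
    x = rng.normal(0, 1, size=(n, 3))
    y = np.array(
        [CLASSES[i] for i in rng.integers(0, n_classes, size=n)], dtype=object
    )
    return TrainingSet(records=x, labels=y, indices=np.arange(n))


class TestKnnPredict:
    def test_k1_exact_match(self):
        ts = make_training(np.random.default_rng(0), 20)
        model = KnnClassifier(training=ts, k=1)
        assert model.predict(ts.records[[5]])[0] == ts.labels[5]

    def test_all_three_nearest_agree(self):
        x = np.array([[0, -1, 0]] * 3 + [[0, 1, 0]] * 3, dtype=float)
        y = np.array(
            [BehaviourClass.LEFT_LEG] * 3 + [BehaviourClass.RIGHT_LEG] * 3,
            dtype=object,
        )
        ts = TrainingSet(records=x, labels=y, indices=np.arange(6))
        model = KnnClassifier(training=ts, k=3)
        assert model.predict([[0, -0.9, 0]])[0] == BehaviourClass.LEFT_LEG

    def test_matches_oracle_on_200_random_queries(self):
        rng = np.random.default_rng(1)
        ts = make_training(rng, 80, n_classes=4)
        model = KnnClassifier(training=ts, k=5)
        q = rng.normal(0, 1, size=(200, 3))
        pred = model.predict(q)
        expect = [oracle_knn(ts.records, ts.labels, 5, qi) for qi in q]
        assert list(pred) == expect

    def test_matches_sklearn_on_binary_problem(self):
        # sklearn as an external oracle; binary + odd k avoids vote ties
        from sklearn.neighbors import KNeighborsClassifier

        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, size=(120, 3))
        y = np.array(
            [CLASSES[i] for i in rng.integers(0, 2, size=120)], dtype=object
        )
        ts = TrainingSet(records=x, labels=y, indices=np.arange(120))
        q = rng.normal(0, 1, size=(100, 3))
        ours = KnnClassifier(training=ts, k=7).predict(q)
        sk = KNeighborsClassifier(n_neighbors=7).fit(
            x, [c.value for c in y]
        ).predict(q)
        assert [c.value for c in ours] == list(sk)

    def test_empty_query_list(self):
        ts = make_training(np.random.default_rng(3), 10)
        model = KnnClassifier(training=ts, k=1)
        assert len(model.predict(np.empty((0, 3)))) == 0

    def test_even_k_rejected(self):
        ts = make_training(np.random.default_rng(4), 10)
        with pytest.raises(ValueError, match="odd"):
            KnnClassifier(training=ts, k=4)

    def test_k_larger_than_training_rejected(self):
        ts = make_training(np.random.default_rng(5), 4)
        with pytest.raises(ValueError):
            KnnClassifier(training=ts, k=5)

    def test_distance_weighted_exact_match_wins(self):
        x = np.array([[0.0, 0.0, 0.0]] + [[0.1, 0, 0]] * 4)
        y = np.array(
            [BehaviourClass.LEFT_LEG] + [BehaviourClass.OTHER] * 4, dtype=object
        )
        ts = TrainingSet(records=x, labels=y, indices=np.arange(5))
        model = KnnClassifier(training=ts, k=5, vote="distance_weighted")
        assert model.predict([[0.0, 0.0, 0.0]])[0] == BehaviourClass.LEFT_LEG

    def test_k1_self_prediction_reproduces_labels(self):
        ts = make_training(np.random.default_rng(6), 60)
        model = KnnClassifier(training=ts, k=1)
        assert list(model.predict(ts.records)) == list(ts.labels)

    @settings(max_examples=25, deadline=None)
    @given(
        n=st.integers(10, 60),
        k=st.sampled_from([1, 3, 5, 7]),
        seed=st.integers(0, 10_000),
    )
    def test_property_oracle_agreement(self, n, k, seed):
        rng = np.random.default_rng(seed)
        ts = make_training(rng, n, n_classes=3)
        model = KnnClassifier(training=ts, k=min(k, n if n % 2 else n - 1))
        q = rng.normal(0, 1, size=(10, 3))
        pred = model.predict(q)
        expect = [oracle_knn(ts.records, ts.labels, model.k, qi) for qi in q]
        assert list(pred) == expect

    def test_json_round_trip(self, tmp_path):
        ts = make_training(np.random.default_rng(7), 30)
        model = KnnClassifier(training=ts, k=3, vote="distance_weighted")
        p = tmp_path / "model.json"
        model.to_json(p)
        back = KnnClassifier.from_json(p)
        assert back.k == 3 and back.vote == "distance_weighted"
        q = np.random.default_rng(8).normal(0, 1, (20, 3))
        assert list(back.predict(q)) == list(model.predict(q))


class TestTrainingSets:
    def test_paper_design_male(self, male_sim):
        _cfg, res = male_sim
        ts = build_training_set(res.trace, res.labels, seed=0)
        counts = ts.class_counts()
        assert counts[BehaviourClass.LEFT_LEG] == 50
        assert counts[BehaviourClass.RIGHT_LEG] == 50
        assert counts[BehaviourClass.OTHER] == 500
        assert len(ts) == 600

    def test_toy_counts_and_disjointness(self):
        trace, labels = toy_three_class()
        tr = build_training_set(trace, labels, n_scent=2, n_other=4, seed=1)
        assert len(tr) == 8
        te = build_testing_set(trace, labels, tr, n_other_test=3000, seed=1)
        assert set(tr.indices) & set(te.indices) == set()

    def test_seed_reproducible(self, male_sim):
        _cfg, res = male_sim
        a = build_training_set(res.trace, res.labels, seed=5)
        b = build_training_set(res.trace, res.labels, seed=5)
        assert np.array_equal(a.indices, b.indices)

    def test_insufficient_samples_error(self):
        trace, labels = toy_three_class(n_left=3)
        with pytest.raises(ValueError, match="left_leg"):
            build_training_set(trace, labels, n_scent=5, n_other=4, seed=0)

    def test_testing_set_difference(self):
        trace, labels = toy_three_class(n_left=10)
        tr = build_training_set(trace, labels, n_scent=3, n_other=5, seed=2)
        te = build_testing_set(trace, labels, tr, n_other_test=3000, seed=2)
        n_left_test = sum(1 for c in te.labels if c == BehaviourClass.LEFT_LEG)
        assert n_left_test == 7

    def test_other_cap_warns(self):
        trace, labels = toy_three_class(n_other=20)
        tr = build_training_set(trace, labels, n_scent=2, n_other=4, seed=0)
        with pytest.warns(UserWarning, match="other"):
            te = build_testing_set(trace, labels, tr, n_other_test=3000, seed=0)
        n_other = sum(1 for c in te.labels if c == BehaviourClass.OTHER)
        assert n_other == 16

    def test_disjointness_on_simulator(self, male_sim):
        _cfg, res = male_sim
        tr = build_training_set(res.trace, res.labels, seed=0)
        te = build_testing_set(res.trace, res.labels, tr, seed=0)
        assert set(tr.indices) & set(te.indices) == set()


class TestTuneK:
    def test_separable_prefers_smallest_k(self, noisefree_sim):
        _cfg, (trace, labels) = noisefree_sim
        k_best, table = tune_k(trace, labels, seed=0)
        assert k_best == 1
        assert all(r["mean_accuracy"] == 1.0 for r in table)

    def test_seed_reproducible(self, male_sim):
        _cfg, res = male_sim
        a = tune_k(res.trace, res.labels, seed=3)
        b = tune_k(res.trace, res.labels, seed=3)
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_fold_count_error(self):
        trace, labels = toy_three_class()
        tr = build_training_set(trace, labels, n_scent=3, n_other=5, seed=0)
        with pytest.raises(ValueError, match="folds"):
            tune_k(trace, labels, folds=4, seed=0, training=tr)

    def test_stratified_folds_balance(self):
        rng = np.random.default_rng(0)
        labels = np.array(
            [BehaviourClass.LEFT_LEG] * 50 + [BehaviourClass.OTHER] * 500,
            dtype=object,
        )
        fold_of = _stratified_folds(labels, 5, rng)
        for f in range(5):
            assert np.sum(fold_of[:50] == f) == 10
            assert np.sum(fold_of[50:] == f) == 100


class TestEvaluate:
    def test_identity(self):
        y = np.array([BehaviourClass.LEFT_LEG] * 5 + [BehaviourClass.OTHER] * 5,
                     dtype=object)
        rep = evaluate(y, y)
        assert rep.accuracy == 1.0
        assert all(m.f1 == 1.0 for m in rep.per_class.values())

    def test_hand_computed_counts(self):
        # TP=2 FP=1 FN=2 TN=5 for LEFT -> precision 2/3, recall 1/2, F1 4/7
        L, O = BehaviourClass.LEFT_LEG, BehaviourClass.OTHER
        y_true = np.array([L, L, L, L, O, O, O, O, O, O], dtype=object)
        y_pred = np.array([L, L, O, O, L, O, O, O, O, O], dtype=object)
        rep = evaluate(y_true, y_pred)
        m = rep.per_class[L]
        assert (m.tp, m.fp, m.fn, m.tn) == (2, 1, 2, 5)
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(1 / 2)
        assert m.f1 == pytest.approx(4 / 7)

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        y_true = np.array([CLASSES[i] for i in rng.integers(0, 4, 200)], dtype=object)
        y_pred = np.array([CLASSES[i] for i in rng.integers(0, 4, 200)], dtype=object)
        rep = evaluate(y_true, y_pred)
        for m in rep.per_class.values():
            assert m.tp + m.fp + m.tn + m.fn == 200

    def test_weighted_recall_equals_accuracy(self):
        rng = np.random.default_rng(1)
        y_true = np.array([CLASSES[i] for i in rng.integers(0, 4, 500)], dtype=object)
        y_pred = np.array([CLASSES[i] for i in rng.integers(0, 4, 500)], dtype=object)
        rep = evaluate(y_true, y_pred)
        assert rep.weighted_recall == pytest.approx(rep.accuracy, abs=1e-12)

    def test_f1_between_precision_and_recall(self):
        rng = np.random.default_rng(2)
        y_true = np.array([CLASSES[i] for i in rng.integers(0, 3, 300)], dtype=object)
        y_pred = np.array([CLASSES[i] for i in rng.integers(0, 3, 300)], dtype=object)
        rep = evaluate(y_true, y_pred)
        for m in rep.per_class.values():
            assert min(m.precision, m.recall) - 1e-12 <= m.f1
            assert m.f1 <= max(m.precision, m.recall) + 1e-12

    def test_zero_denominator_precision_warns(self):
        L, O = BehaviourClass.LEFT_LEG, BehaviourClass.OTHER
        y_true = np.array([L, O, O], dtype=object)
        y_pred = np.array([O, O, O], dtype=object)
        with pytest.warns(UserWarning, match="precision undefined"):
            rep = evaluate(y_true, y_pred)
        assert rep.per_class[L].precision == 0.0

    def test_auc_perfectly_separated(self):
        L, O = BehaviourClass.LEFT_LEG, BehaviourClass.OTHER
        y_true = np.array([L] * 10 + [O] * 10, dtype=object)
        scores = {L: np.r_[np.ones(10), np.zeros(10)]}
        rep = evaluate(y_true, y_true, scores=scores)
        assert rep.per_class[L].auc == 1.0

    def test_auc_random_scores_near_half(self):
        rng = np.random.default_rng(3)
        y_pos = rng.integers(0, 2, 10_000).astype(bool)
        score = rng.uniform(0, 1, 10_000)
        assert _auc_rank(y_pos, score) == pytest.approx(0.5, abs=0.05)

    def test_auc_matches_sklearn_with_ties(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        y_pos = rng.integers(0, 2, 500).astype(bool)
        score = rng.integers(0, 5, 500) / 4.0  # heavy ties, like vote fractions
        assert _auc_rank(y_pos, score) == pytest.approx(
            roc_auc_score(y_pos, score), abs=1e-12
        )

    def test_length_mismatch(self):
        y = np.array([BehaviourClass.OTHER] * 3, dtype=object)
        with pytest.raises(ValueError):
            evaluate(y, y[:2])


class TestCrossIndividual:
    BASE = dict(duration_s=1800.0, marks_per_hour=10.0, noise_sd_g=0.1,
                sex="male")

    def test_matrix_shape(self):
        ds = [
            simulate_accel(SimConfig(seed=s, **self.BASE)) for s in (21, 22, 23)
        ]
        mat = cross_individual_matrix(ds, seed=1)
        assert len(mat) == 3 and all(len(row) == 3 for row in mat)

    def test_exchangeable_pair_off_diagonal_close(self):
        ds = [simulate_accel(SimConfig(seed=s, **self.BASE)) for s in (21, 23)]
        mat = cross_individual_matrix(ds, seed=1)
        for i in range(2):
            for j in range(2):
                assert abs(mat[i][j].accuracy - mat[i][i].accuracy) < 0.02

    def test_rotated_mount_degrades_transfer(self):
        a = simulate_accel(SimConfig(seed=21, **self.BASE))
        b = simulate_accel(SimConfig(seed=22, mount_roll_deg=30.0, **self.BASE))
        mat = cross_individual_matrix([a, b], seed=1)
        assert mat[0][1].accuracy < mat[0][0].accuracy
        assert mat[1][0].accuracy < mat[1][1].accuracy

    def test_vocabulary_mismatch_error(self):
        a = simulate_accel(SimConfig(seed=21, **self.BASE))
        b = simulate_accel(
            SimConfig(seed=22, duration_s=1800.0, marks_per_hour=10.0,
                      noise_sd_g=0.1, sex="female")
        )
        with pytest.raises(ValueError, match="differ in classes"):
            cross_individual_matrix([a, b], seed=1)
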