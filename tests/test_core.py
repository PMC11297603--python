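import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier

from mtforestnet.core import (
    ForestParams,
    MTForestNet,
    MTForestNetResults,
    ScoreMatrix,
    TaskDataset,
    ablate_dataset,
    auc,
    score_all,
    split_tasks,
    stratified_split,
    train_layer,
)
from mtforestnet.exceptions import (
    SplitError,
    UndefinedAUCError,
    ValidationError,
)


def make_task(name, n, n_pos, m=16, seed=0):
    rng = np.random.default_rng(seed)
    X = (rng.random((n, m)) < 0.3).astype(np.uint8)
    y = np.zeros(n, np.int8)
    y[:n_pos] = 1
    ids = np.array([f"{name}_{i}" for i in range(n)], dtype=object)
    return TaskDataset(name, ids, X, y)


class TestForestParams:
    def test_log2_rule_tracks_current_width(self):
        p = ForestParams()
        assert p.max_features(1024) == 10
        assert p.max_features(1072) == 10  # floor(log2(1072))
        assert p.max_features(2) == 1

    def test_defaults_are_reference_configuration(self):
        p = ForestParams()
        assert (p.n_estimators, p.max_features_rule, p.random_state) == (500, "log2", 8)


class TestStratifiedSplit:
    def test_per_class_allocation(self):
        task = make_task("t", 100, 30)
        split = stratified_split(task, seed=3)
        pos_train = ((split.y == 1) & (split.split == "train")).sum()
        assert abs(pos_train - 21) <= 1
        neg_train = ((split.y == 0) & (split.split == "train")).sum()
        assert abs(neg_train - 49) <= 1
        # overall 70/10/20 within one chemical per stratum
        assert abs((split.split == "validation").sum() - 10) <= 2

    def test_deterministic(self):
        task = make_task("t", 50, 20)
        a = stratified_split(task, seed=9).split
        b = stratified_split(task, seed=9).split
        assert np.array_equal(a, b)

    def test_single_class_errors_with_task_name(self):
        task = make_task("lonely", 10, 0)
        with pytest.raises(SplitError, match="lonely"):
            stratified_split(task)

    def test_both_classes_in_train(self):
        task = make_task("t", 12, 2)
        split = stratified_split(task, seed=0)
        tr = split.indices("train")
        assert set(split.y[tr]) == {0, 1}

    def test_split_tasks_independent_per_task(self):
        tasks = [make_task("a", 40, 15), make_task("b", 40, 15)]
        out1 = split_tasks(tasks, seed=4)
        out2 = split_tasks([tasks[1]], seed=4)
        assert np.array_equal(out1[1].split, out2[0].split)


class TestAuc:
    def test_perfect_ties_and_enumerated(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5
        # pairs: (0.8,0.6)+, (0.8,0.7)+, (0.2,0.6)-, (0.2,0.7)- -> 2/4
        assert auc([0.8, 0.6, 0.7, 0.2], [1, 0, 0, 1]) == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedAUCError):
            auc([0.1, 0.2], [1, 1])


class TestTrainLayerAndScoreAll:
    def test_layer1_width_is_m(self, tiny_params):
        tasks = split_tasks([make_task("a", 40, 15), make_task("b", 40, 15)], seed=1)
        layer = train_layer(tasks, None, tiny_params)
        assert all(c.n_features_in_ == 16 for c in layer.classifiers)

    def test_stacked_width_is_m_plus_t(self, tiny_params):
        tasks = split_tasks([make_task("a", 40, 15), make_task("b", 40, 15)], seed=1)
        layer1 = train_layer(tasks, None, tiny_params)
        ids = np.concatenate([t.chem_ids for t in tasks])
        X = np.vstack([t.X for t in tasks])
        sm = score_all(layer1, X, chem_ids=ids)
        layer2 = train_layer(tasks, sm, tiny_params)
        assert all(c.n_features_in_ == 16 + 2 for c in layer2.classifiers)

    def test_own_score_exclusion_drops_one_column(self, tiny_params):
        tasks = split_tasks([make_task("a", 40, 15), make_task("b", 40, 15)], seed=1)
        layer1 = train_layer(tasks, None, tiny_params)
        ids = np.concatenate([t.chem_ids for t in tasks])
        X = np.vstack([t.X for t in tasks])
        sm = score_all(layer1, X, chem_ids=ids)
        layer2 = train_layer(tasks, sm, tiny_params, include_own_score=False)
        assert all(c.n_features_in_ == 16 + 1 for c in layer2.classifiers)

    def test_score_coverage_gap_is_reported(self, tiny_params):
        tasks = split_tasks([make_task("a", 40, 15)], seed=1)
        sm = ScoreMatrix(np.array(["z"], dtype=object), np.array([[0.5]]), ["a"], 1)
        with pytest.raises(ValidationError, match="a_"):
            train_layer(tasks, sm, tiny_params)

    def test_identical_rows_get_identical_scores(self, tiny_params):
        tasks = split_tasks([make_task("a", 40, 15)], seed=1)
        layer = train_layer(tasks, None, tiny_params)
        X = np.tile(tasks[0].X[0], (3, 1))
        sm = score_all(layer, X)
        assert (sm.scores == sm.scores[0]).all()
        assert (0 <= sm.scores).all() and (sm.scores <= 1).all()

    def test_single_tree_pure_leaves_score_binary(self):
        # distinct rows -> a lone tree separates them into pure leaves
        params = ForestParams(n_estimators=1, random_state=8)
        X = ((np.arange(32)[:, None] >> np.arange(5)) & 1).astype(np.uint8)
        y = np.repeat([0, 1], 16)
        ids = np.array([f"c{i}" for i in range(32)], dtype=object)
        tasks = split_tasks([TaskDataset("a", ids, X, y)], seed=1)
        layer = train_layer(tasks, None, params)
        sm = score_all(layer, tasks[0].X)
        assert set(np.unique(sm.scores)) <= {0.0, 1.0}

    def test_width_mismatch(self, tiny_params):
        tasks = split_tasks([make_task("a", 40, 15)], seed=1)
        layer = train_layer(tasks, None, tiny_params)
        with pytest.raises(ValidationError):
            score_all(layer, np.zeros((2, 7), np.uint8))


class TestFit:
    def test_max_layers_1_equals_single_task_forests(self, small_tasks, tiny_params):
        res = MTForestNet(small_tasks, tiny_params).fit(max_layers=1, split_seed=5)
        assert res.n_layers == 1 and res.best_layer == 1
        for ti, task in enumerate(res.tasks):
            tr = task.indices("train")
            clf = RandomForestClassifier(
                n_estimators=25, max_features=tiny_params.max_features(task.n_features),
                random_state=8, n_jobs=1,
            ).fit(task.X[tr], task.y[tr])
            expected = clf.predict_proba(task.X)[:, list(clf.classes_).index(1)]
            rows = res._union.task_rows[ti]
            np.testing.assert_array_equal(res._layer_scores[0][rows, ti], expected)

    def test_deterministic_across_runs(self, small_tasks, tiny_params):
        r1 = MTForestNet(small_tasks, tiny_params).fit(max_layers=3, split_seed=5)
        r2 = MTForestNet(small_tasks, tiny_params).fit(max_layers=3, split_seed=5)
        assert r1.n_layers == r2.n_layers
        for a, b in zip(r1.per_layer_validation_auc, r2.per_layer_validation_auc):
            np.testing.assert_array_equal(a, b)

    def test_best_layer_never_worse_than_layer1(self, fitted_small):
        assert (
            fitted_small.mean_validation_auc[fitted_small.best_layer - 1]
            >= fitted_small.mean_validation_auc[0]
        )

    def test_scores_bounded_and_rows_conserved(self, fitted_small):
        n = len(fitted_small._union.chem_ids)
        for S in fitted_small._layer_scores:
            assert S.shape[0] == n
            assert (0 <= S).all() and (S <= 1).all()

    def test_predict_reproduces_fit_scores(self, fitted_small):
        union = fitted_small._union
        sm = fitted_small.predict(union.X, chem_ids=union.chem_ids)
        np.testing.assert_array_equal(
            sm.scores, fitted_small._layer_scores[fitted_small.best_layer - 1]
        )
        assert sm.layer_index == fitted_small.best_layer

    def test_predict_empty_input(self, fitted_small):
        sm = fitted_small.predict(np.zeros((0, fitted_small.feature_length), np.uint8))
        assert sm.scores.shape == (0, fitted_small.n_tasks)

    def test_predict_width_mismatch(self, fitted_small):
        with pytest.raises(ValidationError):
            fitted_small.predict(np.zeros((3, 5), np.uint8))

    def test_unsplit_without_seed_rejected(self, small_tasks, tiny_params):
        unsplit = [
            TaskDataset(t.task_name, t.chem_ids, t.X, t.y) for t in small_tasks
        ]
        with pytest.raises(ValidationError, match="split_seed"):
            MTForestNet(unsplit, tiny_params).fit()


class TestEvaluate:
    def test_validation_reproduces_stored_trace(self, fitted_small):
        rep = fitted_small.evaluate("validation")
        stored = fitted_small.per_layer_validation_auc[fitted_small.best_layer - 1]
        for name, a in zip(fitted_small.task_order, stored):
            assert rep.per_task_auc[name] == pytest.approx(a, abs=1e-12)

    def test_mean_is_arithmetic_mean_of_defined(self, fitted_small):
        rep = fitted_small.evaluate("test")
        vals = np.array(list(rep.per_task_auc.values()))
        assert rep.mean_auc == pytest.approx(np.nanmean(vals))

    def test_summary_mentions_selected_layer(self, fitted_small):
        s = fitted_small.summary()
        assert "selected" in s and "mean validation AUC" in s


class TestPersistence:
    def test_save_load_round_trip(self, fitted_small, tmp_path):
        d = tmp_path / "model"
        fitted_small.save(d)
        loaded = MTForestNetResults.load(d)
        assert loaded.task_order == fitted_small.task_order
        assert loaded.best_layer == fitted_small.best_layer
        X = fitted_small._union.X
        np.testing.assert_array_equal(
            loaded.predict(X).scores, fitted_small.predict(X).scores
        )

    def test_corrupt_manifest_rejected(self, tmp_path):
        d = tmp_path / "model"
        d.mkdir()
        (d / "manifest.json").write_text("{not json")
        with pytest.raises(ValidationError, match="manifest"):
            MTForestNetResults.load(d)


@pytest.fixture()
def groups(small_tasks):
    return {t.task_name: ("g0" if i < 2 else "g1") for i, t in enumerate(small_tasks)}


class TestAblation:

    def test_excluding_group_drops_its_task_columns(self, small_tasks, groups, tiny_params):
        rep = ablate_dataset(small_tasks, groups, "g1", tiny_params,
                             max_layers=2, split_seed=5)
        assert rep.results.n_tasks == 2
        assert set(rep.task_names) == {t.task_name for t in small_tasks[:2]}

    def test_unknown_group_rejected(self, small_tasks, groups, tiny_params):
        with pytest.raises(ValidationError, match="gX"):
            ablate_dataset(small_tasks, groups, "gX", tiny_params, split_seed=5)

    def test_declared_empty_group_is_noop(self, small_tasks, groups, tiny_params):
        full = MTForestNet(small_tasks, tiny_params).fit(max_layers=2, split_seed=5)
        rep = ablate_dataset(small_tasks, groups, "empty", tiny_params,
                             known_groups=["empty"], max_layers=2, split_seed=5)
        assert rep.mean_test_auc == pytest.approx(full.evaluate("test").mean_auc)
        assert rep.results.n_tasks == full.n_tasks
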