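"""kNN ensemble training, applicability domain, consensus and evaluation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hybridtox as ht
from hybridtox.qhts_io import DescriptorMatrix
from hybridtox.qsar_models import (
    KnnConfig,
    KnnModel,
    calls_from_scores,
    ensemble_from_dict,
    ensemble_to_dict,
    train_knn_ensemble,
)


def _matrix(values, ids=None, names=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"c{i:02d}" for i in range(values.shape[0])]
    names = names or [f"d{j}" for j in range(values.shape[1])]
    return DescriptorMatrix(
        pd.DataFrame(values, index=pd.Index(ids, name="compound_id"), columns=names),
        origin="chemical",
        scaled=True,
    )


def _toy_model(x, y, k=1, ad_cutoff=10.0, names=None):
    x = np.asarray(x, dtype=float)
    names = names or tuple(f"d{j}" for j in range(x.shape[1]))
    return KnnModel(
        descriptor_subset=tuple(names),
        k=k,
        training_ids=tuple(f"t{i}" for i in range(len(x))),
        training_x=x,
        training_labels=np.asarray(y, dtype=int),
        ad_cutoff=ad_cutoff,
        training_ccr=1.0,
    )


def _planted_data(rng, n=60, n_desc=50, n_informative=2):
    """Two descriptors perfectly separate the classes; the rest are noise."""
    y = np.array([i % 2 for i in range(n)])
    x = rng.uniform(0, 1, size=(n, n_desc))
    for j in range(n_informative):
        x[:, j] = y * 0.8 + rng.uniform(0, 0.1, n)
    return _matrix(x), {f"c{i:02d}": int(y[i]) for i in range(n)}


class TestKnnPredict:
    def test_query_on_training_point_returns_its_label_in_ad(self):
        x = [[0.0, 0.0], [1.0, 1.0], [0.0, 1.0]]
        model = _toy_model(x, [0, 1, 1], k=1, ad_cutoff=0.5)
        cls, in_ad = ht.knn_predict(model, np.array([1.0, 1.0]))
        assert cls == 1 and in_ad

    def test_query_far_outside_domain(self):
        model = _toy_model([[0.0, 0.0], [1.0, 0.0]], [0, 1], k=1, ad_cutoff=1.0)
        cls, in_ad = ht.knn_predict(model, np.array([100.0, 100.0]))
        assert not in_ad

    def test_five_point_vote_matches_hand_distance_table(self):
        # query at origin; neighbors at distances 1, 2, 3, 4, 5 with labels
        # 1, 1, 0, 0, 0 -> k=3 neighbors are the first three -> vote 1,1,0 -> 1
        x = np.array([[1.0, 0], [0, 2.0], [3.0, 0], [0, 4.0], [5.0, 0]])
        model = _toy_model(x, [1, 1, 0, 0, 0], k=3, ad_cutoff=100.0)
        cls, in_ad = ht.knn_predict(model, np.array([0.0, 0.0]))
        assert cls == 1 and in_ad

    def test_even_k_tie_broken_by_inverse_distance(self):
        # k=2: neighbors at d=1 (label 1) and d=2 (label 0): weights 1 vs 0.5
        x = np.array([[1.0, 0], [2.0, 0]])
        model = _toy_model(x, [1, 0], k=2, ad_cutoff=100.0)
        cls, _ = ht.knn_predict(model, np.array([0.0, 0.0]))
        assert cls == 1

    def test_exact_weight_tie_calls_nontoxic(self):
        x = np.array([[1.0, 0], [-1.0, 0]])
        model = _toy_model(x, [1, 0], k=2, ad_cutoff=100.0)
        cls, _ = ht.knn_predict(model, np.array([0.0, 0.0]))
        assert cls == 0

    def test_series_input_with_missing_descriptor_rejected(self):
        model = _toy_model([[0.0, 0.0], [1.0, 1.0]], [0, 1], names=("a", "b"))
        with pytest.raises(ValueError, match="lacks"):
            ht.knn_predict(model, pd.Series({"a": 0.5}))


class TestTrainKnnEnsemble:
    def test_planted_informative_descriptors_recovered(self, rng):
        matrix, labels = _planted_data(rng)
        ids = matrix.compound_ids
        splits = [(ids[:40], ids[40:]), (ids[20:], ids[:20])]
        cfg = KnnConfig(
            k_range=(1, 2), subset_size_range=(2, 6), n_proposals=40,
            max_temperatures=8, accept_ccr=0.70, seed=0,
        )
        models = train_knn_ensemble(splits, matrix, labels, cfg)
        assert models
        informative = {"d0", "d1"}
        hits = sum(bool(informative & set(m.descriptor_subset)) for m in models)
        assert hits / len(models) >= 0.9

    def test_unreachable_accept_ccr_keeps_nothing_and_warns(self, rng):
        matrix, labels = _planted_data(rng, n=30)
        ids = matrix.compound_ids
        cfg = KnnConfig(k_range=(1, 1), subset_size_range=(2, 4), n_proposals=10,
                        max_temperatures=2, accept_ccr=1.01, seed=0)
        with pytest.warns(UserWarning, match="no model reached"):
            models = train_knn_ensemble([(ids[:20], ids[20:])], matrix, labels, cfg)
        assert models == []

    def test_single_descriptor_space_matches_exhaustive_search(self, rng):
        # with one descriptor the only possible subset is {d0}; the annealer
        # must return it and the exhaustive-enumeration LOO CCR
        y = np.array([0] * 10 + [1] * 10)
        x = np.c_[np.r_[rng.uniform(0, 0.3, 10), rng.uniform(0.7, 1.0, 10)]]
        matrix = _matrix(x, names=["d0"])
        labels = {c: int(y[i]) for i, c in enumerate(matrix.compound_ids)}
        ids = matrix.compound_ids
        cfg = KnnConfig(k_range=(1, 1), subset_size_range=(1, 1), n_proposals=5,
                        max_temperatures=2, accept_ccr=0.5, seed=0)
        models = train_knn_ensemble([(ids[:14], ids[14:])], matrix, labels, cfg)
        assert len(models) == 1
        assert models[0].descriptor_subset == ("d0",)
        # exhaustive oracle: LOO with k=1 on the single descriptor
        from hybridtox.qsar_models import _loo_ccr

        assert models[0].training_ccr == pytest.approx(_loo_ccr(x[:14], y[:14], 1))

    def test_training_point_self_prediction_at_k1(self, rng):
        matrix, labels = _planted_data(rng, n=30)
        ids = matrix.compound_ids
        cfg = KnnConfig(k_range=(1, 1), subset_size_range=(2, 4), n_proposals=20,
                        max_temperatures=4, accept_ccr=0.6, seed=1)
        models = train_knn_ensemble([(ids[:20], ids[20:])], matrix, labels, cfg)
        assert models
        m = models[0]
        for i, cid in enumerate(m.training_ids):
            cls, in_ad = ht.knn_predict(m, m.training_x[i])
            assert cls == labels[cid] and in_ad

    def test_single_class_split_rejected(self, rng):
        matrix, labels = _planted_data(rng, n=20)
        all_zero = {c: 0 for c in labels}
        ids = matrix.compound_ids
        with pytest.raises(ValueError, match="single class"):
            train_knn_ensemble([(ids[:10], ids[10:])], matrix, all_zero, KnnConfig())


class TestRandomForest:
    def test_separable_data_fits_perfectly(self, rng):
        matrix, labels = _planted_data(rng, n=40)
        model = ht.train_random_forest(matrix, labels, n_trees=50, seed=0)
        scores = model.predict_scores(matrix)
        preds = (scores > 0.5).astype(int)
        assert all(preds[c] == labels[c] for c in labels)

    def test_seeded_runs_identical(self, rng):
        matrix, labels = _planted_data(rng, n=40)
        a = ht.train_random_forest(matrix, labels, n_trees=30, seed=5).predict_scores(matrix)
        b = ht.train_random_forest(matrix, labels, n_trees=30, seed=5).predict_scores(matrix)
        assert np.allclose(a, b)

    def test_planted_descriptors_rank_top_decile_importance(self, rng):
        matrix, labels = _planted_data(rng, n=80, n_desc=50)
        model = ht.train_random_forest(matrix, labels, n_trees=200, seed=0)
        top5 = set(model.importances.index[:5])
        assert {"d0", "d1"} <= top5

    def test_single_class_rejected(self, rng):
        matrix, _ = _planted_data(rng, n=20)
        with pytest.raises(ValueError, match="both classes"):
            ht.train_random_forest(matrix, {c: 1 for c in matrix.compound_ids})


class TestConsensus:
    def test_unanimous_models_score_one(self):
        x = [[0.0, 0.0], [1.0, 1.0]]
        models = [_toy_model(x, [1, 1], k=1) for _ in range(3)]
        pred = ht.consensus_predict(models, np.array([0.0, 0.0]), "q")
        assert pred.score == 1.0 and pred.call == "toxic"

    def test_three_of_four_covering_vote_one(self):
        votes_one = _toy_model([[0.0, 0.0], [5.0, 5.0]], [1, 0], k=1, ad_cutoff=1.0)
        votes_zero = _toy_model([[0.0, 0.0], [5.0, 5.0]], [0, 1], k=1, ad_cutoff=1.0)
        uncovering = _toy_model([[50.0, 50.0], [60.0, 60.0]], [0, 0], k=1, ad_cutoff=1.0)
        pred = ht.consensus_predict(
            [votes_one, votes_one, votes_one, votes_zero, uncovering],
            np.array([0.0, 0.0]),
            "q",
        )
        assert pred.n_models_covering == 4
        assert pred.score == pytest.approx(0.75)

    def test_compound_outside_every_domain_not_covered(self):
        m = _toy_model([[0.0, 0.0], [1.0, 1.0]], [0, 1], k=1, ad_cutoff=0.1)
        pred = ht.consensus_predict([m], np.array([50.0, 50.0]), "q")
        assert pred.call == "not_covered" and pred.score is None and pred.n_models_covering == 0

    def test_identical_models_equal_single_model(self, rng):
        x = rng.uniform(size=(10, 3))
        y = [i % 2 for i in range(10)]
        m = _toy_model(x, y, k=3, ad_cutoff=5.0)
        q = rng.uniform(size=3)
        single, _ = ht.knn_predict(m, q)
        pred = ht.consensus_predict([m] * 7, q)
        assert pred.score == float(single)

    def test_batch_scores_agree_with_per_compound_calls(self, rng):
        x = rng.uniform(size=(12, 4))
        y = [i % 2 for i in range(12)]
        models = [
            _toy_model(x, y, k=k, ad_cutoff=0.8, names=("d0", "d1", "d2", "d3"))
            for k in (1, 2, 3)
        ]
        queries = _matrix(rng.uniform(size=(6, 4)), names=["d0", "d1", "d2", "d3"])
        scores, cover = ht.consensus_scores(models, queries)
        for i, cid in enumerate(queries.compound_ids):
            pred = ht.consensus_predict(models, queries.values[i], cid)
            if pred.score is None:
                assert np.isnan(scores[cid]) and cover[cid] == 0
            else:
                assert scores[cid] == pytest.approx(pred.score)
                assert cover[cid] == pred.n_models_covering


class TestPooledConsensus:
    def test_mean_of_both_learners_with_nan_fallback(self):
        from hybridtox.qsar_models import pooled_consensus

        knn = pd.Series({"a": 1.0, "b": np.nan, "c": 0.2})
        rf = pd.Series({"a": 0.5, "b": 0.8, "c": 0.4})
        pooled = pooled_consensus(knn, rf)
        assert pooled["a"] == pytest.approx(0.75)
        assert pooled["b"] == pytest.approx(0.8)  # uncovered by kNN -> forest alone
        assert pooled["c"] == pytest.approx(0.3)


class TestClassifyWithThresholds:
    @pytest.mark.parametrize(
        "score,t1,t2,expected",
        [
            (0.75, 0.3, 0.7, "toxic"),
            (0.2, 0.3, 0.7, "nontoxic"),
            (0.5, 0.3, 0.7, "inconclusive"),
            (0.3, 0.3, 0.7, "nontoxic"),
            (0.7, 0.3, 0.7, "toxic"),
            (0.5, 0.5, 0.5, "inconclusive"),
            (0.51, 0.5, 0.5, "toxic"),
            (0.49, 0.5, 0.5, "nontoxic"),
        ],
    )
    def test_threshold_semantics(self, score, t1, t2, expected):
        assert ht.classify_with_thresholds(score, t1, t2) == expected

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ht.classify_with_thresholds(0.5, 0.7, 0.3)

    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_elementwise_comparison_oracle(self, score, a, b):
        t1, t2 = min(a, b), max(a, b)
        call = ht.classify_with_thresholds(score, t1, t2)
        if t1 == t2:
            expected = "nontoxic" if score < t1 else "toxic" if score > t2 else "inconclusive"
        else:
            expected = "nontoxic" if score <= t1 else "toxic" if score >= t2 else "inconclusive"
        assert call == expected


class TestEvaluate:
    def test_table_style_arithmetic(self):
        # 11 toxic of which 10 called toxic; 41 nontoxic of which 35 called
        # nontoxic -> sens 0.91, spec 0.85, CCR 0.88 (to two decimals)
        calls, truth = {}, {}
        for i in range(11):
            calls[f"t{i}"] = "toxic" if i < 10 else "nontoxic"
            truth[f"t{i}"] = 1
        for i in range(41):
            calls[f"n{i}"] = "nontoxic" if i < 35 else "toxic"
            truth[f"n{i}"] = 0
        report = ht.evaluate(calls, truth)
        assert round(report.sensitivity, 2) == 0.91
        assert round(report.specificity, 2) == 0.85
        assert round(report.ccr, 2) == 0.88
        assert report.ccr == pytest.approx(0.5 * (report.sensitivity + report.specificity))

    def test_perfect_predictions(self):
        calls = {"a": "toxic", "b": "nontoxic"}
        truth = {"a": 1, "b": 0}
        report = ht.evaluate(calls, truth)
        assert report.ccr == 1.0 and report.coverage == 1.0

    def test_random_calls_near_half_ccr(self, rng):
        n = 1000
        truth = {f"c{i}": i % 2 for i in range(n)}
        calls = {c: ("toxic" if rng.random() < 0.5 else "nontoxic") for c in truth}
        report = ht.evaluate(calls, truth)
        assert abs(report.ccr - 0.5) < 0.05

    def test_coverage_excludes_inconclusive_and_uncovered(self):
        calls = {"a": "toxic", "b": "inconclusive", "c": "not_covered", "d": "nontoxic"}
        truth = {"a": 1, "b": 1, "c": 0, "d": 0}
        report = ht.evaluate(calls, truth)
        assert report.coverage == 0.5
        assert report.ccr == 1.0  # both conclusive calls correct

    def test_absent_class_reported_undefined(self):
        report = ht.evaluate({"a": "toxic"}, {"a": 1})
        assert report.sensitivity == 1.0 and report.specificity is None and report.ccr is None

    def test_ccr_identity_on_random_reports(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 40))
            truth = {f"c{i}": int(rng.integers(2)) for i in range(n)}
            opts = ["toxic", "nontoxic", "inconclusive", "not_covered"]
            calls = {c: opts[rng.integers(4)] for c in truth}
            try:
                report = ht.evaluate(calls, truth)
            except ValueError:
                continue
            if report.ccr is not None:
                assert abs(report.ccr - 0.5 * (report.sensitivity + report.specificity)) < 1e-12


class TestThresholdHeatmap:
    def _scores_truth(self, rng, n=40):
        truth = {f"c{i}": i % 2 for i in range(n)}
        scores = pd.Series(
            {c: float(np.clip(t * 0.6 + rng.normal(0.2, 0.25), 0, 1)) for c, t in truth.items()}
        )
        scores.iloc[:3] = np.nan  # a few uncovered compounds
        return scores, truth

    def test_diagonal_reproduces_single_threshold_evaluate(self, rng):
        scores, truth = self._scores_truth(rng)
        grids = ht.threshold_heatmap(scores, truth, grid_step=0.25)
        for i, t in enumerate(grids.thresholds):
            report = ht.evaluate(calls_from_scores(scores, float(t), float(t)), truth)
            assert grids.coverage[i, i] == pytest.approx(report.coverage)
            if report.ccr is None:
                assert np.isnan(grids.ccr[i, i])
            else:
                assert grids.ccr[i, i] == pytest.approx(report.ccr)

    def test_widening_never_increases_coverage(self, rng):
        scores, truth = self._scores_truth(rng)
        grids = ht.threshold_heatmap(scores, truth, grid_step=0.1)
        n = len(grids.thresholds)
        for i in range(n):
            for j in range(i, n):
                if i > 0:  # widen downward
                    assert grids.coverage[i - 1, j] <= grids.coverage[i, j] + 1e-12
                if j < n - 1:  # widen upward
                    assert grids.coverage[i, j + 1] <= grids.coverage[i, j] + 1e-12

    def test_cells_match_brute_force_recomputation(self, rng):
        scores, truth = self._scores_truth(rng, n=12)
        grids = ht.threshold_heatmap(scores, truth, grid_step=0.5)
        for i, t1 in enumerate(grids.thresholds):
            for j, t2 in enumerate(grids.thresholds):
                if t1 > t2:
                    assert np.isnan(grids.ccr[i, j]) and np.isnan(grids.coverage[i, j])
                    continue
                report = ht.evaluate(calls_from_scores(scores, float(t1), float(t2)), truth)
                assert grids.coverage[i, j] == pytest.approx(report.coverage)


class TestEnsembleSerialization:
    def test_round_trip(self, rng):
        x = rng.uniform(size=(8, 3))
        y = [i % 2 for i in range(8)]
        models = [_toy_model(x, y, k=k, names=("a", "b", "c")) for k in (1, 3)]
        doc = ensemble_to_dict(models, meta={"seed": 1})
        back = ensemble_from_dict(doc)
        q = rng.uniform(size=3)
        for m0, m1 in zip(models, back):
            assert ht.knn_predict(m0, q) == ht.knn_predict(m1, q)
            assert m0.descriptor_subset == m1.descriptor_subset
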