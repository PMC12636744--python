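import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from vaxbiome import ml
from vaxbiome import synthetic as syn
from vaxbiome.errors import ValidationError

FAST_FOREST = ml.ForestSettings(n_trees=60, seed=1)


def planted_dataset(seed=5, n=80, n_taxa=60, n_signal=20, lfc=2.0,
                    cohort="cohort01"):
    spec = syn.SimulationSpec(
        n_cohorts=3, n_samples_per_cohort=n, n_taxa=n_taxa,
        n_signal_taxa=n_signal, log_fold_change=lfc, cohort_batch_sd=0.2,
        n_genes=10, n_signal_genes=2, seed=seed)
    cs = syn.generate_cohort_set(spec)
    X = cs.abundance[cohort].values
    y = cs.truth.cluster_labels[cohort]
    return cs, X, y


class TestRocAuc:
    def test_perfect_ranking(self):
        assert ml.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert ml.roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_inverted_ranking_zero(self):
        assert ml.roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            ml.roc_auc([0.1, 0.2], [1, 1])

    def test_matches_trapezoidal_integration(self, rng):
        # Mann-Whitney formulation vs sklearn's trapezoidal ROC AUC
        for _ in range(20):
            y = rng.integers(0, 2, size=50)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(50), 2)  # force ties
            assert ml.roc_auc(s, y) == pytest.approx(
                roc_auc_score(y, s), abs=1e-12)


class TestRepeatedCv:
    def test_separable_signal_high_auc(self):
        _, X, y = planted_dataset()
        scheme = ml.EvaluationScheme(folds=5, repetitions=3, seed=7)
        cv = ml.repeated_cv(X.to_numpy(), y.to_numpy(), scheme, FAST_FOREST)
        assert cv.mean_auc >= 0.9

    def test_permuted_labels_null_auc(self, rng):
        _, X, y = planted_dataset()
        y_perm = rng.permutation(y.to_numpy())
        scheme = ml.EvaluationScheme(folds=5, repetitions=10, seed=7)
        cv = ml.repeated_cv(X.to_numpy(), y_perm, scheme, FAST_FOREST)
        assert 0.43 <= cv.mean_auc <= 0.57

    def test_deterministic_under_seed(self):
        _, X, y = planted_dataset()
        scheme = ml.EvaluationScheme(folds=5, repetitions=2, seed=3)
        a = ml.repeated_cv(X.to_numpy(), y.to_numpy(), scheme, FAST_FOREST)
        b = ml.repeated_cv(X.to_numpy(), y.to_numpy(), scheme, FAST_FOREST)
        assert a.aucs == b.aucs

    def test_infeasible_stratification_message(self):
        X = np.random.default_rng(0).random((12, 4))
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        scheme = ml.EvaluationScheme(folds=5, repetitions=1)
        with pytest.raises(ValidationError, match="folds"):
            ml.repeated_cv(X, y, scheme, FAST_FOREST)


class TestFeatureRanking:
    def test_perfect_separator_ranked_first(self, rng):
        n = 60
        y = np.array([0] * 30 + [1] * 30)
        X = rng.random((n, 10))
        X[:, 4] = y * 10.0 + rng.random(n) * 0.01
        order = ml.rank_features_training_only(X, y, FAST_FOREST)
        assert order[0] == 4

    def test_ranking_never_touches_test_labels(self, rng):
        # mutation test: corrupting held-out labels leaves rankings identical
        _, X, y = planted_dataset()
        X, y = X.to_numpy(), y.to_numpy()
        tr, te = np.arange(0, 60), np.arange(60, 80)
        before = ml.rank_features_training_only(X[tr], y[tr], FAST_FOREST,
                                                random_state=11)
        y_corrupt = y.copy()
        y_corrupt[te] = rng.integers(0, 2, size=len(te))
        after = ml.rank_features_training_only(X[tr], y_corrupt[tr],
                                               FAST_FOREST, random_state=11)
        np.testing.assert_array_equal(before, after)

    def test_column_shuffle_preserves_top_features(self, rng):
        # exact order invariance is unattainable: the forest draws its
        # random feature subsets by column position, so permuting columns
        # reshuffles tree construction; the top of the ranking (by feature
        # id) must nevertheless be stable
        _, X, y = planted_dataset()
        settings = ml.ForestSettings(n_trees=400, seed=1)
        order = ml.rank_features_training_only(X.to_numpy(), y.to_numpy(),
                                               settings, random_state=2)
        perm = rng.permutation(X.shape[1])
        Xp = X.to_numpy()[:, perm]
        order_p = ml.rank_features_training_only(Xp, y.to_numpy(),
                                                 settings, random_state=2)
        ids = list(X.columns)
        top_before = [ids[i] for i in order[:10]]
        top_after = [ids[perm[i]] for i in order_p[:10]]
        assert top_before[0] == top_after[0]
        assert len(set(top_before) & set(top_after)) >= 8

    def test_aggregate_rankings(self):
        orders = [np.array([0, 1, 2]), np.array([1, 0, 2])]
        agg = ml.aggregate_rankings(orders, 3)
        assert agg.tolist() == [0, 1, 2]


class TestTopkCv:
    def test_topk_full_equals_plain_cv(self):
        _, X, y = planted_dataset()
        scheme = ml.EvaluationScheme(folds=5, repetitions=2, seed=9)
        plain = ml.repeated_cv(X.to_numpy(), y.to_numpy(), scheme, FAST_FOREST)
        scheme_k = ml.EvaluationScheme(folds=5, repetitions=2, seed=9,
                                       top_k=X.shape[1])
        topk = ml.topk_cv(X.to_numpy(), y.to_numpy(), scheme_k, FAST_FOREST)
        assert topk.aucs == plain.aucs

    def test_topk_selection_enriched_in_planted(self):
        cs, X, y = planted_dataset(n=100)
        planted = {list(X.columns).index(t) for t in cs.truth.signal_taxa}
        rankings: list[np.ndarray] = []
        scheme = ml.EvaluationScheme(folds=5, repetitions=2, seed=4, top_k=30)
        ml.topk_cv(X.to_numpy(), y.to_numpy(), scheme, FAST_FOREST,
                   collect_rankings=rankings)
        hits = [len(set(order[:30]) & planted) for order in rankings]
        assert np.mean(hits) >= 15

    def test_topk_too_large_rejected(self):
        _, X, y = planted_dataset()
        scheme = ml.EvaluationScheme(folds=5, repetitions=1,
                                     top_k=X.shape[1] + 1)
        with pytest.raises(ValidationError, match="top_k"):
            ml.topk_cv(X.to_numpy(), y.to_numpy(), scheme, FAST_FOREST)


def cohort_datasets(cs):
    matrices = ml.harmonize_features(
        {c: t for c, t in cs.abundance.items()}, how="union")
    return {c: (matrices[c], cs.truth.cluster_labels[c])
            for c in cs.abundance}


class TestLodo:
    def test_shared_signal_transfers(self):
        cs, _, _ = planted_dataset(n=100)
        datasets = cohort_datasets(cs)
        aucs = ml.lodo(datasets, FAST_FOREST)
        assert all(a >= 0.85 for a in aucs.values())

    def test_permuted_holdout_null(self, rng):
        cs, _, _ = planted_dataset(n=100)
        datasets = cohort_datasets(cs)
        held = "cohort01"
        X, y = datasets[held]
        datasets[held] = (X, pd.Series(rng.permutation(y.to_numpy()),
                                       index=y.index))
        auc = ml.lodo(datasets, FAST_FOREST)[held]
        assert 0.3 <= auc <= 0.7

    def test_two_cohorts_equals_train_test(self):
        cs, _, _ = planted_dataset()
        datasets = cohort_datasets(cs)
        two = {c: datasets[c] for c in list(datasets)[:2]}
        aucs = ml.lodo(two, FAST_FOREST)
        c1, c2 = list(two)
        assert aucs[c1] == ml.train_test_auc(two[c2], two[c1], FAST_FOREST)
        assert aucs[c2] == ml.train_test_auc(two[c1], two[c2], FAST_FOREST)

    def test_feature_mismatch_detected(self):
        cs, _, _ = planted_dataset()
        datasets = cohort_datasets(cs)
        c1 = list(datasets)[0]
        X, y = datasets[c1]
        datasets[c1] = (X.iloc[:, :-1], y)
        with pytest.raises(ValidationError, match="feature space"):
            ml.lodo(datasets, FAST_FOREST)


class TestXlodo:
    def test_single_cohort_degenerates_to_cv(self):
        _, X, y = planted_dataset()
        scheme = ml.EvaluationScheme(folds=5, repetitions=2, seed=6)
        plain = ml.repeated_cv(X.to_numpy(), y.to_numpy(), scheme, FAST_FOREST)
        xl = ml.xlodo({"only": (X, y)}, scheme, FAST_FOREST)["only"]
        assert xl.aucs == plain.aucs

    def test_informative_augmentation_does_not_hurt(self):
        cs, X, y = planted_dataset(n=60)
        datasets = cohort_datasets(cs)
        scheme = ml.EvaluationScheme(folds=5, repetitions=3, seed=8)
        plain = ml.repeated_cv(X.to_numpy(), y.to_numpy(), scheme, FAST_FOREST)
        xl = ml.xlodo(datasets, scheme, FAST_FOREST)["cohort01"]
        assert xl.mean_auc >= plain.mean_auc - 0.05

    def test_noise_augmentation_close_to_plain_cv(self, rng):
        cs, X, y = planted_dataset(n=60)
        datasets = cohort_datasets(cs)
        for c in datasets:
            if c != "cohort01":
                Xc, yc = datasets[c]
                datasets[c] = (Xc, pd.Series(rng.permutation(yc.to_numpy()),
                                             index=yc.index))
        scheme = ml.EvaluationScheme(folds=5, repetitions=3, seed=8)
        plain = ml.repeated_cv(X.to_numpy(), y.to_numpy(), scheme, FAST_FOREST)
        xl = ml.xlodo(datasets, scheme, FAST_FOREST)["cohort01"]
        assert abs(xl.mean_auc - plain.mean_auc) <= 0.15


class TestCrossPredictionMatrix:
    def test_structure_and_range(self):
        cs, _, _ = planted_dataset(n=60)
        datasets = cohort_datasets(cs)
        scheme = ml.EvaluationScheme(folds=5, repetitions=2, seed=2)
        m = ml.cross_prediction_matrix(datasets, scheme, FAST_FOREST)
        assert list(m.auc.index) == m.cohorts + ["LODO", "X-LODO"]
        assert list(m.auc.columns) == m.cohorts
        vals = m.auc.to_numpy()
        assert np.isfinite(vals).all()
        assert (vals >= 0).all() and (vals <= 1).all()

    def test_deterministic(self):
        cs, _, _ = planted_dataset(n=60)
        datasets = cohort_datasets(cs)
        scheme = ml.EvaluationScheme(folds=5, repetitions=2, seed=2)
        a = ml.cross_prediction_matrix(datasets, scheme, FAST_FOREST)
        b = ml.cross_prediction_matrix(datasets, scheme, FAST_FOREST)
        pd.testing.assert_frame_equal(a.auc, b.auc)

    def test_covariates_only_near_chance(self, rng):
        # covariates independent of the cluster: every entry ~ 0.5
        cs, _, _ = planted_dataset(n=80)
        datasets = {}
        for c in cs.metadata:
            md = cs.metadata[c].data
            X = pd.DataFrame({
                "age": md["age"].to_numpy(),
                "sex": (md["sex"] == "F").astype(float).to_numpy()},
                index=md.index)
            datasets[c] = (X, cs.truth.cluster_labels[c])
        scheme = ml.EvaluationScheme(folds=5, repetitions=2, seed=2)
        settings = ml.ForestSettings(n_trees=60, feature_fraction=1.0, seed=1)
        m = ml.cross_prediction_matrix(datasets, scheme, settings)
        vals = m.auc.to_numpy()
        # individual entries are noisy with 2 useless features; the grid as
        # a whole must hover around chance
        assert 0.4 <= vals.mean() <= 0.6
        assert np.abs(vals - 0.5).max() <= 0.3

    def test_small_cohort_fold_override(self):
        cs, _, _ = planted_dataset(n=60)
        datasets = cohort_datasets(cs)
        scheme = ml.EvaluationScheme(folds=10, repetitions=1, seed=2)
        m = ml.cross_prediction_matrix(
            datasets, scheme, FAST_FOREST,
            small_cohort_folds={"cohort01": 5})
        assert np.isfinite(m.auc.to_numpy()).all()


class TestHarmonize:
    def test_union_imputes_zeros(self, small_cohorts):
        tables = dict(small_cohorts.abundance)
        t1 = tables["cohort01"]
        tables["cohort01"] = type(t1)(
            values=t1.values.iloc[:, :-5], taxonomy=t1.taxonomy)
        out = ml.harmonize_features(tables, how="union")
        cols = {tuple(v.columns) for v in out.values()}
        assert len(cols) == 1
        dropped = t1.values.columns[-5:]
        assert (out["cohort01"][dropped] == 0).all().all()

    def test_intersection(self, small_cohorts):
        out = ml.harmonize_features(dict(small_cohorts.abundance),
                                    how="intersection")
        cols = {tuple(v.columns) for v in out.values()}
        assert len(cols) == 1
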