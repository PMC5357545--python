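"""Circulating filter, LDA, LOOCV and the exhaustive panel search."""

import numpy as np
import pytest

from mirspec import (
    CohortConfig,
    evaluate_combination,
    filter_circulating,
    generate_cohort,
    generate_circulating_catalog,
    lda_fit,
    lda_predict,
    loocv_accuracy,
    pair_fold_change_features,
    search_combinations,
)


class TestFilterCirculating:
    def test_keeps_only_plasma_serum(self):
        catalog = {"B": "plasma", "C": "exosome", "D": "serum"}
        assert filter_circulating({"A", "B", "C"}, catalog) == {"B"}

    def test_empty_catalog(self):
        assert filter_circulating({"A", "B"}, {}) == set()

    def test_exosome_only_entry_excluded(self):
        assert filter_circulating({"X"}, {"X": "exosome"}) == set()


@pytest.fixture(scope="module")
def cohort():
    matrix, _ = generate_cohort(
        CohortConfig(n_cancer_types=2, n_pairs_per_type=6, n_mirnas=20, seed=2)
    )
    return matrix


@pytest.fixture(scope="module")
def strong_cohort():
    cfg = CohortConfig(
        n_cancer_types=3, n_pairs_per_type=15, n_mirnas=120,
        frac_de=0.2, frac_specific=0.1, effect_log2fc=3.0, seed=21,
    )
    matrix, truth = generate_cohort(cfg)
    catalog = generate_circulating_catalog(truth, frac_covered=1.0, seed=22)
    return matrix, truth, catalog


class TestPairFoldChangeFeatures:
    def test_one_row_per_pair(self, cohort):
        feats = pair_fold_change_features(cohort, "BRCA", cohort.mirna_ids[:3])
        assert feats.shape == (6, 3)

    def test_scalar_fold_change_values(self, cohort):
        mid = cohort.mirna_ids[0]
        tumor_ids, normal_ids = cohort.paired_samples("BRCA")
        matrix = cohort.subset_samples(cohort.sample_ids)
        matrix.values.loc[mid, tumor_ids] = 4.0
        matrix.values.loc[mid, normal_ids] = 2.0
        feats = pair_fold_change_features(matrix, "BRCA", [mid])
        np.testing.assert_allclose(feats[mid], 1.0)

    def test_equal_pairs_give_zero(self, cohort):
        mid = cohort.mirna_ids[1]
        tumor_ids, normal_ids = cohort.paired_samples("BRCA")
        matrix = cohort.subset_samples(cohort.sample_ids)
        matrix.values.loc[mid, tumor_ids] = matrix.values.loc[mid, normal_ids].to_numpy()
        feats = pair_fold_change_features(matrix, "BRCA", [mid])
        np.testing.assert_allclose(feats[mid], 0.0)


class TestLDA:
    def test_separable_means_train_perfectly(self, rng):
        X = np.r_[rng.normal(-10, 1, (20, 1)), rng.normal(10, 1, (20, 1))]
        y = np.r_[np.zeros(20), np.ones(20)]
        model = lda_fit(X, y)
        assert np.mean(lda_predict(model, X) == y) == 1.0

    def test_identical_distributions_follow_larger_prior(self, rng):
        X = np.zeros((12, 1))
        y = np.r_[np.zeros(8), np.ones(4)]
        model = lda_fit(X + rng.normal(0, 1e-9, X.shape), y)
        assert (lda_predict(model, np.zeros((5, 1))) == 0).all()

    def test_duplicated_feature_column_tolerated(self, rng):
        x = rng.normal(size=(20, 1))
        X = np.hstack([x, x])  # singular without the ridge
        y = (x[:, 0] > 0).astype(int)
        model = lda_fit(X, y)
        assert np.isfinite(model.covariance).all()
        lda_predict(model, X)

    def test_matches_sklearn_predictions(self, rng):
        sklearn_lda = pytest.importorskip("sklearn.discriminant_analysis")
        X = rng.normal(size=(40, 3)) + np.r_[np.zeros((20, 3)), np.ones((20, 3))]
        y = np.r_[np.zeros(20), np.ones(20)]
        model = lda_fit(X, y, ridge=1e-10)
        ref = sklearn_lda.LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        assert (lda_predict(model, X) == ref.predict(X)).all()

    def test_class_with_one_sample_rejected(self):
        with pytest.raises(ValueError):
            lda_fit(np.zeros((3, 1)), np.array([0, 1, 1]))


class TestLOOCV:
    def test_equals_naive_refit(self, rng):
        done = 0
        while done < 10:
            n, d = int(rng.integers(8, 25)), int(rng.integers(1, 5))
            X = rng.normal(size=(n, d))
            y = rng.integers(0, 2, n)
            if min((y == 0).sum(), (y == 1).sum()) < 3:
                continue
            fast = loocv_accuracy(X, y)
            preds = []
            for i in range(n):
                mask = np.ones(n, bool)
                mask[i] = False
                preds.append(lda_predict(lda_fit(X[mask], y[mask]), X[i : i + 1])[0])
            assert fast == pytest.approx(np.mean(np.array(preds) == y), abs=1e-12)
            done += 1

    def test_perfectly_separated_classes(self, rng):
        X = np.r_[rng.normal(-10, 1, (10, 1)), rng.normal(10, 1, (10, 1))]
        y = np.r_[np.zeros(10), np.ones(10)]
        assert loocv_accuracy(X, y) == 1.0

    def test_permuted_labels_near_chance(self, rng):
        accs = []
        for _ in range(20):
            X = np.r_[rng.normal(-10, 1, (10, 1)), rng.normal(10, 1, (10, 1))]
            y = rng.permutation(np.r_[np.zeros(10), np.ones(10)])
            accs.append(loocv_accuracy(X, y))
        assert 0.3 <= np.mean(accs) <= 0.7

    def test_bounded_and_row_order_invariant(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.integers(0, 2, 30)
        acc = loocv_accuracy(X, y)
        assert 0.0 <= acc <= 1.0
        perm = rng.permutation(30)
        assert loocv_accuracy(X[perm], y[perm]) == pytest.approx(acc)

    def test_confusion_counts_conserve_n(self, rng):
        # (TP+TN)/N accuracy implies TP+TN+FP+FN = N; check via complements
        X = rng.normal(size=(24, 2))
        y = rng.integers(0, 2, 24)
        acc = loocv_accuracy(X, y)
        n_correct = round(acc * 24)
        n_wrong = round((1 - acc) * 24)
        assert n_correct + n_wrong == 24

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            loocv_accuracy(np.zeros((3, 1)), np.array([0, 0, 1]))


class TestEvaluateAndSearch:
    def test_mean_accuracy_is_average(self, strong_cohort):
        matrix, truth, _ = strong_cohort
        c = matrix.cancer_types[0]
        mid = sorted(truth.specific_mirnas[c])[0]
        res = evaluate_combination(matrix, c, [mid])
        assert res.mean_accuracy == pytest.approx((res.accuracy1 + res.accuracy2) / 2, abs=1e-12)
        assert 0.0 <= res.accuracy1 <= 1.0 and 0.0 <= res.accuracy2 <= 1.0

    def test_single_strong_marker_classifies_well(self, strong_cohort):
        matrix, truth, _ = strong_cohort
        c = matrix.cancer_types[0]
        mid = sorted(truth.specific_mirnas[c])[0]
        res = evaluate_combination(matrix, c, [mid])
        assert res.mean_accuracy >= 0.9

    def test_unknown_mirna_rejected(self, strong_cohort):
        matrix, _, _ = strong_cohort
        with pytest.raises(ValueError, match="absent"):
            evaluate_combination(matrix, matrix.cancer_types[0], ["MIMAT9999999"])

    def test_combination_count_for_six_candidates(self, strong_cohort):
        matrix, truth, _ = strong_cohort
        c = matrix.cancer_types[0]
        cands = sorted(truth.specific_mirnas[c])[:4] + sorted(truth.de_ids(c) - truth.specific_mirnas[c])[:2]
        ranked = search_combinations(matrix, c, cands, k_max=5)
        assert len(ranked) == 6 + 15 + 20 + 15 + 6

    def test_single_candidate_single_combination(self, strong_cohort):
        matrix, truth, _ = strong_cohort
        c = matrix.cancer_types[0]
        ranked = search_combinations(matrix, c, sorted(truth.specific_mirnas[c])[:1])
        assert len(ranked) == 1

    def test_rerun_is_deterministic(self, strong_cohort):
        matrix, truth, _ = strong_cohort
        c = matrix.cancer_types[0]
        cands = sorted(truth.specific_mirnas[c])
        r1 = search_combinations(matrix, c, cands, k_max=3)
        r2 = search_combinations(matrix, c, cands, k_max=3)
        assert [(r.mirna_ids, r.mean_accuracy) for r in r1] == [
            (r.mirna_ids, r.mean_accuracy) for r in r2
        ]

    def test_empty_candidates_rejected(self, strong_cohort):
        matrix, _, _ = strong_cohort
        with pytest.raises(ValueError, match="empty"):
            search_combinations(matrix, matrix.cancer_types[0], [])

    def test_noise_mirna_barely_moves_accuracy(self, strong_cohort):
        matrix, truth, _ = strong_cohort
        c = matrix.cancer_types[0]
        mid = sorted(truth.specific_mirnas[c])[0]
        noise = sorted(set(matrix.mirna_ids) - truth.de_ids(c))[0]
        base = evaluate_combination(matrix, c, [mid]).mean_accuracy
        with_noise = evaluate_combination(matrix, c, [mid, noise]).mean_accuracy
        assert abs(base - with_noise) < 0.15

    def test_top_panel_recovers_planted_markers(self, strong_cohort):
        """With 3 planted circulating specifics, the best panel keeps >= 2."""
        matrix, truth, catalog = strong_cohort
        for c in matrix.cancer_types:
            planted = sorted(truth.specific_mirnas[c])[:3]
            cands = filter_circulating(set(planted), catalog) | set(
                sorted(truth.de_ids(c) - truth.specific_mirnas[c])[:3]
            )
            ranked = search_combinations(matrix, c, cands, k_max=3)
            assert len(set(ranked[0].mirna_ids) & set(planted)) >= 2
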