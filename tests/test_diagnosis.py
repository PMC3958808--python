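import itertools
import math

import numpy as np
import pytest
from sklearn.naive_bayes import GaussianNB as SkGaussianNB

from fitcloud.cohort import CohortSpec, generate_cohort
from fitcloud.diagnosis import (
    LABELS,
    TESTS,
    ConfusionCounts,
    GaussianNBClassifier,
    KNNClassifier,
    LDAClassifier,
    LabeledDataset,
    RawRecord,
    confusion,
    evaluate_all,
    kfold_cv,
    load_models,
    macro_average,
    precision_recall_f1,
    predict_json,
    preprocess,
    save_models,
    train_models,
)
from fitcloud.errors import (
    DegenerateModelError,
    DomainError,
    StratificationError,
    ValidationError,
)


WORKED_RECORD = RawRecord(
    gender=0, age=25, weight=50, bmi=25,
    flexibility=29.4, reaction_time=501, grip_strength=12.2, balance=5.86,
)


class TestPreprocess:
    def test_worked_female_record_encodes_in_fixed_order(self):
        vector = preprocess(WORKED_RECORD)
        assert vector.tolist() == [0, 25, 50, 25, 29.4, 501, 12.2, 5.86]

    def test_male_flag_in_first_position(self):
        vector = preprocess(
            RawRecord(gender=1, age=70, weight=68, bmi=23,
                      flexibility=20, reaction_time=600, grip_strength=30, balance=4)
        )
        assert vector[0] == 1.0

    @pytest.mark.parametrize(
        "field,value", [("gender", 2), ("age", float("nan")), ("weight", -1),
                        ("balance", float("inf"))]
    )
    def test_invalid_records_rejected(self, field, value):
        record = RawRecord(**{**WORKED_RECORD.__dict__, field: value})
        with pytest.raises(ValidationError):
            preprocess(record)


def _two_class_blobs(n=20, gap=20.0, sd=0.1, seed=0):
    rng = np.random.default_rng(seed)
    X = np.concatenate([rng.normal(-gap / 2, sd, n), rng.normal(gap / 2, sd, n)])
    y = np.array(["weak"] * n + ["strong"] * n)
    return X[:, None], y


class TestGaussianNB:
    def test_separated_classes_fit_perfectly(self):
        X, y = _two_class_blobs()
        model = GaussianNBClassifier().fit(X, y)
        assert np.array_equal(model.predict(X), y)

    def test_balanced_classes_give_uniform_priors(self):
        X, y = _two_class_blobs()
        model = GaussianNBClassifier().fit(X, y)
        assert model.priors_ == pytest.approx([0.5, 0.5])

    def test_posterior_at_class_mean_exceeds_prior(self):
        # Two points, one per class: direct Bayes-rule arithmetic says the
        # posterior of the nearer class at its own mean beats its 0.5 prior.
        X = np.array([[0.0], [4.0]])
        y = np.array(["weak", "strong"])
        model = GaussianNBClassifier().fit(X, y)
        proba = model.predict_proba(np.array([[0.0]]))[0]
        weak_idx = model.classes_.index("weak")
        assert proba[weak_idx] > 0.5

    def test_posterior_matches_hand_computed_bayes_rule(self):
        X = np.array([[0.0], [1.0], [3.0], [4.0]])
        y = np.array(["weak", "weak", "strong", "strong"])
        model = GaussianNBClassifier().fit(X, y)
        x = 1.5
        # independent oracle: densities from the fitted means/variances
        def normal_pdf(x, mu, var):
            return math.exp(-((x - mu) ** 2) / (2 * var)) / math.sqrt(2 * math.pi * var)
        like = {
            "weak": 0.5 * normal_pdf(x, 0.5, 0.25),
            "strong": 0.5 * normal_pdf(x, 3.5, 0.25),
        }
        expected = like["weak"] / (like["weak"] + like["strong"])
        proba = model.predict_proba(np.array([[x]]))[0]
        assert proba[model.classes_.index("weak")] == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_sklearn_on_a_cohort(self):
        data = generate_cohort(CohortSpec(seed=11))
        y = data.labels["balance"]
        ours = GaussianNBClassifier().fit(data.X, y).predict(data.X)
        theirs = SkGaussianNB(var_smoothing=0.0).fit(data.X, y).predict(data.X)
        assert np.mean(ours == theirs) > 0.98

    def test_single_class_data_rejected(self):
        with pytest.raises(DegenerateModelError):
            GaussianNBClassifier().fit(np.zeros((5, 2)), np.array(["weak"] * 5))


class TestKNN:
    def test_k1_training_points_predict_their_own_label(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        y = rng.choice(LABELS, size=30)
        model = KNNClassifier(k=1).fit(X, y)
        assert np.array_equal(model.predict(X), y)

    def test_majority_on_a_three_point_line(self):
        # query at 0.5 is nearer the two 'strong' points at 0 and 1 than the
        # 'weak' point at 10 (brute-force distance sort)
        X = np.array([[0.0], [1.0], [10.0]])
        y = np.array(["strong", "strong", "weak"])
        model = KNNClassifier(k=3).fit(X, y)
        assert model.predict(np.array([[0.5]]))[0] == "strong"

    def test_tie_broken_by_nearest_neighbour(self):
        X = np.array([[0.0], [2.0], [3.0], [4.0]])
        y = np.array(["weak", "weak", "strong", "strong"])
        model = KNNClassifier(k=4).fit(X, y)
        # k = n with two votes each; nearest neighbour of 2.6 is the point
        # at 3.0 (strong) in z-scored (monotone) coordinates
        assert model.predict(np.array([[2.6]]))[0] == "strong"

    def test_k_larger_than_training_set_rejected(self):
        with pytest.raises(DomainError):
            KNNClassifier(k=5).fit(np.zeros((3, 1)), np.array(["weak", "strong", "weak"]))


class TestLDA:
    def test_boundary_is_perpendicular_bisector_for_spherical_classes(self):
        rng = np.random.default_rng(0)
        n = 200
        X = np.vstack([rng.normal((-2, 0), 1.0, (n, 2)), rng.normal((2, 0), 1.0, (n, 2))])
        y = np.array(["weak"] * n + ["strong"] * n)
        model = LDAClassifier().fit(X, y)
        eps = 0.15
        assert model.predict(np.array([[-eps, 0.3]]))[0] == "weak"
        assert model.predict(np.array([[+eps, 0.3]]))[0] == "strong"

    def test_duplicate_features_handled_via_ridge(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(40, 1))
        X = np.hstack([base, base])  # singular pooled covariance
        y = np.array(["weak"] * 20 + ["strong"] * 20)
        X[:20] -= 2.0
        model = LDAClassifier().fit(X, y)
        assert set(model.predict(X)) <= set(LABELS)

    def test_scores_match_hand_computed_discriminants(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
        y = np.array(["weak", "weak", "strong", "strong"])
        model = LDAClassifier().fit(X, y)
        # closed form: class means (1,0) and (1,2); within-class scatter
        # [[4,0],[0,0]] over n-K=2 gives a singular pooled covariance, so
        # the ridge is added in both routes
        means = {"weak": np.array([1.0, 0.0]), "strong": np.array([1.0, 2.0])}
        cov = np.array([[4.0, 0.0], [0.0, 0.0]]) / 2 + LDAClassifier.RIDGE * np.eye(2)
        inv = np.linalg.inv(cov)
        x = np.array([0.5, 1.4])
        expected = {
            c: x @ inv @ mu - 0.5 * mu @ inv @ mu + math.log(0.5)
            for c, mu in means.items()
        }
        scores = model.decision_function(x[None, :])[0]
        by_class = dict(zip(model.classes_, scores))
        for c in means:
            assert by_class[c] == pytest.approx(expected[c], rel=1e-6)

    def test_too_few_samples_rejected(self):
        with pytest.raises(DegenerateModelError):
            LDAClassifier().fit(np.zeros((2, 2)), np.array(["weak", "strong"]))


class TestMetrics:
    def test_perfect_prediction(self):
        counts = confusion(["strong", "weak", "moderate"], ["strong", "weak", "moderate"])
        report = precision_recall_f1(counts)
        for c in LABELS:
            assert counts.fp[c] == counts.fn[c] == 0
        assert report.macro_f1 == 1.0

    def test_enumerated_confusion_example(self):
        counts = confusion(
            ["strong", "strong", "moderate"], ["strong", "moderate", "moderate"]
        )
        assert counts.tp["strong"] == 1 and counts.fn["strong"] == 1
        assert counts.fp["moderate"] == 1 and counts.tp["moderate"] == 1

    def test_counts_partition_the_sample(self):
        rng = np.random.default_rng(5)
        y_true = rng.choice(LABELS, 60)
        y_pred = rng.choice(LABELS, 60)
        counts = confusion(y_true, y_pred)
        assert sum(counts.tp.values()) + sum(counts.fn.values()) == 60

    def test_alien_label_rejected(self):
        with pytest.raises(ValidationError):
            confusion(["strong"], ["average"])

    def test_arithmetic_example_from_the_standard_formulas(self):
        counts = ConfusionCounts(
            tp={"strong": 8, "moderate": 0, "weak": 0},
            fp={"strong": 2, "moderate": 0, "weak": 0},
            fn={"strong": 4, "moderate": 0, "weak": 0},
        )
        report = precision_recall_f1(counts)
        assert report.precision["strong"] == pytest.approx(0.8)
        assert report.recall["strong"] == pytest.approx(2 / 3, abs=1e-4)
        assert report.f1["strong"] == pytest.approx(8 / 11, abs=1e-4)

    def test_zero_over_zero_convention(self):
        counts = ConfusionCounts(
            tp={"strong": 0, "moderate": 0, "weak": 0},
            fp={"strong": 0, "moderate": 0, "weak": 0},
            fn={"strong": 5, "moderate": 0, "weak": 0},
        )
        report = precision_recall_f1(counts)
        assert report.precision["strong"] == report.recall["strong"] == report.f1["strong"] == 0.0

    def test_exhaustive_enumeration_oracle_on_four_instances(self):
        """Check every 3^4 prediction pattern against a brute-force oracle."""
        y_true = np.array(["strong", "moderate", "weak", "strong"])
        for pattern in itertools.product(LABELS, repeat=4):
            y_pred = np.array(pattern)
            report = precision_recall_f1(confusion(y_true, y_pred))
            for c in LABELS:
                tp = sum(t == c and p == c for t, p in zip(y_true, y_pred))
                fp = sum(t != c and p == c for t, p in zip(y_true, y_pred))
                fn = sum(t == c and p != c for t, p in zip(y_true, y_pred))
                p = tp / (tp + fp) if tp + fp else 0.0
                r = tp / (tp + fn) if tp + fn else 0.0
                f1 = 2 * p * r / (p + r) if p + r else 0.0
                assert report.precision[c] == pytest.approx(p)
                assert report.recall[c] == pytest.approx(r)
                assert report.f1[c] == pytest.approx(f1)
                # identities: harmonic mean, range, perfection
                assert 0.0 <= report.f1[c] <= 1.0
                if fp == 0 and fn == 0 and tp > 0:
                    assert report.f1[c] == 1.0


class TestCrossValidation:
    def test_separable_data_scores_one_for_all_learners(self):
        # three tight clusters separated in every feature: any reasonable
        # classifier should be perfect under cross-validation
        rng = np.random.default_rng(2)
        centers = {"weak": 0.0, "moderate": 50.0, "strong": 100.0}
        X = np.vstack([rng.normal(centers[c], 0.5, (40, 8)) for c in LABELS])
        y = np.repeat(list(LABELS), 40)
        data = LabeledDataset(X=X, labels={t: y.copy() for t in TESTS})
        for learner in ("naive_bayes", "knn", "lda"):
            report = kfold_cv(data, "flexibility", learner, seed=0)
            assert report.macro_f1 == 1.0

    def test_shuffled_labels_score_at_chance(self):
        data = generate_cohort(CohortSpec(n_subjects=850, separation=2.0, seed=4))
        rng = np.random.default_rng(4)
        data.labels["balance"] = rng.permutation(data.labels["balance"])
        report = kfold_cv(data, "balance", "naive_bayes", seed=4)
        assert abs(report.macro_f1 - 1 / 3) <= 0.08

    def test_same_seed_reproduces_the_report(self):
        data = generate_cohort(CohortSpec(seed=6))
        a = kfold_cv(data, "grip_strength", "knn", seed=9)
        b = kfold_cv(data, "grip_strength", "knn", seed=9)
        assert a == b

    def test_class_smaller_than_fold_count_rejected(self):
        data = generate_cohort(CohortSpec(n_subjects=12, seed=0))
        y = data.labels["balance"].copy()
        y[y == "weak"] = "moderate"
        y[:2] = "weak"  # only two members
        data.labels["balance"] = y
        with pytest.raises(StratificationError):
            kfold_cv(data, "balance", "naive_bayes", k_folds=4)


class TestEvaluateAll:
    def test_macro_average_of_published_style_row(self):
        # the headline accuracy is the macro average of four per-test F1s
        assert macro_average([0.87, 0.95, 0.97, 0.84]) == pytest.approx(0.9075)

    def test_table_has_twelve_cells(self):
        data = generate_cohort(CohortSpec(seed=1))
        report = evaluate_all(data)
        assert sum(len(row) for row in report.f1_table.values()) == 12
        assert set(report.f1_table) == {"naive_bayes", "knn", "lda"}

    def test_naive_bayes_beats_knn_on_gaussian_cohorts(self):
        # class structure is Gaussian per class, so NB's model is correct
        wins = 0
        for seed in range(20):
            data = generate_cohort(CohortSpec(n_subjects=120, seed=seed))
            nb = macro_average(
                [kfold_cv(data, t, "naive_bayes", seed=seed).macro_f1 for t in TESTS]
            )
            knn = macro_average(
                [kfold_cv(data, t, "knn", seed=seed).macro_f1 for t in TESTS]
            )
            wins += nb >= knn
        assert wins == 20


class TestPersistenceAndJson:
    @pytest.fixture()
    def models(self):
        return train_models(generate_cohort(CohortSpec(seed=5)))

    def test_round_trip_predictions_identical(self, tmp_path, models):
        data = generate_cohort(CohortSpec(seed=7))
        save_models(models, tmp_path / "models")
        loaded = load_models(tmp_path / "models")
        for test in TESTS:
            assert np.array_equal(models[test].predict(data.X), loaded[test].predict(data.X))

    @pytest.mark.parametrize("learner", ["naive_bayes", "knn", "lda"])
    def test_every_learner_persists(self, tmp_path, learner):
        data = generate_cohort(CohortSpec(seed=8))
        models = train_models(data, learner=learner)
        save_models(models, tmp_path / "m")
        loaded = load_models(tmp_path / "m")
        for test in TESTS:
            assert np.array_equal(
                models[test].predict(data.X[:10]), loaded[test].predict(data.X[:10])
            )

    def test_worked_instance_yields_four_labels(self, models):
        request = {
            "gender": 0, "age": 25, "weight": 50, "bmi": 25,
            "flexibility": 29.4, "reaction_time": 501,
            "grip_strength": 12.2, "balance": 5.86,
        }
        response = predict_json(models, request)
        assert set(response) == set(TESTS)
        assert all(label in LABELS for label in response.values())

    def test_malformed_field_named_in_error(self, models):
        request = {
            "gender": 0, "age": 25, "weight": 50, "bmi": 25,
            "flexibilty": 29.4, "reaction_time": 501,  # misspelled
            "grip_strength": 12.2, "balance": 5.86,
        }
        response = predict_json(models, request)
        assert "error" in response
        assert response["error"]["field"] in ("flexibility", "flexibilty")

    def test_non_numeric_value_rejected(self, models):
        request = {
            "gender": 0, "age": "old", "weight": 50, "bmi": 25,
            "flexibility": 29.4, "reaction_time": 501,
            "grip_strength": 12.2, "balance": 5.86,
        }
        response = predict_json(models, request)
        assert response["error"]["field"] == "age"

    def test_json_route_agrees_with_direct_predict(self, models):
        data = generate_cohort(CohortSpec(seed=9))
        row = data.X[0]
        request = {name: float(v) for name, v in zip(
            ("gender", "age", "weight", "bmi", "flexibility",
             "reaction_time", "grip_strength", "balance"), row)}
        request["gender"] = int(request["gender"])
        response = predict_json(models, request)
        for test in TESTS:
            assert response[test] == models[test].predict(row[None, :])[0]


class TestDatasetValidation:
    def test_label_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            LabeledDataset(
                X=np.zeros((3, 8)),
                labels={t: np.array(["strong"] * (2 if t == "balance" else 3))
                        for t in TESTS},
            )
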