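import copy

import numpy as np
import pytest
from sklearn.svm import SVC

from npmap4.classify import (
    Map4KernelSVC,
    Map4KNNClassifier,
    OriginModel,
    PhyschemSVC,
    kernel_matrix,
    predict_origin,
    train_map4_knn,
    train_map4_svm,
)
from npmap4.evaluation import roc_auc
from npmap4.fingerprint import map4_fingerprint
from npmap4.records import Dataset, SplitSpec, split_train_test
from npmap4.synthetic import GeneratorConfig, generate_dataset


def split_features(ds, sigs, index, seed=11):
    train, test = split_train_test(ds, SplitSpec(0.5, seed))
    X_train = sigs[[index[i] for i in train.ids]]
    X_test = sigs[[index[i] for i in test.ids]]
    return train, test, X_train, X_test


class TestKernelMatrix:
    def test_single_signature_self_kernel(self):
        f = map4_fingerprint("CCO")
        assert kernel_matrix([f], [f]).tolist() == [[1.0]]

    def test_square_kernel_symmetric_unit_diagonal(self, small_signatures):
        K = kernel_matrix(small_signatures[:10], small_signatures[:10])
        assert np.allclose(K, K.T)
        assert np.allclose(np.diag(K), 1.0)
        assert K.min() >= 0.0 and K.max() <= 1.0


class TestMap4KernelSVC:
    def test_separated_classes_training_auc(self, small_dataset, small_signatures, small_index):
        train, test, X_train, X_test = split_features(
            small_dataset, small_signatures, small_index
        )
        est = Map4KernelSVC(seed=0).fit(X_train, train.origins)
        assert est.best_C_ in (0.1, 1.0, 10.0, 100.0, 1000.0)
        train_auc = roc_auc(train.origins, est.predict_proba_positive(X_train))
        assert train_auc >= 0.99

    def test_probabilities_complementary_and_thresholded(
        self, small_dataset, small_signatures, small_index
    ):
        train, test, X_train, X_test = split_features(
            small_dataset, small_signatures, small_index
        )
        est = Map4KernelSVC(seed=0).fit(X_train, train.origins)
        proba = est.predict_proba(X_test)
        assert np.allclose(proba.sum(axis=1), 1.0)
        labels = est.predict(X_test)
        assert np.array_equal(labels == "bacterium", proba[:, 0] >= 0.5)

    def test_deterministic_under_seed(self, small_dataset, small_signatures, small_index):
        train, test, X_train, X_test = split_features(
            small_dataset, small_signatures, small_index
        )
        a = Map4KernelSVC(seed=4).fit(X_train, train.origins)
        b = Map4KernelSVC(seed=4).fit(X_train, train.origins)
        assert a.best_C_ == b.best_C_
        assert np.allclose(a.predict_proba(X_test), b.predict_proba(X_test))

    def test_single_class_rejected(self, small_signatures):
        with pytest.raises(ValueError, match="single class"):
            Map4KernelSVC().fit(small_signatures[:10], ["bacterium"] * 10)

    def test_unknown_label_rejected(self, small_signatures):
        with pytest.raises(ValueError, match="labels"):
            Map4KernelSVC().fit(small_signatures[:10], ["plant"] * 5 + ["fungus"] * 5)

    def test_class_weighting_helps_minority_recall(self):
        # 9:1 imbalance; compare balanced weighting against an unweighted SVC
        ds = generate_dataset(GeneratorConfig(n_per_class=90, seed=21))
        keep = [r for r in ds if r.origin == "fungus"] + [
            r for r in ds if r.origin == "bacterium"
        ][:12]
        from npmap4.fingerprint import signatures_for

        sub = Dataset(records=keep)
        sigs = signatures_for(sub.smiles)
        train, test, X_train, X_test = split_features(
            sub, sigs, {r.id: i for i, r in enumerate(sub)}, seed=2
        )
        y_test = np.asarray(test.origins)
        minority = "bacterium"
        weighted = Map4KernelSVC(seed=0).fit(X_train, train.origins)
        pred_w = weighted.predict(X_test)
        plain = SVC(kernel="precomputed", C=weighted.best_C_, class_weight=None).fit(
            kernel_matrix(X_train, X_train), np.asarray(train.origins) == minority
        )
        pred_p = plain.predict(kernel_matrix(X_test, X_train))
        mask = y_test == minority
        recall_w = np.mean(pred_w[mask] == minority) if mask.any() else 0.0
        recall_p = np.mean(pred_p[mask]) if mask.any() else 0.0
        assert recall_w >= recall_p


class TestMap4KNN:
    def test_query_identical_to_training_molecule(self, small_dataset, small_signatures, small_index):
        train, test, X_train, X_test = split_features(
            small_dataset, small_signatures, small_index
        )
        est = Map4KNNClassifier(k_grid=(1,), seed=0).fit(X_train, train.origins)
        # each training molecule's own signature: probability 1 for its class
        proba = est.predict_proba_positive(X_train)
        y = np.asarray(train.origins) == "bacterium"
        assert np.array_equal(proba, y.astype(float))

    def test_vote_is_unweighted_neighbor_fraction(
        self, small_dataset, small_signatures, small_index
    ):
        train, test, X_train, X_test = split_features(
            small_dataset, small_signatures, small_index
        )
        est = Map4KNNClassifier(seed=0).fit(X_train, train.origins)
        k = est.best_k_
        D = 1.0 - kernel_matrix(X_test, X_train)
        y = (np.asarray(train.origins) == "bacterium").astype(float)
        expected = np.array(
            [y[np.argsort(row, kind="stable")[:k]].mean() for row in D]
        )
        assert np.allclose(est.predict_proba_positive(X_test), expected)

    def test_separated_classes_balanced_accuracy(
        self, small_dataset, small_signatures, small_index
    ):
        from npmap4.evaluation import evaluate_predictions

        train, test, X_train, X_test = split_features(
            small_dataset, small_signatures, small_index
        )
        est = Map4KNNClassifier(seed=0).fit(X_train, train.origins)
        report = evaluate_predictions(test.origins, est.predict_proba_positive(X_test))
        assert report.balanced_accuracy >= 0.9

    def test_k_larger_than_training_rejected(self, small_signatures):
        y = ["bacterium", "fungus"] * 3
        with pytest.raises(ValueError, match="exceed"):
            Map4KNNClassifier(k_grid=(50,)).fit(small_signatures[:6], y)


class TestPhyschemSVC:
    def make_features(self, n=40, seed=13):
        rng = np.random.default_rng(seed)
        X0 = rng.normal(0.0, 1.0, size=(n, 5))
        X1 = rng.normal(2.5, 1.0, size=(n, 5))
        X = np.vstack([X0, X1])
        y = np.array(["fungus"] * n + ["bacterium"] * n)
        return X, y

    def test_scaler_fitted_on_training_only(self):
        X, y = self.make_features()
        est = PhyschemSVC(seed=0).fit(X, y)
        Xs = est.scaler_.transform(X[:, est.feature_mask_])
        assert np.allclose(Xs.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(Xs.std(axis=0), 1.0, atol=1e-9)

    def test_constant_feature_dropped_with_warning(self):
        X, y = self.make_features()
        X = np.column_stack([X, np.full(len(X), 7.0)])
        with pytest.warns(UserWarning, match="constant feature"):
            est = PhyschemSVC(seed=0).fit(X, y)
        assert est.feature_mask_.sum() == X.shape[1] - 1
        # prediction still works on the full-width matrix
        assert est.predict_proba(X).shape == (len(X), 2)

    def test_separable_features_learned(self):
        X, y = self.make_features()
        est = PhyschemSVC(seed=0).fit(X, y)
        assert roc_auc(y, est.predict_proba_positive(X)) >= 0.99

    def test_no_signal_gives_chance_auc(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 5))
        y = np.array(["bacterium", "fungus"] * 60)
        est = PhyschemSVC(seed=0).fit(X[:80], y[:80])
        auc = roc_auc(y[80:], est.predict_proba_positive(X[80:]))
        assert 0.25 <= auc <= 0.75


class TestOriginModel:
    def test_predict_table_contract(self, small_dataset, small_signatures, small_index):
        train, test, X_train, X_test = split_features(
            small_dataset, small_signatures, small_index
        )
        model = train_map4_knn(train, X_train, seed=0)
        table = predict_origin(model, test)
        assert np.allclose(table["p_fungal"] + table["p_bacterial"], 1.0)
        assert set(table["label"]) <= {"bacterium", "fungus"}
        # query identical to a training molecule reports distance 0 to it
        table_self = model.predict_table(Dataset(records=list(train.records[:3])))
        assert np.allclose(table_self["nn_jaccard_distance"], 0.0)
        assert list(table_self["nn_id"]) == [r.id for r in train.records[:3]]

    def test_save_load_round_trip_and_version_guard(
        self, tmp_path, small_dataset, small_signatures, small_index
    ):
        train, test, X_train, X_test = split_features(
            small_dataset, small_signatures, small_index
        )
        model = train_map4_svm(train, X_train, seed=0)
        path = tmp_path / "model.joblib"
        model.save(path)
        back = OriginModel.load(path)
        assert back.hyperparameters == model.hyperparameters
        a = model.estimator.predict_proba_positive(X_test)
        b = back.estimator.predict_proba_positive(X_test)
        assert np.allclose(a, b)
        stale = copy.deepcopy(model)
        stale.encoding_version = "MAP4-OTHER-9"
        stale.save(path)
        with pytest.raises(ValueError, match="encoding"):
            OriginModel.load(path)
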