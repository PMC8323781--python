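"""SVM grid search, cross-validation, persistence, and the Model/Results
surface."""

import numpy as np
import pytest

from raacfam import (
    FeatureMatrix,
    FeatureSpec,
    ProteinFamilyModel,
    SVMConfig,
    TrainedModel,
    cross_validate,
    get_type33,
    grid_search,
    grid_search_train,
)
from raacfam.errors import ConfigError, DatasetError
from raacfam.model import make_folds


def two_clusters(rng, n=100, gap=4.0, spread=0.1, dim=2):
    """Linearly separable 2-cluster data with inter-class distance >> spread."""
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    X = rng.normal(0, spread, (n, dim))
    X[y == 1, 0] += gap
    return X, y


def as_feature_matrix(X, y, size=2, k=1):
    spec = FeatureSpec(get_type33(size), k)
    assert X.shape[1] == spec.n_features
    return FeatureMatrix(X, y, [f"s{i}" for i in range(len(y))], spec)


class TestSVMConfig:
    def test_default_grids_inside_open_bounds(self):
        cfg = SVMConfig()
        assert all(2.0**-5 < c < 2.0**15 for c in cfg.c_grid)
        assert all(2.0**-15 < g < 2.0**3 for g in cfg.gamma_grid)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"c_grid": ()},
            {"c_grid": (2.0**-5,)},  # boundary excluded (open interval)
            {"c_grid": (2.0**15,)},
            {"gamma_grid": (2.0**3,)},
            {"cv_folds": 1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SVMConfig(**kwargs)


@pytest.fixture(scope="module")
def cfg():
    return SVMConfig(cv_folds=5, seed=9)


@pytest.fixture(scope="module")
def fitted(small_dataset):
    records, labels, _ = small_dataset
    model = ProteinFamilyModel.from_sequences(records, labels, scheme_size=5, k=1)
    return model.fit(select=False, svm_config=SVMConfig(cv_folds=5, seed=4))


class TestGridSearch:
    def test_separable_clusters_reach_high_cv_accuracy(self, rng, cfg):
        X, y = two_clusters(rng)
        result = grid_search(X, y, cfg)
        assert result.cv_accuracy >= 0.95
        assert 2.0**-5 < result.C < 2.0**15
        assert 2.0**-15 < result.gamma < 2.0**3

    def test_permuted_labels_give_chance_accuracy(self, rng, cfg):
        X, y = two_clusters(rng)
        perm = rng.permutation(y)
        result = grid_search(X, perm, cfg)
        se = np.sqrt(0.25 / len(y))
        assert abs(result.cv_accuracy - 0.5) <= 3 * se

    def test_tie_break_prefers_smaller_C_then_gamma(self, rng):
        # constant features: every cell scores identically, first cell wins
        X = np.full((20, 2), 0.5)
        y = np.array([0, 1] * 10)
        cfg = SVMConfig(
            c_grid=(1.0, 4.0), gamma_grid=(0.25, 1.0), cv_folds=4, seed=0
        )
        result = grid_search(X, y, cfg)
        assert (result.C, result.gamma) == (1.0, 0.25)

    def test_enlarging_grid_never_decreases_selected_accuracy(self, rng):
        X, y = two_clusters(rng, n=60, gap=1.0, spread=0.4)
        small = SVMConfig(c_grid=(1.0, 4.0), gamma_grid=(0.5,), cv_folds=5, seed=2)
        large = SVMConfig(
            c_grid=(1.0, 4.0, 16.0), gamma_grid=(0.5, 2.0), cv_folds=5, seed=2
        )
        assert (
            grid_search(X, y, large).cv_accuracy
            >= grid_search(X, y, small).cv_accuracy
        )

    def test_single_class_rejected(self, rng):
        with pytest.raises(DatasetError):
            grid_search(rng.random((10, 2)), np.zeros(10, dtype=int))


class TestCrossValidate:
    def test_perfect_separation_scores_perfectly(self, rng):
        X, y = two_clusters(rng, n=40)
        pooled, per_fold = cross_validate(X, y, 8.0, 0.5, SVMConfig(cv_folds=5))
        assert pooled.acc == 1.0
        assert pooled.mcc == 1.0
        assert len(per_fold) == 5

    def test_same_seed_reproduces_folds_and_report(self, rng):
        X, y = two_clusters(rng, n=40, gap=1.0, spread=0.5)
        cfg = SVMConfig(cv_folds=5, seed=17)
        folds_a = make_folds(y, cfg)
        folds_b = make_folds(y, cfg)
        for (tr_a, te_a), (tr_b, te_b) in zip(folds_a, folds_b):
            assert np.array_equal(tr_a, tr_b) and np.array_equal(te_a, te_b)
        a, _ = cross_validate(X, y, 2.0, 0.5, cfg)
        b, _ = cross_validate(X, y, 2.0, 0.5, cfg)
        assert a.to_dict() == b.to_dict()

    def test_twenty_samples_ten_folds_two_each(self):
        y = np.array([0, 1] * 10)
        folds = make_folds(y, SVMConfig(cv_folds=10, seed=0))
        assert all(len(test) == 2 for _, test in folds)


class TestTrainedModel:
    def test_training_sequences_recovered(self, fitted, small_dataset):
        records, labels, _ = small_dataset
        table = fitted.predict(records)
        agree = (table.label.to_numpy(dtype=int) == labels).mean()
        assert agree >= 0.9  # refit on all data; separable synthetic

    def test_identical_inputs_identical_outputs(self, fitted, small_dataset):
        records, _, _ = small_dataset
        seq = records[0][1]
        table = fitted.predict([("a", seq), ("b", seq)])
        assert table.label.iloc[0] == table.label.iloc[1]
        assert table.score.iloc[0] == table.score.iloc[1]
        assert table.probability.iloc[0] == table.probability.iloc[1]

    def test_short_sequence_reported_as_skipped(self, small_dataset):
        records, labels, _ = small_dataset
        model = ProteinFamilyModel.from_sequences(
            records, labels, scheme_size=5, k=2
        )
        res = model.fit(select=False, svm_config=SVMConfig(cv_folds=5, seed=4))
        table = res.predict([("ok", records[0][1]), ("tiny", "A")])
        assert list(table.status) == ["ok", "skipped: shorter than k"]

    def test_empty_input_rejected(self, fitted):
        with pytest.raises(DatasetError):
            fitted.predict([])

    def test_save_load_round_trip(self, fitted, small_dataset, tmp_path):
        records, _, _ = small_dataset
        path = tmp_path / "model.joblib"
        fitted.save(path)
        loaded = TrainedModel.load(path)
        assert loaded.C == fitted.trained.C
        assert loaded.gamma == fitted.trained.gamma
        assert loaded.spec.feature_names == fitted.trained.spec.feature_names
        a = fitted.predict(records[:5])
        b = loaded.predict_records(records[:5])
        assert np.array_equal(a.label.to_numpy(), b.label.to_numpy())
        np.testing.assert_allclose(a.score.to_numpy(), b.score.to_numpy())


class TestProteinFamilyModel:
    def test_from_fasta_and_summary(self, small_fasta):
        pos, neg, _ = small_fasta
        model = ProteinFamilyModel.from_fasta(pos, neg, scheme_size=5, k=1)
        res = model.fit(
            ifs_step=2, svm_config=SVMConfig(cv_folds=5, seed=8)
        )
        text = res.summary()
        assert "RBF kernel" in text and "Accuracy" in text and "MCC" in text
        assert res.trained.C in SVMConfig().c_grid
        assert len(res.selected_features) == res.ifs.best_dimension

    def test_seed_reproducibility_end_to_end(self, small_dataset):
        records, labels, _ = small_dataset
        reports = []
        for _ in range(2):
            model = ProteinFamilyModel.from_sequences(
                records, labels, scheme_size=5, k=1
            )
            res = model.fit(ifs_step=2, svm_config=SVMConfig(cv_folds=5, seed=13))
            reports.append(
                (res.trained.C, res.trained.gamma, res.ifs.best_dimension,
                 res.cv_report.to_dict())
            )
        assert reports[0] == reports[1]

    def test_single_class_rejected(self, small_dataset):
        records, labels, _ = small_dataset
        with pytest.raises(DatasetError):
            ProteinFamilyModel.from_sequences(
                records, np.ones_like(labels), scheme_size=5, k=1
            )
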