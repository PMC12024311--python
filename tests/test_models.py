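import numpy as np
import pytest
from sklearn.metrics import confusion_matrix as sk_confusion

from mibci.errors import ConfigurationError, MibciError, TrainingError
from mibci.features import WPTSearchSpace, Zscaler
from mibci.labels import CLASS_ORDER, EpochLabel
from mibci.models import (
    ConfusionMatrix,
    HyperparamGrid,
    ModelConfig,
    ModelKind,
    compare_models,
    evaluate,
    run_cv,
    search_wpt_model,
    train_classifier,
)


def test_training_rejects_missing_or_sparse_classes():
    X = np.random.default_rng(0).normal(size=(40, 5))
    y = np.array([EpochLabel.REST] * 40, dtype=object)
    with pytest.raises(TrainingError, match="missing classes"):
        train_classifier(X, y, ModelConfig(ModelKind.SVM))
    y4 = np.array(
        [EpochLabel.REST, EpochLabel.LEFT_FLEX, EpochLabel.LEFT_EXT, EpochLabel.RIGHT_FLEX] * 10,
        dtype=object,
    )
    with pytest.raises(TrainingError, match="right_ext"):
        train_classifier(X, y4, ModelConfig(ModelKind.SVM))


@pytest.mark.parametrize("kind", [ModelKind.WPT_NN, ModelKind.LSTM, ModelKind.SVM])
def test_save_load_predict_identity(tmp_path, kind, cluster_data):
    X, y = cluster_data
    train_idx = np.arange(500) % 5 != 0  # stratified 400-sample training split
    held = ~train_idx
    scaler = Zscaler().fit(X[train_idx])
    model = train_classifier(X[train_idx], y[train_idx], ModelConfig(kind, seed=3), scaler=scaler)
    before = model.predict(X[held])
    model.save(tmp_path / kind.value)
    from mibci.models import FittedModel

    loaded = FittedModel.load(tmp_path / kind.value)
    np.testing.assert_array_equal(loaded.predict(X[held]), before)


def test_cv_folds_partition_the_data(cluster_data):
    X, y = cluster_data
    sub = np.arange(0, 500, 5)  # 100 samples, 20 per class
    res = run_cv(X[sub], y[sub], ModelConfig(ModelKind.SVM, seed=0), k=5, seed=0)
    assert len(res.fold_accuracies) == 5
    # every sample in exactly one validation fold, folds of size 20
    assert np.all(res.fold_assignment >= 0)
    for fold in range(5):
        assert np.sum(res.fold_assignment == fold) == 20
    assert res.mean_accuracy == pytest.approx(np.mean(res.fold_accuracies))


def test_cv_fold_assignment_deterministic(cluster_data):
    X, y = cluster_data
    a = run_cv(X, y, ModelConfig(ModelKind.SVM, seed=0), seed=11)
    b = run_cv(X, y, ModelConfig(ModelKind.SVM, seed=0), seed=11)
    np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
    assert a.fold_accuracies == b.fold_accuracies


def test_cv_stable_under_row_duplication(cluster_data):
    X, y = cluster_data
    base = run_cv(X, y, ModelConfig(ModelKind.SVM, seed=0), seed=0).mean_accuracy
    X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
    doubled = run_cv(X2, y2, ModelConfig(ModelKind.SVM, seed=0), seed=0).mean_accuracy
    assert abs(base - doubled) < 0.05


def test_cv_warns_and_falls_back_without_stratification(cluster_data):
    X, y = cluster_data
    sub = np.arange(0, 500, 5)
    ys = y[sub].copy()
    ys[np.where(ys == 4)[0][:16]] = 3  # class 4 keeps only 4 members < k
    with pytest.warns(UserWarning, match="fewer than"):
        run_cv(X[sub], ys, ModelConfig(ModelKind.SVM, seed=0), k=5, seed=0)


def test_evaluate_matches_brute_force_recount(cluster_data):
    X, y = cluster_data
    model = train_classifier(X, y, ModelConfig(ModelKind.RANDOM_FOREST, seed=1))
    cm = evaluate(model, X[:200], y[:200])
    pred = model.predict(X[:200])
    ref = sk_confusion(list(y[:200]), list(pred), labels=model.classes)
    np.testing.assert_array_equal(cm.counts, ref)
    assert cm.total == 200
    assert cm.accuracy == pytest.approx(np.trace(ref) / 200)


def test_perfect_predictions_give_diagonal_matrix():
    classes = list(range(5))
    counts = np.diag([50] * 5)
    cm = ConfusionMatrix(counts=counts, classes=classes)
    assert cm.accuracy == 1.0
    np.testing.assert_array_equal(cm.row_sums(), [50] * 5)


def test_evaluate_rejects_foreign_labels(cluster_data):
    X, y = cluster_data
    model = train_classifier(X, y, ModelConfig(ModelKind.SVM, seed=0))
    with pytest.raises(MibciError, match="outside"):
        evaluate(model, X[:5], np.array([9] * 5, dtype=object))


def test_search_degenerate_space_returns_single_cell(small_windows):
    space = WPTSearchSpace(wavelets=("db4",), levels=(3,))
    res = search_wpt_model(small_windows, space=space, n_iter=2, seed=0)
    assert res.best_spec.wavelet_name == "db4"
    assert res.best_spec.level == 3


def test_search_follows_injected_objective(small_windows):
    """A stubbed scorer that prefers level 5 must win the search."""
    res = search_wpt_model(
        small_windows,
        n_iter=12,
        seed=0,
        scorer=lambda spec, ds: float(spec.level),
    )
    assert res.best_spec.level == 5
    assert len(res.trials) == 12


def test_search_is_deterministic(small_windows):
    kw = dict(n_iter=3, seed=5, scorer=lambda spec, ds: float(spec.level == 4))
    a = search_wpt_model(small_windows, **kw)
    b = search_wpt_model(small_windows, **kw)
    assert a.best_spec == b.best_spec
    assert a.hyperparams == b.hyperparams


def test_grid_samples_come_from_printed_sets():
    grid = HyperparamGrid()
    rng = np.random.default_rng(0)
    for _ in range(100):
        draw = grid.sample(rng)
        assert draw["batch_size"] in (10, 20, 30)
        assert draw["epochs"] in (5, 10, 20)
        assert draw["optimizer"] in ("adam", "rmsprop")
        assert draw["init_mode"] in ("uniform", "lecun_uniform", "normal")
        assert draw["activation"] in ("relu", "tanh")
        assert draw["neurons"] in (32, 64, 128)


def test_leaderboard_majority_baseline_and_ordering(small_windows):
    kinds = (ModelKind.MAJORITY, ModelKind.SVM, ModelKind.RANDOM_FOREST)
    board = compare_models(small_windows, kinds=kinds, seed=0)
    ranking = board.ranking()
    accs = [a for _, a in ranking]
    assert accs == sorted(accs, reverse=True)
    # majority baseline ~= majority-class frequency
    y = small_windows.labels
    freq = max(np.mean(y == lab) for lab in CLASS_ORDER)
    assert board.results[ModelKind.MAJORITY].mean_accuracy == pytest.approx(freq, abs=0.02)


def test_leaderboard_deterministic(small_windows):
    kinds = (ModelKind.MAJORITY, ModelKind.SVM)
    a = compare_models(small_windows, kinds=kinds, seed=3).ranking()
    b = compare_models(small_windows, kinds=kinds, seed=3).ranking()
    assert a == b


def test_compare_requires_two_kinds(small_windows):
    with pytest.raises(ConfigurationError):
        compare_models(small_windows, kinds=(ModelKind.SVM,), seed=0)
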