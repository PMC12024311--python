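"""Randomized wavelet/hyperparameter search and the model comparison.

Synthesizes two virtual subjects, searches the {db4, coif1, sym5} x {3,4,5}
wavelet space with a fixed random draw from the network grid, then ranks all
classifier families under identical 5-fold splits.
"""
from mibci import ModelKind, compare_models, make_session_fixture, make_windows, search_wpt_model

tables = make_session_fixture(2, seed=3, depth=0.6)
windows = make_windows(tables)
print(f"{windows.n_windows} windows of {windows.windows.shape[1]} rows")

search = search_wpt_model(windows, n_iter=4, seed=0)
print(f"best wavelet: {search.best_spec.wavelet_name} level {search.best_spec.level}, "
      f"mean 5-fold CV accuracy {search.cv_result.mean_accuracy:.3f}")
print(f"fixed network draw: {search.hyperparams}")

board = compare_models(
    windows,
    kinds=(ModelKind.WPT_NN, ModelKind.DENSE_NN, ModelKind.SVM, ModelKind.RANDOM_FOREST),
    seed=0,
    wavelet_spec=search.best_spec,
)
print("\nleaderboard (mean CV accuracy, identical folds):")
for kind, acc in board.ranking():
    print(f"  {kind.value:15s} {acc:.3f}")
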