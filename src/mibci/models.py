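"""Five-class classifiers, cross-validation and the randomized model search.

The classifier under study is a dense softmax network on multilevel-wavelet
features (``WPT_NN``); comparisons are the same dense family on raw band-power
features (``DENSE_NN``), a 1-D convolutional variant (``CNN_STYLE``), an LSTM
on band-power sequences, an RBF support vector machine and a random forest,
plus a majority-class dummy baseline. All are assessed with stratified 5-fold
cross-validation, normalization fit inside each training fold, and summarized
by per-fold accuracies and 5x5 confusion matrices.

Hyperparameters for the network families are drawn from a fixed grid
(batch_size {10,20,30}, epochs {5,10,20}, optimizer {adam,rmsprop}, init_mode
{uniform,lecun_uniform,normal}, activation {relu,tanh}, neurons {32,64,128});
the model search first fixes one grid draw, then searches the wavelet/level
space for the feature stage.
"""
from __future__ import annotations

import enum
import json
import pickle
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .errors import ConfigurationError, MibciError, TrainingError
from .features import (
    DEFAULT_STATS,
    WindowDataset,
    WPTSearchSpace,
    Zscaler,
    sample_wpt_hyperparams,
)
from .labels import CLASS_ORDER, EpochLabel
from .nn import Conv1DNet, DenseNet, LSTMNet, TrainSettings, _BaseNet
from .synth import BandPowerTable
from .wavelets import WaveletSpec


class ModelKind(enum.Enum):
    WPT_NN = "wpt_nn"
    DENSE_NN = "dense_nn"
    CNN_STYLE = "cnn_style"
    LSTM = "lstm"
    SVM = "svm"
    RANDOM_FOREST = "random_forest"
    MAJORITY = "majority"  # analytic baseline, not part of the comparison set

    @classmethod
    def comparison_set(cls) -> tuple["ModelKind", ...]:
        return (cls.WPT_NN, cls.DENSE_NN, cls.LSTM, cls.SVM, cls.RANDOM_FOREST)


@dataclass(frozen=True)
class HyperparamGrid:
    """The randomized-search grid for the network families."""

    batch_size: tuple[int, ...] = (10, 20, 30)
    epochs: tuple[int, ...] = (5, 10, 20)
    optimizer: tuple[str, ...] = ("adam", "rmsprop")
    init_mode: tuple[str, ...] = ("uniform", "lecun_uniform", "normal")
    activation: tuple[str, ...] = ("relu", "tanh")
    neurons: tuple[int, ...] = (32, 64, 128)

    def sample(self, rng: np.random.Generator) -> dict:
        return {
            name: values[int(rng.integers(len(values)))]
            for name, values in asdict(self).items()
        }


#: per-kind defaults used when no grid draw is supplied
_KIND_DEFAULTS: dict[ModelKind, dict] = {
    ModelKind.WPT_NN: {},
    ModelKind.DENSE_NN: {},
    ModelKind.CNN_STYLE: {"epochs": 30, "neurons": 64},
    ModelKind.LSTM: {"epochs": 30, "neurons": 32, "lr": 0.01},
}


@dataclass
class ModelConfig:
    """What to train: model family, its knobs, the class set, the seed."""

    kind: ModelKind
    hyperparams: dict = field(default_factory=dict)
    n_classes: int = 5
    seed: int = 0

    def settings(self) -> TrainSettings:
        merged = {**_KIND_DEFAULTS.get(self.kind, {}), **self.hyperparams}
        return TrainSettings(**merged)


def _resolve_classes(y: np.ndarray, n_classes: int) -> list:
    if len(y) and isinstance(y[0], EpochLabel):
        return list(CLASS_ORDER)
    classes = sorted(set(y.tolist()))
    if len(classes) > n_classes:
        raise TrainingError(f"found {len(classes)} classes, config allows {n_classes}")
    return classes


@dataclass
class FittedModel:
    """A trained classifier plus everything needed to reuse it."""

    kind: ModelKind
    classes: list
    estimator: object  # _BaseNet or sklearn estimator
    config: ModelConfig
    scaler: Zscaler | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class labels (in the model's class vocabulary)."""
        Xs = self.scaler.transform(X) if self.scaler is not None else np.asarray(X, dtype=float)
        if isinstance(self.estimator, _BaseNet):
            idx = self.estimator.predict(Xs)
            return np.array([self.classes[i] for i in idx], dtype=object)
        preds = self.estimator.predict(Xs)
        if isinstance(self.classes[0], EpochLabel):
            return np.array([EpochLabel.from_string(p) for p in preds], dtype=object)
        return np.asarray(preds, dtype=object)

    # -- persistence ------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "kind": self.kind.value,
            "classes": [str(c) for c in self.classes],
            "class_type": "epoch_label" if isinstance(self.classes[0], EpochLabel) else "raw",
            "hyperparams": self.config.hyperparams,
            "n_classes": self.config.n_classes,
            "seed": self.config.seed,
            "normalization": self.scaler.to_dict() if self.scaler else None,
            "format_version": 1,
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2))
        if isinstance(self.estimator, _BaseNet):
            np.savez(d / "weights.npz", **self.estimator.get_weights())
        else:
            with open(d / "estimator.pkl", "wb") as fh:
                pickle.dump(self.estimator, fh)
        return d

    @classmethod
    def load(cls, directory: str | Path) -> "FittedModel":
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        kind = ModelKind(meta["kind"])
        if meta["class_type"] == "epoch_label":
            classes: list = [EpochLabel.from_string(s) for s in meta["classes"]]
        else:
            classes = [int(c) if c.lstrip("-").isdigit() else c for c in meta["classes"]]
        config = ModelConfig(kind, meta["hyperparams"], meta["n_classes"], meta["seed"])
        if (d / "weights.npz").exists():
            net = _make_net(kind, config)
            with np.load(d / "weights.npz") as z:
                net.set_weights({k: z[k] for k in z.files})
            est: object = net
        else:
            with open(d / "estimator.pkl", "rb") as fh:
                est = pickle.load(fh)
        scaler = Zscaler.from_dict(meta["normalization"]) if meta["normalization"] else None
        return cls(kind=kind, classes=classes, estimator=est, config=config, scaler=scaler)


def _make_net(kind: ModelKind, config: ModelConfig) -> _BaseNet:
    cls = {ModelKind.WPT_NN: DenseNet, ModelKind.DENSE_NN: DenseNet,
           ModelKind.CNN_STYLE: Conv1DNet, ModelKind.LSTM: LSTMNet}[kind]
    return cls(n_classes=config.n_classes, settings=config.settings(), seed=config.seed)


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    config: ModelConfig,
    scaler: Zscaler | None = None,
) -> FittedModel:
    """Fit one classifier; deterministic under ``config.seed`` (single thread).

    ``scaler``, when given, is applied to the features before fitting and
    stored with the model so inference normalizes identically.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=object)
    if not np.all(np.isfinite(X)):
        raise TrainingError("features contain non-finite values")
    classes = _resolve_classes(y, config.n_classes)
    counts = {c: int(np.sum(y == c)) for c in classes}
    if classes == list(CLASS_ORDER):
        absent = [str(c) for c in classes if counts[c] == 0]
        if absent:
            raise TrainingError(f"training data is missing classes: {absent}")
    elif len(classes) < config.n_classes:
        raise TrainingError(
            f"training data holds {len(classes)} distinct classes "
            f"({[str(c) for c in classes]}); config expects {config.n_classes}"
        )
    few = [str(c) for c, n in counts.items() if n < 2]
    if few:
        raise TrainingError(f"need >= 2 samples per class; too few for: {few}")
    if scaler is not None:
        X = scaler.transform(X)

    if config.kind in (ModelKind.WPT_NN, ModelKind.DENSE_NN, ModelKind.CNN_STYLE, ModelKind.LSTM):
        net = _make_net(config.kind, config)
        y_idx = np.array([classes.index(v) for v in y])
        net.fit(X, y_idx)
        est: object = net
    else:
        y_fit = [str(v) for v in y] if isinstance(classes[0], EpochLabel) else list(y)
        if config.kind is ModelKind.SVM:
            est = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=config.seed).fit(X, y_fit)
        elif config.kind is ModelKind.RANDOM_FOREST:
            est = RandomForestClassifier(
                n_estimators=200, random_state=config.seed, n_jobs=1
            ).fit(X, y_fit)
        elif config.kind is ModelKind.MAJORITY:
            est = DummyClassifier(strategy="most_frequent").fit(X, y_fit)
        else:  # pragma: no cover
            raise ConfigurationError(f"unknown model kind {config.kind}")
    return FittedModel(kind=config.kind, classes=classes, estimator=est, config=config, scaler=scaler)


# ---------------------------------------------------------------- evaluation
@dataclass
class ConfusionMatrix:
    """5x5 count matrix: rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.classes), len(self.classes)):
            raise ConfigurationError("confusion matrix shape must match class count")
        if (self.counts < 0).any():
            raise ConfigurationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total if self.total else float("nan")

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def evaluate(model: FittedModel, features: np.ndarray, labels: np.ndarray) -> ConfusionMatrix:
    """Confusion matrix of a fitted model on labeled data."""
    y = np.asarray(labels, dtype=object)
    bad = sorted({str(v) for v in y.tolist() if v not in model.classes})
    if bad:
        raise MibciError(f"labels outside the model's class set: {bad}")
    pred = model.predict(features)
    k = len(model.classes)
    counts = np.zeros((k, k), dtype=int)
    tindex = {c: i for i, c in enumerate(model.classes)}
    for t, p in zip(y, pred):
        counts[tindex[t], tindex[p]] += 1
    return ConfusionMatrix(counts=counts, classes=model.classes)


# ---------------------------------------------------------------- cross-validation
@dataclass
class CVResult:
    fold_accuracies: list[float]
    confusions: list[ConfusionMatrix]
    fold_assignment: np.ndarray  # validation-fold index per sample
    config: ModelConfig
    wavelet_spec: WaveletSpec | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def _cv_splitter(y: np.ndarray, k: int, seed: int):
    _, counts = np.unique([str(v) for v in y], return_counts=True)
    if counts.min() < k:
        warnings.warn(
            f"a class has fewer than {k} members; falling back to unstratified folds",
            stacklevel=3,
        )
        return KFold(n_splits=k, shuffle=True, random_state=seed)
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)


def run_cv(
    features: np.ndarray,
    labels: np.ndarray,
    config: ModelConfig,
    k: int = 5,
    seed: int = 0,
    wavelet_spec: WaveletSpec | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation with per-fold normalization.

    The z-score normalization is fit on each training fold only and applied to
    its validation fold, so no validation statistics leak into training. Fold
    assignment depends only on (labels, k, seed), making comparisons across
    model kinds share identical folds.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=object)
    if k < 2:
        raise ConfigurationError(f"k must be >= 2, got {k}")
    if len(y) < k:
        raise ConfigurationError(f"need at least k={k} samples, got {len(y)}")
    splitter = _cv_splitter(y, k, seed)
    y_str = np.array([str(v) for v in y])
    accs, cms = [], []
    assignment = np.full(len(y), -1, dtype=int)
    for fold, (tr, va) in enumerate(splitter.split(X, y_str)):
        assignment[va] = fold
        scaler = Zscaler().fit(X[tr])
        model = train_classifier(X[tr], y[tr], config, scaler=scaler)
        cm = evaluate(model, X[va], y[va])
        accs.append(cm.accuracy)
        cms.append(cm)
    return CVResult(
        fold_accuracies=accs,
        confusions=cms,
        fold_assignment=assignment,
        config=config,
        wavelet_spec=wavelet_spec,
    )


# ---------------------------------------------------------------- search
@dataclass
class SearchTrial:
    wavelet_spec: WaveletSpec
    mean_accuracy: float | None
    error: str | None = None


@dataclass
class SearchResult:
    best_spec: WaveletSpec
    hyperparams: dict
    cv_result: CVResult
    trials: list[SearchTrial]


def search_wpt_model(
    tables: list[BandPowerTable] | WindowDataset,
    space: WPTSearchSpace | None = None,
    grid: HyperparamGrid | None = None,
    n_iter: int = 9,
    seed: int = 0,
    k: int = 5,
    scorer=None,
) -> SearchResult:
    """Two-stage randomized search for the wavelet-feature classifier.

    Stage 1 draws one network configuration from the hyperparameter grid and
    fixes it. Stage 2 draws ``n_iter`` wavelet/level cells uniformly from the
    search space, scores each by mean 5-fold CV accuracy of the WPT network on
    features extracted with that cell, and returns the best. ``scorer`` may
    replace the CV objective (``scorer(spec, windows) -> float``) for testing.
    """
    from .features import make_windows  # local import to avoid cycle confusion

    space = space or WPTSearchSpace()
    grid = grid or HyperparamGrid()
    if n_iter < 1:
        raise ConfigurationError(f"n_iter must be >= 1, got {n_iter}")
    windows = tables if isinstance(tables, WindowDataset) else make_windows(tables)
    space.validate_for_length(windows.windows.shape[1])

    rng = np.random.default_rng(seed)
    fixed = grid.sample(rng)
    trials: list[SearchTrial] = []
    best: tuple[float, WaveletSpec, CVResult | None] | None = None
    for i in range(n_iter):
        spec = sample_wpt_hyperparams(space, seed=int(rng.integers(2**31)))
        try:
            if scorer is not None:
                score, cv = float(scorer(spec, windows)), None
            else:
                X = windows.wavelet_features(spec)
                config = ModelConfig(ModelKind.WPT_NN, dict(fixed), seed=seed)
                cv = run_cv(X, windows.labels, config, k=k, seed=seed, wavelet_spec=spec)
                score = cv.mean_accuracy
        except MibciError as exc:
            trials.append(SearchTrial(spec, None, error=str(exc)))
            continue
        trials.append(SearchTrial(spec, score))
        if best is None or score > best[0]:
            best = (score, spec, cv)
    if best is None:
        diag = "; ".join(f"{t.wavelet_spec}: {t.error}" for t in trials)
        raise MibciError(f"all {n_iter} search trials failed: {diag}")
    score, spec, cv = best
    if cv is None:  # stubbed scorer: still report a real CV for the winner
        X = windows.wavelet_features(spec)
        config = ModelConfig(ModelKind.WPT_NN, dict(fixed), seed=seed)
        cv = run_cv(X, windows.labels, config, k=k, seed=seed, wavelet_spec=spec)
    return SearchResult(best_spec=spec, hyperparams=dict(fixed), cv_result=cv, trials=trials)


# ---------------------------------------------------------------- comparison
def features_for_kind(
    kind: ModelKind, windows: WindowDataset, wavelet_spec: WaveletSpec, n_seq_steps: int = 16
) -> np.ndarray:
    """The feature representation each model family consumes.

    Wavelet statistics for ``WPT_NN``; per-window mean band powers for the
    dense network, SVM, forest and majority baseline; flattened band-power
    sequences for the recurrent and convolutional families.
    """
    if kind is ModelKind.WPT_NN:
        return windows.wavelet_features(wavelet_spec)
    if kind in (ModelKind.LSTM, ModelKind.CNN_STYLE):
        seq = windows.sequences(n_steps=n_seq_steps)
        return seq.reshape(seq.shape[0], -1)
    return windows.mean_band_powers()


def compare_models(
    tables: list[BandPowerTable] | WindowDataset,
    kinds: tuple[ModelKind, ...] = ModelKind.comparison_set(),
    seed: int = 0,
    wavelet_spec: WaveletSpec | None = None,
    k: int = 5,
    hyperparams: dict | None = None,
) -> "Leaderboard":
    """Mean CV accuracy per model kind under identical folds and seed."""
    from .features import make_windows

    if len(kinds) < 2:
        raise ConfigurationError("compare_models needs at least two model kinds")
    windows = tables if isinstance(tables, WindowDataset) else make_windows(tables)
    spec = wavelet_spec or WaveletSpec("db4", 4)
    results: dict[ModelKind, CVResult] = {}
    for kind in kinds:
        X = features_for_kind(kind, windows, spec)
        config = ModelConfig(kind, dict(hyperparams or {}), seed=seed)
        results[kind] = run_cv(X, windows.labels, config, k=k, seed=seed, wavelet_spec=spec)
    return Leaderboard(results=results, wavelet_spec=spec, seed=seed)


@dataclass
class Leaderboard:
    results: dict[ModelKind, CVResult]
    wavelet_spec: WaveletSpec
    seed: int

    def ranking(self) -> list[tuple[ModelKind, float]]:
        """Kinds by descending mean accuracy; ties broken by kind name."""
        return sorted(
            ((kind, cv.mean_accuracy) for kind, cv in self.results.items()),
            key=lambda kv: (-kv[1], kv[0].value),
        )

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "model": kind.value,
                "mean_accuracy": acc,
                **{f"fold{i + 1}": a for i, a in enumerate(self.results[kind].fold_accuracies)},
            }
            for kind, acc in self.ranking()
        ]
        return pd.DataFrame(rows)
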