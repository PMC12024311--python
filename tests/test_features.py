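import numpy as np
import pandas as pd
import pytest

from mibci.errors import ConfigurationError
from mibci.features import (
    DEFAULT_STATS,
    FeatureLayout,
    WPTSearchSpace,
    Zscaler,
    extract_feature_matrix,
    extract_features,
    majority_label,
    make_windows,
    sample_wpt_hyperparams,
)
from mibci.labels import EpochLabel
from mibci.synth import BandPowerTable
from mibci.wavelets import WaveletSpec


def test_zero_window_gives_zero_features():
    vec = extract_features(np.zeros((256, 8)), WaveletSpec("db4", 4))
    assert np.all(vec == 0.0)


def test_feature_vector_length_counts_by_layout():
    # 8 channels x (level 4 + 1 arrays) x 4 statistics = 160
    vec = extract_features(np.random.default_rng(0).normal(size=(256, 8)), WaveletSpec("db4", 4))
    assert vec.shape == (160,)
    layout = FeatureLayout(tuple(f"ch{i}" for i in range(8)), 4, DEFAULT_STATS)
    assert layout.n_features == 160
    assert len(layout.names()) == 160


def test_extraction_is_pure():
    rng = np.random.default_rng(3)
    w = rng.normal(size=(128, 4))
    spec = WaveletSpec("sym5", 3)
    np.testing.assert_array_equal(extract_features(w, spec), extract_features(w, spec))


def test_batch_extraction_matches_single_window():
    rng = np.random.default_rng(4)
    windows = rng.normal(size=(5, 128, 3))
    spec = WaveletSpec("coif1", 3)
    batch = extract_feature_matrix(windows, spec)
    for i in range(5):
        np.testing.assert_allclose(batch[i], extract_features(windows[i], spec), rtol=1e-12)


def test_nonfinite_window_rejected():
    w = np.zeros((64, 2))
    w[3, 1] = np.nan
    with pytest.raises(ConfigurationError):
        extract_features(w, WaveletSpec("haar", 2))


def test_dyadic_shift_preserves_energy_statistics():
    """Rolling the window by one full dyadic block permutes coefficient blocks,
    so per-array energy summaries are unchanged (haar, level 2)."""
    rng = np.random.default_rng(9)
    w = rng.normal(size=(64, 1))
    spec = WaveletSpec("haar", 2)
    shifted = np.roll(w, 2**spec.level, axis=0)
    a = extract_features(w, spec, stats=("energy",))
    b = extract_features(shifted, spec, stats=("energy",))
    np.testing.assert_allclose(a, b, atol=1e-6)


def test_hyperparam_sampler_is_deterministic_and_in_space():
    space = WPTSearchSpace()
    first = sample_wpt_hyperparams(space, seed=123)
    assert sample_wpt_hyperparams(space, seed=123) == first
    for seed in range(50):
        spec = sample_wpt_hyperparams(space, seed=seed)
        assert spec.wavelet_name in space.wavelets
        assert spec.level in space.levels


def test_hyperparam_sampler_is_uniform_over_cells():
    space = WPTSearchSpace()
    counts: dict[tuple[str, int], int] = {}
    for seed in range(9000):
        spec = sample_wpt_hyperparams(space, seed=seed)
        counts[(spec.wavelet_name, spec.level)] = counts.get((spec.wavelet_name, spec.level), 0) + 1
    assert len(counts) == 9
    p = 1.0 / 9.0
    bound = 3 * np.sqrt(p * (1 - p) / 9000)
    for c in counts.values():
        assert abs(c / 9000 - p) < bound


def _tiny_table(n_rows: int, label: str = "rest") -> BandPowerTable:
    cols = {"timestamp": np.arange(n_rows) * 0.008}
    rng = np.random.default_rng(0)
    for i in range(8):
        for b in ("delta", "theta", "alpha", "beta", "gamma"):
            cols[f"ch{i + 1}_{b}"] = rng.random(n_rows)
    cols["label"] = [label] * n_rows
    return BandPowerTable(pd.DataFrame(cols))


def test_windows_never_span_table_boundaries():
    t1, t2 = _tiny_table(500), _tiny_table(500)
    ds = make_windows([t1, t2], window_rows=384, hop_rows=64)
    # each 500-row table yields floor((500-384)/64)+1 = 2 windows
    assert ds.n_windows == 4
    assert ds.windows.shape == (4, 384, 40)


def test_majority_label_ties_resolve_to_rest():
    labs = np.array(
        [EpochLabel.LEFT_FLEX, EpochLabel.LEFT_FLEX, EpochLabel.REST, EpochLabel.REST],
        dtype=object,
    )
    assert majority_label(labs) is EpochLabel.REST
    labs = np.array([EpochLabel.LEFT_FLEX] * 3 + [EpochLabel.REST], dtype=object)
    assert majority_label(labs) is EpochLabel.LEFT_FLEX


def test_zscaler_roundtrip_and_constant_columns():
    rng = np.random.default_rng(1)
    X = rng.normal(2.0, 3.0, size=(200, 4))
    X[:, 2] = 5.0  # constant feature must not divide by zero
    Z = Zscaler().fit(X)
    Xs = Z.transform(X)
    np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(Xs[:, 2], 0.0, atol=1e-12)
    d = Z.to_dict()
    np.testing.assert_allclose(Zscaler.from_dict(d).transform(X), Xs)


def test_search_space_validates_window_length():
    WPTSearchSpace().validate_for_length(384)
    with pytest.raises(Exception):
        WPTSearchSpace().validate_for_length(64)  # sym5 level 5 infeasible
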