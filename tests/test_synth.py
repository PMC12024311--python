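import numpy as np
import pytest
from scipy import stats as sps

from mibci.errors import ConfigurationError, MibciError
from mibci.labels import EpochLabel
from mibci.protocol import ProtocolSpec, build_protocol_timeline
from mibci.synth import (
    ERDSpec,
    NoiseModel,
    Recording,
    compute_band_powers,
    default_erd_template,
    feature_column_names,
    generate_recording,
    make_session_fixture,
)

SHORT = ProtocolSpec(repetitions=1, segment_s=4, rest_s=4)


def _mean_power(table, column: str, label: str) -> float:
    f = table.frame
    return float(f.loc[f.label == label, column].mean())


def test_same_seed_gives_bit_identical_recordings():
    tl = build_protocol_timeline(SHORT)
    a = generate_recording(tl, default_erd_template(0.5), seed=99)
    b = generate_recording(tl, default_erd_template(0.5), seed=99)
    np.testing.assert_array_equal(a.samples, b.samples)
    assert not np.array_equal(
        a.samples, generate_recording(tl, default_erd_template(0.5), seed=100).samples
    )


def test_full_suppression_forces_power_below_rest():
    tl = build_protocol_timeline(SHORT)
    spec = ERDSpec("alpha", 1.0, {2}, {EpochLabel.LEFT_FLEX})
    for seed in range(5):
        rec = generate_recording(tl, [spec], seed=seed)
        bp = compute_band_powers(rec, step_s=0.04)
        assert _mean_power(bp, "ch3_alpha", "left_flex") < _mean_power(bp, "ch3_alpha", "rest")


def test_zero_depth_is_null_across_seeds():
    """With no injected ERD the event-vs-rest alpha power difference is noise."""
    tl = build_protocol_timeline(SHORT)
    diffs = []
    for seed in range(40):
        rec = generate_recording(tl, [], seed=seed)
        bp = compute_band_powers(rec, step_s=0.04)
        rest = _mean_power(bp, "ch1_alpha", "rest")
        diffs.append((_mean_power(bp, "ch1_alpha", "left_flex") - rest) / rest)
    assert sps.ttest_1samp(diffs, 0.0).pvalue > 0.01


def test_unknown_channel_or_band_rejected():
    tl = build_protocol_timeline(SHORT)
    with pytest.raises(ConfigurationError):
        generate_recording(tl, [ERDSpec("alpha", 0.5, {11}, {EpochLabel.REST})], seed=0)
    with pytest.raises(ConfigurationError):
        generate_recording(tl, [ERDSpec("sigma", 0.5, {0}, {EpochLabel.REST})], seed=0)
    with pytest.raises(ConfigurationError):
        ERDSpec("alpha", 1.5, {0}, {EpochLabel.REST})


def test_band_power_table_has_40_feature_columns():
    rec = generate_recording(build_protocol_timeline(SHORT), [], seed=0)
    bp = compute_band_powers(rec, step_s=0.04)
    assert len(bp.feature_columns) == 40
    assert bp.feature_columns == feature_column_names(8)
    assert np.all(np.diff(bp.timestamps) > 0)
    assert (bp.features >= 0).all()


def test_all_zero_recording_gives_zero_powers():
    n = 2500
    rec = Recording(
        samples=np.zeros((n, 8)),
        fs=250.0,
        labels=np.array([EpochLabel.REST] * n, dtype=object),
        channel_names=[f"ch{i+1}" for i in range(8)],
        seed=0,
    )
    bp = compute_band_powers(rec, step_s=0.04)
    assert np.all(bp.features == 0.0)


def test_unit_sinusoid_concentrates_in_alpha():
    """Mean square of a unit 10 Hz sinusoid is 1/2, confined to 8-12 Hz."""
    fs, n = 250.0, 5000
    t = np.arange(n) / fs
    samples = np.zeros((n, 8))
    samples[:, 0] = np.sin(2 * np.pi * 10.0 * t)
    rec = Recording(
        samples=samples,
        fs=fs,
        labels=np.array([EpochLabel.REST] * n, dtype=object),
        channel_names=[f"ch{i+1}" for i in range(8)],
        seed=0,
    )
    bp = compute_band_powers(rec, window_s=1.0, step_s=0.1)
    alpha = bp.frame["ch1_alpha"].mean()
    assert alpha == pytest.approx(0.5, rel=0.05)
    for band in ("delta", "theta", "beta", "gamma"):
        assert alpha >= 10 * bp.frame[f"ch1_{band}"].mean()


def test_window_longer_than_recording_errors():
    rec = generate_recording(build_protocol_timeline(SHORT), [], seed=0)
    with pytest.raises(MibciError):
        compute_band_powers(rec, window_s=1000.0)


def test_too_short_window_rejected():
    rec = generate_recording(build_protocol_timeline(SHORT), [], seed=0)
    with pytest.raises(ConfigurationError):
        compute_band_powers(rec, window_s=0.1)


def test_erd_depth_monotonically_deepens_power_ratio():
    """Event/rest band-power ratio falls as suppression depth rises."""
    tl = build_protocol_timeline(SHORT)
    depths = [0.0, 0.2, 0.5, 0.8, 1.0]
    ratios = []
    for depth in depths:
        r = []
        for seed in range(20):
            rec = generate_recording(
                tl, [ERDSpec("alpha", depth, {0, 1}, {EpochLabel.LEFT_FLEX})], seed=seed
            )
            bp = compute_band_powers(rec, step_s=0.04)
            r.append(
                _mean_power(bp, "ch1_alpha", "left_flex") / _mean_power(bp, "ch1_alpha", "rest")
            )
        ratios.append(np.mean(r))
    assert all(a > b for a, b in zip(ratios, ratios[1:]))


def test_band_powers_bounded_by_total_signal_power():
    """Disjoint frequency masks: summed band power cannot exceed signal power."""
    rec = generate_recording(build_protocol_timeline(SHORT), [], seed=3)
    bp = compute_band_powers(rec, step_s=0.04)
    total_signal = np.mean(rec.samples**2, axis=0)  # per channel
    for ch in range(8):
        band_sum = sum(bp.frame[f"ch{ch+1}_{b}"].mean() for b in ("delta", "theta", "alpha", "beta", "gamma"))
        assert band_sum <= total_signal[ch] * 1.01


def test_session_fixture_schema_and_determinism():
    tables = make_session_fixture(3, seed=1, protocol=SHORT, step_s=0.04)
    assert len(tables) == 3
    cols = tables[0].feature_columns
    assert all(t.feature_columns == cols for t in tables)
    again = make_session_fixture(3, seed=1, protocol=SHORT, step_s=0.04)
    for a, b in zip(tables, again):
        np.testing.assert_array_equal(a.features, b.features)
    combined = tables[0].concat(tables[1])
    assert combined.n_rows == tables[0].n_rows + tables[1].n_rows
    with pytest.raises(ConfigurationError):
        make_session_fixture(0, seed=1)
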