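import numpy as np
import pytest

from mibci.bundle import ModelBundle
from mibci.errors import StreamError
from mibci.io import write_acquisition_csv
from mibci.labels import CLASS_ORDER, EpochLabel
from mibci.stream import (
    ActuatorCommand,
    CommandLogSink,
    InProcessTransport,
    StreamEngine,
    StreamPacket,
    debounce,
    map_label_to_command,
    replay_csv,
)

A, B = ActuatorCommand.LEFT_FLEX_CMD, ActuatorCommand.RIGHT_EXT_CMD


def test_label_command_mapping_is_a_bijection():
    assert map_label_to_command(EpochLabel.REST) is ActuatorCommand.NOOP
    assert map_label_to_command(EpochLabel.LEFT_FLEX) is ActuatorCommand.LEFT_FLEX_CMD
    images = {map_label_to_command(lab) for lab in CLASS_ORDER}
    assert len(images) == 5


def test_debounce_dwell_one_is_identity():
    seq = [A, B, A, A, B]
    assert debounce(seq, 1) == seq


def test_debounce_suppresses_transients():
    # A appears consecutively only at windows 3-4 -> takes effect at window 4
    out = debounce([A, B, A, A], 2)
    assert out == [ActuatorCommand.NOOP, ActuatorCommand.NOOP, ActuatorCommand.NOOP, A]


def test_debounce_constant_stream_emits_once_and_holds():
    out = debounce([A] * 6, 1)
    assert out == [A] * 6


def _packets(windows, n_rows):
    rows = windows.windows[0]  # replay one window's rows repeatedly is enough
    for i in range(n_rows):
        yield StreamPacket(timestamp=float(i), values=rows[i % len(rows)])


def test_one_command_per_completed_hop(trained_bundle, small_windows):
    bundle, _ = trained_bundle
    n_rows = 384 + 64 * 99  # exactly 100 completed windows
    cmds = StreamEngine(bundle).run(_packets(small_windows, n_rows))
    assert len(cmds) == 100


def test_all_sinks_receive_identical_ordered_sequences(trained_bundle, small_windows):
    bundle, _ = trained_bundle
    s1, s2 = CommandLogSink(), CommandLogSink()
    transport = InProcessTransport()
    seen = []
    transport.subscribe(seen.append)
    engine = StreamEngine(bundle, sinks=[s1, s2, transport.push])
    cmds = engine.run(_packets(small_windows, 384 + 64 * 4))
    assert s1.records == s2.records == seen == cmds


def test_replay_matches_batch_evaluation(tmp_path, trained_bundle, small_session_tables, small_windows):
    """Online sliding-window decoding equals offline windowed prediction bit-for-bit."""
    bundle, X = trained_bundle
    csv_path = write_acquisition_csv(small_session_tables[0], tmp_path / "session.csv")
    cmds = StreamEngine(bundle).run(replay_csv(csv_path))
    n_sub = sum(
        1 for _ in range(0, small_session_tables[0].n_rows - 384 + 1, 64)
    )
    assert len(cmds) == n_sub
    batch = [map_label_to_command(l) for l in bundle.model.predict(X[:n_sub])]
    assert [c for _, c in cmds] == batch


def test_replay_is_deterministic(tmp_path, trained_bundle, small_session_tables):
    bundle, _ = trained_bundle
    csv_path = write_acquisition_csv(small_session_tables[0], tmp_path / "session.csv")
    a = StreamEngine(bundle).run(replay_csv(csv_path))
    b = StreamEngine(bundle).run(replay_csv(csv_path))
    assert a == b


def test_no_lookahead_prefix_property(trained_bundle, small_windows):
    """Truncating the source never changes commands already emitted."""
    bundle, _ = trained_bundle
    full = StreamEngine(bundle).run(_packets(small_windows, 384 + 64 * 6))
    short = StreamEngine(bundle).run(_packets(small_windows, 384 + 64 * 3))
    assert full[: len(short)] == short


def test_schema_mismatch_aborts_with_diagnostic(trained_bundle):
    bundle, _ = trained_bundle
    bad = [StreamPacket(timestamp=0.0, values=np.zeros(39))]
    with pytest.raises(StreamError, match="39"):
        StreamEngine(bundle).run(iter(bad))


def test_non_monotone_timestamps_rejected(trained_bundle, small_windows):
    bundle, _ = trained_bundle
    rows = small_windows.windows[0]
    pkts = [
        StreamPacket(timestamp=1.0, values=rows[0]),
        StreamPacket(timestamp=0.5, values=rows[1]),
    ]
    with pytest.raises(StreamError, match="monotone"):
        StreamEngine(bundle).run(iter(pkts))


def test_bundle_roundtrip_preserves_decisions(tmp_path, trained_bundle, small_windows):
    bundle, X = trained_bundle
    bundle.save(tmp_path / "bundle")
    loaded = ModelBundle.load(tmp_path / "bundle")
    window = small_windows.windows[0]
    assert loaded.model.predict(X[:10]).tolist() == bundle.model.predict(X[:10]).tolist()
    np.testing.assert_allclose(
        loaded.featurize_window(window), bundle.featurize_window(window), rtol=1e-12
    )
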