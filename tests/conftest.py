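import numpy as np
import pytest

from mibci.features import make_windows
from mibci.protocol import ProtocolSpec
from mibci.synth import make_session_fixture


@pytest.fixture(scope="session")
def small_session_tables():
    """Two 3-repetition subjects with strong (depth 0.9) contralateral ERD."""
    return make_session_fixture(
        2, seed=42, protocol=ProtocolSpec(repetitions=3), depth=0.9
    )


@pytest.fixture(scope="session")
def small_windows(small_session_tables):
    return make_windows(small_session_tables)


@pytest.fixture(scope="session")
def trained_bundle(small_windows):
    """WPT-NN bundle trained on the small session, plus its training features."""
    from mibci.bundle import ModelBundle
    from mibci.features import DEFAULT_STATS, Zscaler
    from mibci.models import ModelConfig, ModelKind, train_classifier
    from mibci.wavelets import WaveletSpec

    spec = WaveletSpec("db4", 4)
    X = small_windows.wavelet_features(spec)
    scaler = Zscaler().fit(X)
    model = train_classifier(
        X, small_windows.labels, ModelConfig(ModelKind.WPT_NN, seed=2), scaler=scaler
    )
    bundle = ModelBundle(
        model=model,
        wavelet_spec=spec,
        stats=DEFAULT_STATS,
        column_names=small_windows.column_names,
        window_rows=384,
        hop_rows=64,
    )
    return bundle, X


@pytest.fixture(scope="session")
def cluster_data():
    """Five well-separated Gaussian clusters, 100 samples each, 20-D."""
    rng = np.random.default_rng(7)
    centers = rng.normal(0, 5, (5, 20))
    X = np.vstack([c + rng.normal(0, 0.5, (100, 20)) for c in centers])
    y = np.repeat(np.arange(5), 100).astype(object)
    return X, y
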