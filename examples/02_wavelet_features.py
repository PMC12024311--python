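"""Multilevel DWT of a windowed signal and the fixed-length feature vector.

Shows the coefficient pyramid (cA_n, cD_n ... cD_1), verifies perfect
reconstruction and energy conservation, and builds the per-window summary
vector the classifier consumes.
"""
import numpy as np

from mibci import WaveletSpec, extract_features, multilevel_dwt, reconstruct

rng = np.random.default_rng(0)
signal = rng.standard_normal(384)

spec = WaveletSpec("db4", level=4)
result = multilevel_dwt(signal, spec)
print(f"{spec.wavelet_name} level {spec.level}: cA_{result.level} has "
      f"{len(result.cA_n)} coefficients; details "
      f"{[len(d) for d in result.details]} (cD_{result.level} ... cD_1)")

energy_in = float(np.sum(signal**2))
print(f"energy: signal {energy_in:.6f}, coefficients {result.energy:.6f} "
      f"(relative error {abs(result.energy - energy_in) / energy_in:.2e})")

roundtrip = reconstruct(result, spec, length=len(signal))
print(f"round-trip max abs error: {np.max(np.abs(roundtrip - signal)):.2e}")

# a 40-column band-power window -> 40 x (4+1) arrays x 4 statistics = 800 features
window = rng.standard_normal((384, 40))
vec = extract_features(window, spec)
print(f"feature vector length for a 40-column window: {len(vec)}")
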