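# Methods

This note documents the models, the numerical choices, and what the synthetic
benchmark does and does not establish.

## Synthetic sessions

**Protocol timeline.** One session module is `repetitions` cycles of four 5-s
active segments (left flexion, left extension, right flexion, right
extension, in that order) followed by a 10-s rest block; defaults are 10
repetitions, giving 200 s of active task time and 300 s total. Labels are
assigned per sample on the sampling grid by rounding cumulative segment
edges, so no drift accumulates.

**Signal model.** Each of the 8 channels (250 Hz default) is

    x_c(t) = n_c(t) + Σ_b  a_b(c, t) · o_{b,c}(t)

where `n_c` is 1/f background noise (spectrum shaped ∝ f^(−1/2) in amplitude
over 0.5–45 Hz, normalized to exactly `rms_uv` = 10 µV RMS per channel) and
`o_{b,c}` is band-limited Gaussian noise confined to band *b* (alpha 8–12 Hz
and beta 13–30 Hz by default), normalized per channel to a fixed power ratio
against the background. ERD is an amplitude envelope: an `ERDSpec(band,
depth, channels, labels)` multiplies the oscillation by √(1−depth) wherever
its labels are active, so band power scales by (1−depth); negative depths
encode ERS by the same formula. All draws come from one
`numpy.random.Generator` seeded per call — identical configuration and seed
give bit-identical sample matrices.

**Oscillation-to-noise calibration.** `NoiseModel.osc_power` (default 2.0 per
band) is the oscillation power as a multiple of the channel's *total*
background power. A 1/f spectrum spreads its power as log-frequency, so a
4-Hz analysis band around 10 Hz holds only ≈ 9% of the background power;
in-band oscillation-to-noise is therefore ≈ 20. This matters for ERD
recovery: the measured percent change is biased toward zero by the factor
S/(S+N_band) ≈ 0.96, i.e. an injected depth d is read back as ≈ −96·d %,
inside the ±10 pp recovery band at every depth. Had the ratio been defined
in-band (S/N_band = 2), the bias factor would be 2/3 and depth recovery would
be impossible at the stated tolerance — that is why the calibration is
defined against total background power.

**ERD template.** The default template expresses the classical contralateral
organization, with the flexion/extension contrast carried by the band:
flexion suppresses mu/alpha and extension suppresses beta, each on the
hemisphere opposite the moving arm (channels 0–3 = left hemisphere, 4–7 =
right, configurable). Some band- or topography-based signature separating
flexion from extension is a modeling necessity: with identical signatures the
two movements of one arm would be indistinguishable by construction and no
classifier could exceed 60% five-class accuracy. Virtual subjects share the
template; individuality is log-normal amplitude jitter (σ = 0.1 in log
space) on the background RMS and per-band oscillation power.

**Band powers.** Channels are band-limited by zeroing the full-record rFFT
outside each band (disjoint masks, so summed band power cannot exceed total
signal power, Parseval); a row's power is the mean square of that component
over a 0.5-s window centred on the row timestamp, emitted every 0.008 s
(125 rows/s at 250 Hz). Row labels are the window's majority label with ties
resolved toward rest. The 0.5-s minimum window is two cycles of the delta
band's upper edge (4 Hz); requiring two cycles of its *lower* edge (0.5 Hz)
would force ≥ 4-s windows, which straddle the 5-s protocol segments and
contaminate event windows with rest power badly enough to break depth
recovery, so the upper-edge rule is used and slow bands are simply smoothed
estimates. What the generator does **not** model: ocular/muscle artifacts,
line noise, electrode drift, volume conduction, or realistic inter-subject
topography. Passing tests show the pipeline recovers structure it was built
to inject; they do not certify performance on recorded EEG.

## Features

The multilevel DWT wraps `pywt.wavedec`/`waverec` with **periodization**
boundary handling, which makes the transform orthonormal for orthogonal
wavelets: coefficient energy equals signal energy exactly when the signal
length is divisible by 2^level, and reconstruction is exact for any length.
Symmetric half-sample extension was considered and rejected because its
boundary duplication breaks exact Parseval, which is the module's core
oracle. Window geometry defaults to 384 rows (≈ 3 s) every 64 rows (≈ 0.5 s);
384 is divisible by 2^5, so every cell of the {db4, coif1, sym5} × {3, 4, 5}
search space is admissible and energy-exact. Level feasibility follows
`level ≤ floor(log2(n/(filter_len − 1)))`.

Each window yields `n_channels × (level+1) × 4` features — per coefficient
array: mean, SD, energy, max-|·| — a fixed-length vector independent of
window length, robust to variable epoch durations, laid out channel-major
with the statistic order recorded in a JSON sidecar for reuse at inference.
Normalization is per-feature z-score, fit on training folds only.

## Classifiers

No deep-learning framework is a dependency; `mibci.nn` implements the three
network families in NumPy with exactly the randomized-search knobs: dense
(input → dense(neurons, act) → dropout 0.2 → dense(neurons/2, act) →
softmax(5)), 1-D conv (width-3 kernels, neurons/4 filters, global average
pooling), and a standard LSTM (forget-gate bias 1, last hidden state →
softmax). Flat feature vectors fed to sequence models are reshaped to 8
steps. Optimizers are Adam (β = 0.9/0.999) and RMSprop (ρ = 0.9), base
learning rate 0.005 (0.01 for the LSTM) — chosen for convergence within the
grid's small epoch budgets on z-scored inputs. Weight init, batch shuffling
and dropout all draw from one seeded generator; single-threaded training is
bit-reproducible. Argmax prediction breaks ties toward the lowest class
index. SVM (RBF, C = 1, gamma scaled) and random forest (200 trees, seeded,
one job) come from scikit-learn; a majority-class dummy is available as an
analytic baseline.

The two-stage search mirrors the training procedure it models: one draw from
the printed network grid is fixed, then `n_iter` wavelet/level cells are
drawn uniformly and scored by mean stratified 5-fold CV accuracy; the full
trial log is retained. Cross-validation fits normalization inside each
training fold; fold assignment depends only on (labels, k, seed) so model
comparisons share identical folds. Classes with fewer members than k trigger
a warning and a fall back to unstratified folds.

## ERD/ERS analysis

Cycles are recovered from contiguous label runs; cycle k of a task uses rest
run k (the same repetition's rest block) as baseline, falling back to the
event series' own mean when no rest rows exist. Rows within 0.25 s (half the
default band-power window) of a run edge are trimmed so sliding windows that
straddle segment boundaries do not mix event and rest power. Hemisphere
series are unweighted means over that hemisphere's channels; mu is the alpha
column. Per cell the analysis reports the baseline, max excursions above and
below it ("maximum amplitude changes" read as extremal deviations from the
stated baseline, not first differences), the classical percent change of
mean event power (the quantity used in recovery checks), the excursions as
percent of baseline, and the ratio max_increase/max_decrease — flagged
undefined rather than fabricated when max_decrease is 0, with the convention
recorded in the report metadata. The full key cross is 2 arms × 2 movements
× 2 hemispheres × 2 bands × repetitions (160 cells at 10 repetitions);
unpopulated cells are absent, never imputed.

## Streaming

A model bundle carries weights, wavelet spec, statistic order, normalization,
class order and window geometry. The engine buffers incoming rows; whenever
the newest window start falls on a hop multiple it featurizes exactly as at
training time and emits one command per completed hop — so batch evaluation
of the same windows is bit-identical to the replay, and a command depends
only on rows up to its window's end. Labels map bijectively to actuator
commands (rest ↔ no-op). Debouncing (default dwell 2 in the pipeline
config, 1 = off in the engine default) requires a candidate command to
persist for N consecutive windows before switching, holding the prior state
otherwise. Schema mismatches and non-monotone timestamps abort the stream
with a diagnostic rather than guessing column order.

## Reproducibility and problem sizes

One global seed fans out per stage as `(seed XOR crc32(stage_name)) mod
2^31`; every consumed seed is recorded in the pipeline manifest. Test and
acceptance problem sizes are chosen to exercise each claim at desk scale:
1000 signals for the wavelet oracle; n = 500 five-cluster sets for chance
band and separability; ten virtual subjects at depth 0.6 for the end-to-end
accuracy check with a 1-subject, 5-repetition series per (depth, seed) cell
for depth monotonicity; 50-cycle sessions for ERD recovery and 50–100 short
sessions for the depth-0 null. The model-comparison leaderboard on synthetic
sessions is reported as a computed quantity only — synthetic band-power
streams are far more homogeneous than recorded EEG, and relative rankings of
model families on them carry no implication for recorded data.

## Known limitations

- The acquisition software's true band-power estimator is unspecified; the
  FFT-masking estimator here is a documented stand-in, and whether tables
  hold instantaneous or windowed power is a configuration choice (windowed).
- Wavelet-packet best-basis trees are out of scope: the feature stage
  implements plain multilevel DWT semantics (cA_n, cD_n … cD_1), which is
  what the coefficient-list interface describes.
- LSL networking, serial framing and actuator control are replaced by the
  transport contract; only in-process, file-replay and log transports ship.
- Statistical testing across subjects, time-resolved ERD curves
  (inter-trial-variance methods), and any clinical interpretation are out of
  scope.
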