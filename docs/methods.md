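# Methods

## Problem and model

A non-invasive fetal ECG is recorded as a mixture on the maternal abdomen:
the maternal ECG (MECG) dominates, the fetal ECG (FECG) appears at a
fraction of its amplitude with a narrower QRS, and both sit in noise
(baseline wander, powerline interference, broadband muscle/electrode
noise). The package separates the two cardiac components from a *single*
abdominal channel with a W-shaped pair of attention R2U-Nets:

- the **maternal branch** (convolution kernel 5) encodes and decodes the
  mixture into an MECG estimate;
- the **fetal branch** (kernel 3) encodes the same mixture, subtracts the
  maternal encoder's feature maps level by level, passes the difference
  through `tanh`, and decodes the result into an FECG estimate.

Both branches are five-level 1-D encoder–decoders. Every level uses a
**recurrent residual convolution (RRC) block**: with forward convolution
`conv_f`, recurrent convolution `conv_r` and activation `act`,

    y(0) = act(conv_f(x));   y(t) = act(conv_f(x) + conv_r(y(t-1))),  t = 1..T
    output = x' + y(T)

with `T = 2` recurrence steps and `x'` the input (through a 1x1 projection
when the channel count changes — the residual identity is only defined for
equal shapes, and the first block of each level changes width). Skip
connections are replaced by **additive attention gates**:

    alpha = sigmoid( psi( relu(W_u u + W_g g + b_g) ) + b_psi ),  gated = alpha * u

where `u` is the encoder feature map and `g` the decoder-side gating
signal, upsampled to `u`'s length before gating. `alpha` is one coefficient
per sample position, broadcast over channels.

Decoding is linear-interpolation upsampling followed by a 1x1
channel-reducing convolution (not a transposed convolution, which
introduces checkerboard artifacts in 1-D reconstruction), an attention-gated
skip, channel concatenation, and an RRC block. The output heads are 1x1
convolutions with *linear* activation: targets are Z-scored and exceed
(-1, 1), so the network's only saturating nonlinearity is the `tanh` at the
feature-subtraction point. The head weights are initialized at 1/100 of
their He scale so the untrained network predicts near zero; without this
the residual chains give the raw output a magnitude of hundreds and the
first epochs are spent rescaling, which makes short CPU runs erratic
across seeds.

Channel widths double per level, 64–1024 at full scale; `width_multiplier`
scales them uniformly (the desk preset uses 1/8: 8–128). Fusion happens at
every encoder level by default and the fused maps feed the fetal decoder's
attention gates; `fusion_feeds_encoder=True` additionally routes the fused
maps into the fetal encoder's own downstream levels (both wirings are
implemented; skip-only is the default because it keeps the two encoders'
representations independent). The two branches share no weights. No batch
normalization is used. Block activation defaults to leaky ReLU (slope
0.01); plain ReLU is available.

### Numerical engine

The network runs on a small reverse-mode autodiff engine over float64
numpy arrays (same-padded stride-1 `conv1d` via strided windows + einsum,
2:1 max pooling, 2x linear upsampling with half-pixel centers, the usual
activations, channel concat, full reductions). Every primitive's gradient
is verified against central finite differences in the test suite. Adam
(beta 0.9/0.999, eps 1e-8) with global-norm gradient clipping at 5.0
performs the updates. Determinism: all randomness (init, shuffling, data
synthesis) flows through seeded `numpy` generators; two runs with one seed
are bit-identical.

## Preprocessing

1. Zero-phase 4th-order Butterworth band-pass. Target band 3–100 Hz; the
   forward–backward application squares the magnitude response, so the
   upper design corner is pre-warped to 117 Hz to keep 5–90 Hz within
   ±1 dB while the effective -3 dB point stays near 100 Hz. Zero phase
   preserves R-peak timing, on which the 31.25 ms detection tolerance
   depends. Powerline (50 Hz) is inside the band and left to the network.
2. Polyphase resampling to 250 Hz (filtering precedes resampling whenever
   the native rate is higher, for anti-alias safety). Annotation indices
   are rescaled and rounded once, at the native rate.
3. Windowing into 1024-sample segments with 24 samples of overlap at each
   end (hop 976). The final window is anchored at the signal tail; if the
   tail window would leave earlier samples uncovered it is appended rather
   than substituted.
4. Per-segment Z-score (the mean/sd pair is retained; sd floored at 1e-8
   for flat segments). Normalization is per segment, not per record,
   because windowing precedes normalization in the conditioning chain.

Inversion (`stitch`) denormalizes per segment and reassembles by
overlap-discard: each window owns its central 976 samples, with ownership
boundaries adapted so the tail-anchored window never leaves a gap. The
round trip `stitch(segment(x))` is exact for any length >= 1024. When a
*component* (fetal estimate) is reconstructed from a normalized *mixture*
window, only the scale is restored, not the mixture mean.

Supervision targets are cut at the same offsets as the mixture windows and
divided by the mixture window's sd (maternal targets also have the mixture
mean removed), so predictions and targets share one scale and the stitched
estimate returns to record scale through the stored normalization state.

## Synthetic data generator

The generator emulates the structure of the FECGSYN-style simulated
corpus; it is the package's study condition, not a tuning knob.

- **Beat model.** Each beat is a sum of five Gaussians (P, Q, R, S, T)
  whose centers and widths are fractions of the local RR interval — an
  ECGSYN-style time-domain model rather than a dipole/volume-conductor
  simulation. It carries the P/QRS/T morphology that extraction must
  preserve, which is the property the network is tested on. Maternal beats
  are wider (QRS sd 1.6 % of RR vs 0.9 % fetal); fetal amplitude is set by
  the fetal/maternal R-peak ratio, default 0.25 (the corpus the taxonomy
  mirrors does not publish its ratio; 0.25 matches the usual description
  of the abdominal FECG as a small fraction of the maternal amplitude, and
  it is a parameter).
- **Rates.** Maternal 85 bpm, fetal 140 bpm by default, multiplicative RR
  jitter 3 %; physiological bounds (50–140, 100–240 bpm) are enforced.
- **Noise.** White + 0.3 Hz baseline-wander sinusoid + 50 Hz powerline in
  a 0.5/0.3/0.2 power mix, jointly rescaled so that
  `10*log10(P_fetal/P_noise)` equals the requested level exactly (the five
  levels 0, 3, 6, 9, 12 dB). SNR is defined against the *fetal* component
  because the noise levels stress fetal extraction; rescale accordingly if
  a maternal-referenced SNR is needed.
- **Scenarios.** `baseline` (no noise/events), `C0` (noise only), `C1`
  (band-limited fetal amplitude modulation, depth 0.35, < 0.4 Hz), `C2`
  (linear HR ramp applied to the fetal or maternal RR schedule, same
  jitter draws), `C3` (an EMG-like burst: 3–45 Hz noise under a ~10 s
  envelope at 1.2x the maternal R amplitude, booked as interference on the
  noise channel *after* SNR calibration, so the stated noise level keeps
  its meaning), `C4` (ectopic beats: swapped polarity, doubled QRS width;
  Poisson counts at half the requested per-minute rate in each of the two
  components), `C5-stub` (a second fetal train 25 bpm faster at 0.7x
  amplitude — a twin-pregnancy stub, not a physiological twin model).
- **Bookkeeping.** Records carry channels
  `[abdominal_mixture, maternal_truth, fetal_truth, noise]`; the mixture
  always equals the sum of the other three exactly, and R-peak annotations
  mark the exact R-wave centers. One seeded generator per record makes
  datasets byte-reproducible from their manifest.

What the generator does **not** emulate: electrode geometry and projection
(real fetal amplitude varies with fetal position), realistic EMG spectra,
waveform variability across subjects, and non-stationary noise. Passing
tests on this data therefore demonstrates that the architecture, training
loop and scoring behave as specified and that the network can learn the
separation task — not clinical-grade performance on real abdominal
recordings.

## Training

MAE loss by default (MSE available for the loss ablation), summed over the
two branches with weights (1, 1). Full-scale settings: Adam, learning rate
1e-4, batch 32, 30 epochs. The desk preset — the configuration actually
exercised by the tests and the acceptance script — uses the 1/8-width
network, learning rate 1e-3, batch 8, up to 10 epochs, and at most 500
training segments drawn from about twenty 60-second records; this fits in
a few minutes on one CPU core while leaving enough optimization steps to
learn the separation. The train/validation split is by record (10 %,
minimum one record) and the best-validation epoch's weights are kept. A
non-finite loss aborts with the offending batch named.

## Evaluation

- `MSE`, `MAE`, `SNR = 10*log10(sum y^2 / sum (y-yhat)^2)` against the
  band-passed, resampled fetal truth.
- Pan–Tompkins detection on the extracted fetal signal: band-pass
  (maternal 5–15 Hz, fetal 10–30 Hz — scaled up because the fetal QRS is
  roughly half as wide), five-point derivative, squaring, moving-window
  integration (150 ms / 80 ms), adaptive dual thresholds with running
  signal/noise estimates, search-back at half threshold for long gaps,
  refractory period 300 ms / 200 ms, and refinement to the dominant
  extremum of the band-passed signal near each integration peak.
- Matching is greedy nearest one-to-one within 31.25 ms, ties toward the
  earlier predicted peak. Greedy equals the exhaustive optimum whenever
  true beats are separated by more than twice the tolerance — guaranteed
  physiologically by the refractory period — and the suite checks this
  against a brute-force matcher.
- F1 defaults to the harmonic mean of SE and PPV, which is the convention
  consistent with published per-record tables; the literal overlap
  quantity `TP/(TP+FP+FN)` is exposed separately (`detection_jaccard`) and
  is always <= the harmonic mean.
- Aggregation: `mean_per_record` (mean ± sd across records, the default)
  or `pooled` (sum TP/FP/FN before scoring); published "total" rows are
  reproducible under either reading.

## Problem sizes and tolerances

The reference experiment (`fecgnet.experiments.desk_extraction_experiment`)
uses 22 training records of 60 s (about 350 windows, capped at 500), 10
epochs, and 5 held-out records; the detector sanity check uses a clean
140 bpm fetal ECG of 60 s. Filter contracts are asserted to ±1 dB in the
passband and >= 20 dB stopband attenuation at 0.5 Hz; oracle equivalences
to 1e-6; stitching to 1e-9; the generator's SNR calibration to 0.1 dB.

## Known limitations

- The network here is CPU-bound float64 numpy; full-scale (width 64–1024,
  1750 five-minute records) training is out of reach of this engine and of
  the package's scope — desk-scale results demonstrate behaviour, not
  state-of-the-art accuracy.
- The C5 twin scenario is a stub (a second beat train), and detection
  scoring considers only the primary fetal annotation set.
- WFDB support is a minimal single-segment format-16 reader/writer with a
  JSON annotation sidecar — enough for round trips and PhysioNet-style
  headers, not a general WFDB implementation.
- The maternal-branch target on real data (no maternal truth) is the
  abdominal mixture itself, treating fetal energy as a small residual;
  this is an approximation that full fine-tuning pipelines would refine.
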