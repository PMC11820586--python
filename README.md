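# fecgnet

Fetal ECG extraction from single-channel maternal abdominal ECG with a
W-shaped recurrent-residual attention network.

## The problem

A non-invasive fetal ECG (FECG) is buried in the maternal abdominal
recording (maECG): the maternal ECG (MECG) is several times larger, the
fetal QRS is narrower and often overlaps it, and baseline wander,
powerline interference and muscle noise sit on top. Clean FECG waveforms —
including P and T waves, not just the QRS — are what obstetric diagnosis
needs, so the extraction must reconstruct morphology, not merely locate
beats.

## The model

Two five-level 1-D attention R2U-Nets are joined in a W shape. One branch
(kernel 5) reconstructs the MECG from the mixture; the other (kernel 3)
encodes the same mixture, subtracts the maternal encoder's features level
by level through a `tanh`, and decodes the difference into the FECG:

    fetal features at level l:   tanh( E_f^l(x) − E_m^l(x) )

Each level is a recurrent residual convolution (RRC) block,

    y(0) = act(conv_f(x)),   y(t) = act(conv_f(x) + conv_r(y(t−1))),   t = 1..T,
    out  = x + y(T),         T = 2,

and skip connections are additive attention gates
`α = σ(ψ(relu(W_u u + W_g g + b_g)) + b_ψ)`, `gated = α ⊙ u`, with the
decoder-side signal `g` gating the encoder features `u` per sample
position. Training minimizes the summed mean absolute error of both
branches with Adam. Extraction quality is scored with MSE, MAE and
`SNR = 10 log₁₀(Σy²/Σ(y−ŷ)²)`; fetal QRS detection with Pan–Tompkins
followed by one-to-one peak matching at a 31.25 ms tolerance and
SE/PPV/F1.

Everything runs on a compact numpy autodiff engine included in the
package (gradients are finite-difference verified); a built-in synthetic
generator produces maternal+fetal+noise mixtures with ground-truth
waveforms and R-peak annotations under physiological-event scenarios
(C0–C5: noise only, fetal movement, heart-rate ramps, uterine
contractions, ectopic beats, a twin stub) at five noise levels
(0–12 dB), so the whole pipeline is testable without downloading
anything. See `docs/methods.md` for the full model and generator account.

## Worked example

```sh
fecgnet simulate --n 22 --scenario C0 --noise 6 --duration 60 --seed 11 --out data/
fecgnet train --manifest data/manifest.tsv --preset desk --seed 0 --out ckpt/
fecgnet simulate --n 5 --scenario C0 --noise 6 --duration 60 --seed 99 --out held/
fecgnet evaluate --checkpoint ckpt/ --records held/ --out report.tsv
```

The same experiment through the library:

```python
from fecgnet.experiments import desk_extraction_experiment
res = desk_extraction_experiment(train_seed=0)
print({k: round(v, 2) for k, v in res.items() if isinstance(v, float)})
```

prints (one CPU core, a few minutes):

```
{'snr_in_db': -13.62, 'snr_out_db': 8.43, 'snr_improvement_db': 22.05,
 'se_pct': 89.74, 'ppv_pct': 100.0, 'f1_pct': 94.58,
 'mse': 0.0, 'mae': 0.01, 'final_train_loss': 0.1}
```

Reading: the raw mixture's fetal SNR is about −14 dB (the fetal component
is a small fraction of what the channel carries); after extraction the
fetal estimate sits at about +8 dB — a ~22 dB improvement — and
Pan–Tompkins on the extracted signal recovers fetal beats with F1 ≈ 95 %
at the 31.25 ms tolerance. This is the desk-scale (1/8-width, 10-epoch)
configuration; it demonstrates the pipeline learns the separation, not
full-scale accuracy.

## Layout

- `fecgnet.signal_io` — the `Record` container; minimal WFDB and CSV I/O
  with a JSON annotation sidecar; slicing.
- `fecgnet.synthgen` — Gaussian-PQRST beat model, scenario taxonomy,
  calibrated noise, dataset manifests.
- `fecgnet.preprocess` — 3–100 Hz zero-phase band-pass, resampling to
  250 Hz, 1024-sample windows (24-sample edge overlap), per-window
  Z-score, exact inverse stitching.
- `fecgnet.r2wnet` — RRC blocks, attention gates, the W-shaped model,
  checkpoints; `fecgnet.nn` — the autodiff engine and Adam.
- `fecgnet.training` — joint two-branch loss, training loop, ablation
  harness (loss / depth / block type).
- `fecgnet.evaluation` — signal metrics, Pan–Tompkins, tolerance matching,
  SE/PPV/F1, aggregation.
- `fecgnet.cli` — `simulate`, `preprocess`, `train`, `extract`,
  `evaluate`, `ablate` subcommands.
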