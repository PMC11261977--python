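# icam — ion count-aided microscopy

Quantitative, shot-noise-mitigated secondary-electron (SE) yield mapping
for scanning charged-particle microscopy (helium-ion microscopy in
particular), built on a statistical model of the full detection chain.

## The problem

In SE imaging a focused beam dwells on each pixel; every incident ion
liberates a burst of secondary electrons that the detector converts into
a voltage pulse. Conventional images integrate the detector voltage, so
they inherit three noise sources — fluctuation in the number of incident
ions (*source shot noise*), in SEs per ion (*target shot noise*), and in
detector response — and their gray scale is arbitrary. For dose-sensitive
samples the dose needed for an acceptable image may already be damaging.

This package implements ion count-aided (ICA) imaging: the digitized
detector waveform is processed into per-pixel pulse *counts* and pulse
*heights*, and the count of detected ions replaces the nominal dose in
the yield estimate, removing most of the source shot noise and producing
maps whose pixel values are physical SE yields.

## Model and estimators

Per pixel with dose λ (ions) and yield η (SEs/ion):

- ions `M ~ Poisson(λ)`; SEs per ion `X_i ~ Poisson(η)`;
  total `Y = Σ X_i` (Neyman Type A: `E[Y] = λη`, `var Y = λη(η+1)`);
- an ion is detected iff `X_i ≥ 1`, so the pulse count
  `M̃ ~ Poisson(λ(1−e^−η))` and detected bursts are zero-truncated
  Poisson;
- a pulse carrying `j` SEs has peak height `N(j·c_μ, j·c_σ²)` where
  `c_μ`, `c_σ` are the per-SE gain and spread of the detector
  (canonically 0.163 V and 0.097 V).

Estimators of η from the measurement `(M̃, Ũ_1…Ũ_M̃)`, `V = Σ Ũ_i`:

    η̂_conv = (V/c_μ) / λ
    η̂_ICA  = (V/c_μ) / (M̃_corr + λ e^−η̂_ICA)      (solved per pixel)

`M̃_corr = M̃ / γ_τ` corrects pile-up with `γ_τ = exp(−Λ(1−e^−η)τ)` for
dose rate Λ and dead time τ. The Fisher-information ratio between the
two measurement schemes predicts the dose reduction ICA buys: ≈2.1 at
η = 2.75 and ≈1.4 at η = 1.82 for a detector with `c_σ/c_μ = 0.6` at
λ = 21, approaching `(η+1)(1−ηe^−η)` for an ideal detector.

## Worked example

`python examples/01_simulate_and_estimate.py` simulates a gold-on-silicon
squares phantom at dose 21 ions/pixel and maps it with both estimators:

```
silicon  true eta 1.82: conventional 1.822 +/- 0.521, count-aided 1.798 +/- 0.442, variance ratio 1.39
gold     true eta 2.75: conventional 2.718 +/- 0.724, count-aided 2.713 +/- 0.497, variance ratio 2.12
```

Both maps are unbiased; the pixel variance over single-material regions
is imaging noise, and its ratio (1.39 / 2.12) is the dose-reduction
factor, growing with yield exactly as the information analysis predicts.
The other examples walk the remaining capabilities: waveform synthesis
and pulse extraction with pile-up correction (`02`), detector calibration
from pulse-height distributions (`03`), the information analysis (`04`),
and Monte-Carlo dose-reduction measurement plus single-image SNR (`05`).

A thin CLI wraps the same library:
`icam simulate|process|calibrate|estimate|fisher|evaluate|pipeline`
(see `icam --help`).

## Layout

- `src/icam/model.py` — distributions of the generative model
- `src/icam/synth.py` — phantoms, measurement tuples, sampled waveforms
- `src/icam/pulses.py` — pulse detection and pile-up correction
- `src/icam/estimate.py` — the two yield estimators and yield maps
- `src/icam/calibrate.py` — detector calibration from pulse heights
- `src/icam/fisher.py` — information analysis and ratio curves
- `src/icam/evaluate.py` — noise-vs-dose curves, histograms, Thong SNR
- `src/icam/cli.py` — command-line front end
- `docs/methods.md` — modelling choices, numerics, and limitations
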