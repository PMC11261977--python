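# Methods

## Generative model

A pixel dwelled for time `t_d` under beam current `I_b` receives
`M ~ Poisson(λ)` ions, `λ = I_b·t_d/e` (elementary charge fixed at the
2019 SI exact value `1.602176634e-19 C`). Ion `i` liberates
`X_i ~ Poisson(η)` secondary electrons; the total `Y = Σ X_i` follows the
Neyman Type A law with `E[Y] = λη`, `var(Y) = λη(η+1)`. Only ions with
`X_i ≥ 1` register a pulse, so the pulse count `M̃` is a thinned Poisson
with mean `λ(1−e^−η)` and a detected burst size is zero-truncated
Poisson. The detector adds, per SE, an independent Gaussian voltage with
mean `c_μ` and standard deviation `c_σ`; a `j`-SE pulse peaks at
`N(j·c_μ, j·c_σ²)`, making the pulse-height density a zero-truncated
Poisson mixture of Gaussians. Spread is assumed to add linearly in SE
number (variance `j·c_σ²`); correlated gain fluctuations are not
modelled. The detection quantum efficiency multiplies apparent yields and
is kept strictly as an output scale factor (never inside likelihoods):
dividing a raw map by the DQE converts to absolute yields.

Canonical parameter values used as simulation defaults throughout:
`c_μ = 0.163 V`, `c_σ = 0.097 V` (so `c_σ/c_μ ≈ 0.6`), dose rate
0.6875 ions/µs (0.11 pA), dwell times 2–32 µs giving λ between ~1.4 and
22 ions/pixel, pulse FWHM 160 ns, sampling interval 10 ns.

## Series and quadrature numerics

Infinite sums over SE or pulse counts are truncated at
`max(50, ceil(mean + 10·sd))` terms of the relevant law; the omitted tail
is far below estimator noise. `total_se_pmf` uses the standard two-stage
recursion for a Poisson-stopped Poisson sum,
`p_n = (λη e^−η / n) Σ_{j<n} η^j/j! · p_{n−1−j}`, which is stable where
naive convolution loses precision; an exhaustive enumeration over ion
outcomes is kept as a test oracle only. Mixture densities are evaluated
with log-sum-exp. Fisher-information integrals use a dense trapezoid grid
spanning the mixture mean ± 12 standard deviations, with η-derivatives of
the log density by central differences at relative step `1e−4`;
grid points where the density underflows below `1e−280` are excluded.

## Estimators

The conventional estimate is `η̂ = (V/c_μ)/λ`, exactly unbiased under the
model. The ion-count-aided estimate solves
`η(M̃_corr + λe^−η) = V/c_μ`; the additive term `λe^−η` is
`E[M − M̃ | M̃]`, the expected number of ions that produced no SEs. The
root is bracketed by the denominator bounds
`[(V/c_μ)/(M̃_corr+λ), (V/c_μ)/M̃_corr]` and found by Brent iteration
(tolerance 1e−9); the objective's derivative can change sign, so it is
sampled at 32 bracket points and pixels with multiple sign changes — as
well as pixels with `V > 0` but a zero corrected count, for which no
unique root exists — are flagged and fall back to the conventional value
rather than emitting NaNs. Maps are solved with a vectorized fixed-point
iteration `η ← R/(M̃_corr + λe^−η)` (a contraction at realistic operating
points, verified against the scalar solver) with the bracketed routine as
per-pixel fallback.

The ICA estimator is implicit and nonlinear, so it carries an `O(1/λ)`
bias (≈ −0.8% at η = 2.75, λ = 21, shrinking with dose); the
conventional estimator has none. Tests assert exact mean-unbiasedness
only for the conventional route and a ≤1–3% bias envelope for ICA.

Dose-sensitivity analysis holds the measurement statistics at their
model expectations and re-solves the ICA equation with the misspecified
dose substituted *only* in the explicit `λe^−η` correction term — the
pulse count is data and is not rescaled. This convention yields a 0.8%
shift for a 10% dose error at η = 2.75. The conventional analogue is the
exact elasticity `|d ln η̂ / d ln λ| = 1`: relative dose errors transfer
one-to-one.

## Pulse extraction and pile-up

A pulse is a strict local maximum above a voltage threshold (recommended
≥5× the baseline noise), separated from the previous accepted maximum by
at least `ceil(0.8·FWHM/Δt)` samples, assigned to the pixel containing
its peak sample. The trace is first smoothed with a ~FWHM/4 boxcar,
which suppresses noise ripple that would otherwise register as spurious
flank maxima while attenuating a FWHM-wide peak by only ~0.2%.

Pile-up undercounting is corrected by `M̃_corr = M̃ / γ_τ` with
`γ_τ = exp(−Λ(1−e^−η)τ)`. Because η is unknown at processing time, the η
inside γ is resolved by fixed-point iteration with the ICA estimator
(initialized from the conventional estimate, tolerance 1e−6; γ depends
weakly on η so a few iterations suffice). γ below 0.5 is refused: the
linear small-pile-up model is invalid there, and deconvolving heavily
overlapped pulses is out of scope.

The dead time τ defaults to 0.13 µs, the canonical instrument value. On
simulated waveforms the *effective* dead time is a joint property of the
pulse kernel and the peak finder: ~0.175 µs for the default Gaussian
kernel (symmetric pulses merge when a small pulse sits within ~2.6
kernel sigmas of a large one), and smaller but less rate-stable for the
bi-exponential kernel. The package therefore provides
`calibrate_dead_time`, which inverts the exponential model on a
calibration run; tests calibrate τ at one dose rate and verify that the
γ model transfers it to the operating point within 1%.

Two waveform-level effects bound what any detection scheme can recover:
the model's Gaussian pulse heights place a few percent of pulses (~2.5%
at η = 2, threshold 0.02 V) below any usable threshold, so waveform-level
count anchors are stated against the detectable expectation
`λ(1−e^−η)·P(U ≥ threshold)`; and threshold sweeps move counts by the PHD
mass inside the swept window, which is ~1% only at yields high enough
(η ≳ 4) that little mass sits near the threshold.

## Detector calibration

`fit_phd` maximizes the unbinned log-likelihood of raw peak heights in
`(η, c_μ, c_σ)`, log-parameterized for positivity, with a Nelder–Mead
pass (tolerant of series-truncation noise) refined by L-BFGS-B; standard
errors come from the inverse observed information with a delta-method
transform. Binning is reserved for display. `cmu_low_yield` returns the
KDE mode of a low-yield PHD — at η ≲ 0.6 nearly every pulse carries one
SE so the mode sits at `c_μ`; the estimator is documented as biased
upward at higher yields. Because `c_μ`, `c_σ` are detector properties,
fits across simulated yields 0.5–3 must agree within confidence
intervals; this is the model's key self-consistency check.

## Information analysis

The count-aided measurement is `(M̃, Ũ_1…Ũ_M̃)`. Since heights are
independent of the count given the count,
`FI_icam = λe^−2η/(1−e^−η) + λ(1−e^−η)·I_U(η)`, with the single-pulse
information `I_U` computed by quadrature of the squared score. It is
validated against a Monte-Carlo score-variance oracle (finite-difference
scores on simulated data).

For the conventional channel two figures are implemented. The exact
Fisher information of the scalar `V` — an atom at zero of mass
`exp(−λ(1−e^−η))` plus the Neyman-mixture continuous part — is computed
by quadrature and validated against the same score-variance oracle; by
the data-processing inequality it never exceeds the joint information.
The ratio curves, however, use a moment-matched Gaussian noise model of
the conventional channel (`mean = ληc_μ`,
`var = λ[η(η+1)c_μ² + ηc_σ²]`, both η-dependent,
`FI = μ′²/σ² + σ²′²/2σ⁴`). This models what conventional imaging
resolves rather than the information an optimal decoder could extract
from the exact law of V, and it is the definition whose consequences
check out empirically on every axis we can test: its ideal-detector
limit is exactly `(η+1)(1−ηe^−η)` at leading order in λ, its ratio at
`c_σ/c_μ = 0.6`, λ = 21 (2.16 at η = 2.75, 1.39 at η = 1.82) matches
the Monte-Carlo conventional/ICA variance ratio within a few percent,
and below η ≈ 1 its ratio dips to ~1, reproducing the observation that
count aiding pays off only above yields of about one. The exact-mixture
ratio runs ~10% higher (2.35/1.50) because V's maximum-likelihood
decoder slightly out-performs the linear conventional estimator. Being a
noise model rather than an exact FI, the Gaussian figure is not bounded
by the data-processing inequality and can exceed the joint information
at low yield; the curves are intended for η ≳ 1 where ICA is useful.

The closed-form ideal limit `(η+1)(1−ηe^−η)` holds as `c_σ → 0` at
leading order in λ; at λ = 21 the finite-dose variance-sensitivity term
depresses the ratio by ~9%.

## Image-quality evaluation

`mc_noise_curve` simulates uniform-yield fields (no feature variance, so
no saturation) and records each estimator's pixel standard deviation;
both follow ~`1/√λ`. `dose_reduction_factor` reads the horizontal gap on
log-dose axes as the geometric mean over matched noise levels; for exact
power-law curves it equals the variance ratio at every level. Phantom
patterns with spatial η variation (`squares`, `scratch`) reproduce the
saturation of measured standard deviation at the feature floor
qualitatively; no numeric target is attached because it is
sample-dependent.

Thong's single-image SNR separates signal from noise through the
autocorrelation along the fast-scan axis: white noise contributes only at
lag 0, so a quadratic fit to lags 1–4 extrapolated to lag 0 estimates the
noise-free power `S`, and `SNR = S/(R(0)−S)`. Several extrapolation
variants exist in the literature; absolute values are variant-dependent,
so only orderings and synthetic constructions with known
signal-to-noise variance ratios are asserted.

## Synthetic data scope

The generator emulates Poisson ion arrivals (uniform arrival times within
a dwell, making per-pixel counts marginally Poisson and pile-up
realistic), zero-truncated SE bursts, Gaussian per-SE response, pulse
kernels of configurable shape (Gaussian default; bi-exponential
fast-rise/slow-decay alternative, FWHM 160 ns either way — the real
detector's shape is not pinned down), and white Gaussian baseline noise
(default sd 0.01 V, small against `c_μ = 0.163 V`; the real noise floor
is instrument-specific). It does not emulate beam-induced damage, scan
distortion, detector afterpulsing, saturation, or drift — so passing
tests demonstrate correctness of the estimation machinery under the
stated model, not robustness to instrument pathologies.

Default problem sizes in tests (1e5–4e5 pixels for Monte-Carlo moments,
1e5 pulses for calibration recovery, a few thousand 32 µs dwells for
waveform runs) keep every statistical tolerance at ≥3 standard errors
while completing on a single CPU in minutes.
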