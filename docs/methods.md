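# Methods

This note documents the models, estimators, and synthetic-data conventions in
`lnadapt`, the defaults they ship with, and the choices made where the design
was genuinely open.

## Stimulus model

A dynamic random chord (DRC) is represented by its dB-level matrix
`L[t, f]` (chords × frequencies); each 25-ms chord superposes tones on a
logarithmic grid (mouse paradigm: 25 tones, 1–64 kHz at 1/4-octave spacing;
human paradigm: 29 tones, 150 Hz–19.2 kHz). Tone levels are i.i.d. uniform in
dB within the chord's contrast regime; *contrast* is the full dB width of
that uniform (mouse: 20 dB low / 40 dB high; human: 10/30 dB) around a fixed
40 dB SPL mean. All analysis operates on the level matrix; waveform rendering
(tone synthesis with 5-ms cosine ramps and random phases) exists only for
audio export.

Because the dB scale is logarithmic, a wider uniform has a larger expected
acoustic power, so unmatched high-contrast DRCs are a few dB louder overall.
The analytic expectation of that difference is exposed as a diagnostic
(`expected_total_level_difference`), and a level-matched generator rescales
every chord's summed power `Σ 10^(L/10)` to the power of a chord at the
regime mean, equalising per-chord total level across regimes exactly at the
expense of marginal tone-level uniformity.

2-AFC trials follow the fixed 1950-ms layout: 1000 ms DRC, 100 ms broadband
noise (reference), 250 ms DRC, 100 ms noise (target), 500 ms DRC. Noise
probes enter the spectrogram as flat blocks at `level − 10·log10(n_channels)`
per channel so that channel powers sum to the stated total.

## Encoding model and estimators

**Linear stage.** The STRF is constrained to be separable,
`k_fh = k_f ⊗ k_h`, with a causal temporal kernel on 25-ms taps
(`n_history` = 10 taps = 250 ms by default; unstated in the source paradigm
and configurable). Fitting is Gaussian maximum likelihood — alternating
closed-form ridge regressions for `k_f` and `k_h`, each sub-problem being
linear because the factorisation is bilinear — iterated until the relative
training-error change falls below 1e-6 or 200 iterations. A small ridge
penalty (1e-3 relative to the mean design norm, intercept unpenalised) keeps
near-collinear designs conditioned; this is a documented deviation from pure
ML. The canonical form is unique: unit-norm temporal kernel with
non-negative peak, scale and sign carried by `k_f`. Pre-stimulus history is
padded with the first chord. PSTHs are trial-averaged spike counts in 25-ms
bins aligned 1:1 with chords, with the first 500 ms of every presentation
excluded (onset transients are outside the steady-state model).

Tuning parameters: best frequency (BF) is the grid frequency at the spectral
kernel's maximum; frequency bandwidth is the FWHM of `k_f` in octaves with
linear interpolation between channels (truncated at the kernel edge and
flagged if the half-max is never crossed); temporal bandwidth is the FWHM of
`k_h` in ms, floored at one 25-ms bin; max weight is the largest entry of the
full kernel.

**Output nonlinearity.** Per contrast condition, rate is a 4-parameter
sigmoid of the shared drive with gain `b/(4d)`. Fitting minimises squared
error (consistent with the dynamic model's objective) with a deterministic
multi-start — `c` over drive quantiles 0.1…0.9, `d` over decades of the
drive SD, the best few starts refined by bounded trust-region least squares
with an analytic Jacobian. Constraints `b ≥ 0, d > 0` resolve the sign
degeneracy of `(b, d)`. Whether the original analysis constrained parameters
is unknown; these are identifiability choices. Compensation uses the uniform
dB widths as the contrast values `C`, and the cortical-silencing effect is
the % gain (or y-offset) change across contrast with cortex off minus the
same change with cortex on.

**Reliability screen.** With `P(·)` the population variance of a response
across time bins and N repeats:

    SP = (N·P(mean PSTH) − mean_n P(trial_n)) / (N − 1),
    NP = mean_n P(trial_n) − SP.

`SP + NP` equals the mean per-trial power identically, and SP is an unbiased
estimate of the stimulus-locked rate power (slightly negative estimates are
preserved, not clamped, so the screen can act on them). Units are retained
iff NP/SP ≤ 60 and the cross-validated linear prediction correlation
`cc_pred` ≥ 0.1 (both inclusive at the boundary, both configurable; the
train/test split is 90/10 contiguous by default).

## Adaptation dynamics

On switching-contrast stimuli each sigmoid parameter is interpolated through
a smoothed contrast trace `s_t = Σ_h w_h C_{t−h}` with
`w_h ∝ exp(−h/τ′)` normalised to sum to one over a horizon keeping residual
kernel weight below 1e-4. Normalisation is the reading under which sustained
contrast drives the parameters exactly to their steady-state values, which
the two-state model requires; pre-stimulus history is initialised to the
first epoch's state to avoid spurious onset transients. One τ is shared by
all four parameters. The fit initialises the static per-contrast sigmoids on
the last second of each 2-s epoch, then jointly optimises the nine
parameters by L-BFGS-B from four τ starts (10/50/200/600 ms) with
τ ∈ [1, 700] ms; 700 ms is the cap because slower time constants cannot be
reliably estimated from 2-s epochs (a fitted τ at the cap is flagged as a
ceiling). If the two fitted steady states predict rates closer than the
per-bin residual noise, τ is flagged unidentifiable.

Model selection compares three nested variants by cross-validated
correlation (5 contiguous folds): a single contrast-independent sigmoid, an
instantaneous two-state model, and the τ-augmented model. A unit is
"contrast dependent" when the two-state model wins, and "τ improves" when
the adaptive model then beats the instantaneous one; τ is only interpreted
for contrast-dependent units.

## Psychometrics and the neurometric model

Psychometric curves are maximum-likelihood sigmoids of target level with a
cumulative-Gaussian (probit) core by default and guess/lapse asymptotes
estimated in [0, 0.05]; a logistic core and fixed asymptotes are available
as options. The probit default is deliberate: the ideal-observer form of
both the synthetic observers and the Poisson-count decision rule is
Gaussian, and an ML logit fit to probit-shaped data narrows the estimated
25–75% width by ~10% (it steepens to chase the lighter Gaussian tails),
which would bias every JND downstream. The JND is the dB distance between
the 25% and 75% points of the fitted curve; treating discrimination
sensitivity as `G = 1/JND`, perceptual compensation uses the same formula as
neuronal gain. Because group aggregation of per-participant compensation is
ambiguous (averaging per-participant values differs from the compensation of
mean JNDs), the participant table reports per-participant values and leaves
aggregation to the caller.

The neurometric model reads a population of contrast-dependent LN units: for
each trial, each unit's rate in a decision window around each noise probe is
taken from the contrast-appropriate sigmoid on its STRF drive (clamped at
zero), counts are Poisson, summed across units and window bins, and the
probe with more spikes is called "louder" (ties by fair coin — any
deterministic tie rule would bias P(louder) at threshold). The decision
window is the probe's four 25-ms bins plus a latency allowance derived from
the population's temporal-kernel peak lag (one bin for causal kernels
peaking at lag 1, zero for instantaneous kernels); the window is
configurable. Since a sum of independent Poisson counts is Poisson in the
summed rate, the batch simulator draws one variate per window from the
population-summed rate — statistically identical to per-unit draws.
Equal weighting of units is assumed. The default paradigm is 9 target levels
(62–78 dB, reference 70 dB), 500 trials per level, 25 runs per population,
in 20-dB and 40-dB contrast flanking DRC.

## Synthetic ground truth

`make_population` builds LN units whose compensation is exact by
construction: the y-range `b` is shared between contrast conditions and the
gain change is carried entirely by the sigmoid width,
`d_high = d_low · (1 + target·(C_high−C_low)/(100·C_low))`. Carrying the
gain change in `d` (not `b`) keeps the firing rate at the sigmoid midpoint
identical across contrasts, so Poisson noise at the psychophysical reference
level is contrast-invariant and a 100%-compensating population yields
JND_high = 2·JND_low exactly in the ideal-observer limit; a `b`-carried gain
change would confound gain with rate (and hence noise) changes. STRF truth
kernels are Gabor-like Gaussians in frequency (σ = 2 channels) times a
difference-of-exponentials in time, BFs tiling the grid interior; defaults
put the baseline at 0.25 and the range at 2.5 spikes per 25-ms bin (10 and
100 spikes/s). Adaptation time constants default to a lognormal with median
100 ms. Sigmoid rates are clamped at zero before Poisson draws (rates must
be non-negative; fitted sigmoids with `a < 0` can dip below zero).

Two operating points are provided. `"drc"` (default) centres the sigmoid on
the mean DRC drive with `d_low` equal to the low-contrast drive SD — the
regime in which STRF, sigmoid, and τ recovery are exercised. `"probe"`
centres the sigmoid on the drive of a flat noise probe at the reference
level (70 dB), with an instantaneous, spectrally broad kernel (σ = 6
channels) and 5 dB of probe level per width unit. The probe variant exists
because neurometric readout requires monotone level sensitivity around the
reference: units fitted around the DRC drive saturate at probe levels, and
multi-bin kernels mix probe and flanking-DRC drive inside the decision
window, breaking the proportionality between neuronal gain and probe-level
sensitivity. This is also why populations of realistic DRC-fitted units
predict *less* perceptual compensation than their neuronal compensation — a
compression the decision model genuinely produces — while the probe-point
fixture isolates the gain→JND link for validation.

## What the synthetic data do and do not emulate

The generator reproduces the study conditions (stimulus statistics, 25-ms
binning, Poisson variability, contrast-dependent sigmoids with exponential
relaxation, 2-AFC trial structure) but not: non-Poisson spiking history
effects, non-separable or contrast-dependent STRFs, multiple simultaneous
adaptation time scales, correlated noise across units, or attentional/state
fluctuations in observers. Passing recovery tests therefore demonstrates
estimator correctness under the model's own assumptions, not robustness of
the published physiological values; the headline recordings behind those
values are available only on request and are not reproduced here.

## Problem sizes and numerics

Default validation scales: 40-s stimuli (1600 chords), 20 Poisson repeats
for constant-contrast fits, 40 for switching-contrast fits; a 50-unit
population for pipeline recovery; neurometric demo runs use 5 runs × 100
trials/level (the full paradigm, 25 × 500, is a config change). Bootstrapped
95% CIs of medians use 10,000 resamples. Degenerate inputs are handled
explicitly: constant responses fit `b ≈ 0` with a flag, all-zero PSTHs give
zero kernels, empty screened populations produce an empty-but-valid report,
psychometric fits pinned at a response bound are flagged and excluded from
run summaries. Every stochastic step takes an explicit seed and identical
configuration plus seed reproduces outputs bit-for-bit.
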