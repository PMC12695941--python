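# Methods

This note documents the models, parameter choices and numerical decisions
behind `vocsig`, in the order data flows through the pipeline.

## Synthetic call model

The generator exists to give every statistical stage a ground truth: a
cohort in which we *know* how much of the acoustic variance separates
individuals and how much is per-call jitter. It is a deliberately minimal
source–filter model, not a physiological one.

**Meows** are additive harmonic stacks at a per-call fundamental
(individual mean ± Gaussian jitter, truncated to 150–1200 Hz). Harmonic
*k* has amplitude `k⁻² · (1 + 2.5 · Σⱼ exp(−(f_k − Fⱼ)²/2bwⱼ²))`: a
−12 dB/octave source tilt shaped by two Gaussian resonance bumps — a crude
vocal-tract filter whose centre placement is the main carrier of
individuality for the MFCCs. The peak gain of 2.5 is deliberately smaller
than the 4× tilt drop between harmonics 1 and 2, so the fundamental is
always the largest spectral peak below the first resonance (a property the
tests verify by FFT peak-picking). The amplitude envelope rises over the
first 15% and decays over the last 30% of the call, mimicking the
open-then-closing-mouth contour of a meow. Default individual means:
F0 450 ± 80 Hz between individuals, resonances near 950 and 2800 Hz
(± 120/220 Hz between individuals), duration 0.72 ± 0.25 s truncated to
the observed 0.17–2.21 s range.

**Purrs** are pulse trains at a per-call rate truncated to 20–40 Hz
(individual means 27.5 ± 2 Hz): each pulse is an exponentially damped
white-noise burst occupying `pulse_duty_cycle` of the period, and the
assembled train is passed through a two-pole resonance at an
individual-specific centre (400 ± 90 Hz between individuals). A square
alternation at 0.9 Hz between gain 1 (egressive) and gain
`envelope_asymmetry` (ingressive) emulates the two breathing phases;
asymmetry 1 gives equal-RMS half-cycles. Durations follow 10.77 ± 2.5 s
truncated to 1.09–39.82 s, the observed purr range. No published
per-individual spectral statistics exist for purrs, so the burst-envelope
parameterisation is a free modelling choice validated purely through
recovery properties (separability must rise with between-individual
variance and vanish under label permutation).

`between_sd_scale` multiplies every between-individual spread,
`within_sd_scale` every per-call jitter; at `between_sd_scale = 0` all
profiles are identical, giving an exact null cohort. Truncation is by
clipping (simple, deterministic, keeps the draw count fixed). One RNG
stream per cohort is seeded from `CohortSpec.seed`; profile sampling
consumes the stream before any call synthesis, so cohorts are
byte-reproducible.

**What the generator does not emulate:** background noise, reverberation,
microphone variation, context-dependent modulation (arousal, addressee),
amplitude cues (deliberately — features are gain-invariant), or realistic
formant dynamics within a call. Passing tests therefore show that the
statistics recover a *clean* planted signal at realistic sample sizes; they
do not bound performance on field recordings.

**Problem sizes.** Simulated cohorts default to 8 individuals × 15 calls
(the scale of the balanced comparison, 117 calls per type over 8 cats) and
the species simulations to 6 × 40 = 240 calls (the scale of the ~250-call
cross-species set). Synthetic meows are rendered at 16 kHz and purrs at
4 kHz: the meow model contains no energy above ~6 kHz and the purr model
none above ~1 kHz, so these rates leave ample spectral headroom while
keeping simulation-heavy tests fast. Real 96 kHz recordings are fully
supported and 96 kHz remains the synthesis default outside the test suite.

## Feature extraction

Per call: duration (samples / rate), spectral centroid (magnitude-weighted
mean over positive frequencies of the whole-call rFFT), and MFCC1–10.

The MFCC chain is the classical one — Hamming-windowed frames, magnitude
rFFT, triangular mel filterbank, log, orthonormal DCT-II, frame average —
with these fixed decisions:

- **Window:** 30 ms (meow) / 300 ms (purr); the two call types differ by
  ~40× in F0 and ~15× in duration, so one window cannot serve both.
- **Hop:** 50% of the window. Only full frames are analysed (a trailing
  partial frame is dropped) to avoid zero-padding bias in the average.
- **Filterbank:** 26 triangular filters, centres equally spaced in mel
  (m(f) = 2595·log₁₀(1 + f/700)) between 0 Hz and Nyquist. Construction
  fails loudly if the FFT cannot resolve adjacent centres.
- **No pre-emphasis:** the purr fundamental region (tens of Hz) is exactly
  where individual information lives; a pre-emphasis filter would suppress
  it.
- **c₀ excluded:** "10 MFCCs" means coefficients 1–10. c₀ is a loudness
  proxy; excluding it makes the coefficients exactly invariant to any
  positive gain, which the tests assert to 10⁻⁸. (`include_c0=True` is
  available for sensitivity checks.)
- **Log floor:** `1e-12 ×` the call's maximum filterbank energy, added
  before the log. Relative (not absolute) so gain invariance is exact;
  silent calls fall back to an absolute floor and yield finite
  coefficients.
- **DCT:** orthonormal type-II, fixing the coefficient scale across
  implementations. The test suite verifies the whole chain against an
  independently coded brute-force implementation (explicit per-frame DFT,
  hand-built triangles and DCT matrix).

QC spectrograms use a 1024-point FFT with a Hamming window at 87.5%
overlap; at 96 kHz that is a 93.75 Hz bin width and a 1.33 ms hop, and the
code reports both.

## Discriminant analysis

`stepwise_select` implements the classical Wilks'-Λ procedure: at each
step, among features not yet entered, the one minimising the overall
Λ = det(W)/det(T) enters if its partial
F = ((N−g−p)/(g−1))·(Λ_p/Λ_{p+1} − 1) reaches `f_to_enter`; entered
features whose F-to-remove falls below `f_to_remove` are removed.
Defaults 3.84 / 2.71 are the conventional thresholds of the commercial DFA
implementations this mirrors; they are parameters, not constants. Before
selection, features with tolerance (1 − R² against the others) below
0.001 are screened out, dropping the later column on ties so the screen is
order-stable.

`fit_lda` solves the symmetric generalized eigenproblem B·v = λ·W·v
(between- vs within-group SSCP) via `scipy.linalg.eigh`, keeps
min(p, g−1) functions, and scales coefficients to unit pooled within-group
score variance. Reported per function k: eigenvalue, explained variation
100·λₖ/Σλ, residual Wilks' Λₖ = Π_{i≥k} 1/(1+λᵢ), and the chi-squared
approximation −(N − 1 − (p+g)/2)·ln Λₖ on (p−k+1)(g−k+1) df. Tiny negative
eigenvalues from the decomposition are clipped to zero; a singular
within-group matrix raises with the offending feature list.

Classification uses linear scores with the shared pooled covariance
(x'S⁻¹μ_g − ½μ_g'S⁻¹μ_g + ln π_g), priors proportional to full-sample
group sizes by default (uniform by flag). Leave-one-out refits the means
and pooled covariance on every fold; feature selection is performed once
on the full data and held fixed (the standard behaviour of the software
this emulates), with a strict nested-selection mode available for
sensitivity analysis. Ties in the posterior break to the larger prior,
then label order — determinism over elegance. If selection returns no
features (a real possibility on null data at F-to-enter 3.84),
classification falls back to priors alone, which keeps the permutation
null centred on the chance level rather than biased by forced fitting.
Holding out a call from a group of two would leave a single member, so
LOOCV requires three calls per group and errors otherwise.

The exact binomial test of classification success is one-sided (greater),
because the hypothesis is directional.

## Stereotypy index and capacity

For each parameter, F = MS_between/MS_within with individual identity as
the single factor (with one factor, type II sums of squares equal type I,
and treating the factor as random changes nothing about this ratio — noted
here once). Then Hₛ = log₂√((F + n̄ − 1)/n̄). F = 1 gives exactly 0 bits;
F < 1 would give negative bits and is clipped to 0, since information
content cannot be negative and sub-null F is sampling noise. n̄ is the
pooled mean calls per individual of the table actually analysed (rows /
groups), not a hard-coded constant. Contributions are summed over the raw
ten MFCCs — no PCA decorrelation — matching how the index is convention-
ally applied to MFCC sets; a decorrelated variant (PCA rotation before the
per-parameter F) is available behind `decorrelate=True` for users worried
about double-counting correlated coefficients. Duration and spectral
centroid stay descriptive and are not summed into H_S. Capacity is
2^H_S individuals.

## Signal-space dispersion

Calls are projected onto the retained discriminant functions; each call's
dispersion is its Euclidean distance to its own group's centroid.
Centroids are recomputed from the projected calls (not read off the
model), so the operation also works for held-out projections. The default
space uses *all* retained functions; a 2-function mode reproduces the
conventional two-dimensional signal-space plots. Distances are compared
across groups by one-way ANOVA with partial η² = SS_b/(SS_b+SS_w) and
Tukey-HSD post-hoc contrasts (Bonferroni-corrected t-tests by flag) —
Tukey being the conventional companion of a one-way ANOVA when the
procedure is otherwise unspecified. Degenerate inputs are handled
explicitly: zero total variance errors; zero within-group variance with
nonzero between reports F = ∞, p = 0, η² = 1.

## Known limitations

- The synthesizer's individuality model is low-dimensional (F0, two
  resonances/one burst centre, duration, duty cycle, asymmetry); real
  vocal signatures are richer and noisier.
- Stepwise selection inherits the known optimism of selecting on the full
  sample before leave-one-out classification; the nested mode quantifies
  that optimism but is slower.
- The chi-squared test for residual functions is asymptotic and unreliable
  for very small groups.
- Exact numeric reproduction of any externally published MFCC table is
  not guaranteed: frame overlap, filterbank size, frequency limits and the
  c₀ convention vary between implementations, which is why all of them are
  explicit configuration here.
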