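# Methods

## Signal model of the synthetic generator

Sympathetic nerve activity is simulated as multiplicative amplitude
modulation over an additive instrument floor:

    x(t) = A · m(t) · c(t) + ε(t)

- **m(t)**, the slow modulator, is a rectified sum of sinusoids,
  `m(t) = max(0, 1 + d · Σᵢ aᵢ sin(2π fᵢ t + φᵢ⁰ + φᵢ(t)))`, with
  modulation depth `d ∈ [0, 1]` (default 0.6). Rectification keeps the
  envelope non-negative, as a physical amplitude must be; the harmonics
  it introduces are part of the model. Each component's phase drifts as
  a stationary Ornstein–Uhlenbeck process (default s.d. 0.1 rad, time
  constant 10 s), a minimal stand-in for the slow jitter that
  baroreceptor entrainment imposes on burst timing.
- **c(t)**, the burst carrier, is white noise shaped by second-order
  Butterworth band-passes centred on the configured carrier peaks and
  normalised to unit variance. Bursts of action potentials are
  broadband events, so the carrier is shaped noise, not a sinusoid.
- **ε(t)** is white noise with s.d. `noise_floor_sd` (default 0.05,
  i.e. 5 % of the carrier s.d.), the analogue of the residual signal
  under ganglionic blockade. `generate_noise_floor` emits a pure-floor
  trace from a decorrelated stream of the same seed.

All draws flow through one `numpy` Generator seeded from the config, so
identical (config, seed) reproduces samples bit for bit. Cohort
members use `base_seed + animal_id`.

### Default study conditions

Defaults encode the study design this pipeline addresses: 3 groups
(normotensive control; renovascular-hypertensive 2K1C; 2K1C treated
with the AT1 antagonist losartan) × 2 nerves (renal, splanchnic) ×
2 conditions (baseline BAS; BIC, after GABA-A antagonist disinhibition
of the hypothalamic paraventricular nucleus), 5 animals per group,
10-min recordings at 1 kHz.

- Baseline envelope components lie in the 0–2 Hz and 6–8 Hz bands, with
  per-(group, nerve) positions and amplitude ratios so each of the six
  composite classes has a distinct PSD shape; the losartan group
  carries its extra 5 and 8 Hz components.
- BIC envelope components collapse to a shared pattern: 0.5 Hz dominant
  and 1.5 Hz at half its amplitude. The shared level exceeds the
  baseline sub-4 Hz power, reproducing the rise of the 0–4 Hz band and
  fall of the 4–10 Hz band after disinhibition. A `convergence`
  parameter in [0, 1] interpolates between the class-specific baseline
  pattern (0) and the fully shared pattern (1, the default); sweeping
  it is how the distance-contraction behaviour is probed.
- Carrier peaks sit at 150 Hz (dominant) and 190 Hz (weaker, with
  class-specific relative power 0.4–0.8); the hypertensive splanchnic
  nerve after disinhibition instead carries a single 90 Hz peak.
- Amplitudes are arbitrary units throughout: no absolute calibration
  exists for multiunit nerve recordings, so only relative spectral
  structure is meaningful.

### What the generator does not emulate

Real recordings contain cardiac-locked rhythmicity, respiratory
coupling, non-stationary drift, movement artifacts, correlated (not
white) instrument noise, and discrete spike waveforms. Passing tests
against this generator therefore demonstrate that the analysis chain
recovers the spectral structure it is pointed at — not that it is
robust to every pathology of in-vivo data.

## Conditioning

- **Resampling**: polyphase with a Kaiser (β = 5) anti-alias filter;
  the identity when rates already match. Anti-aliasing is always
  applied before decimation.
- **Comb notch**: cascaded second-order IIR notches at 60 k Hz for all
  harmonics below Nyquist. The quality factor (35 at the fundamental)
  is scaled per harmonic (Q·k) so every notch has the same ≈1.7 Hz
  absolute bandwidth; a constant relative Q would violate the ±1 dB
  pass-band contract 5 Hz away from the upper harmonics.
- **Band-pass**: Chebyshev type-I, total order 12 (N = 6 per edge in
  the scipy convention, doubled by the band transform), 2 dB ripple,
  1–200 Hz. "Ripple" implies an equiripple pass-band, hence the
  Chebyshev-I family.
- **Zero phase**: all IIR filters run forward–backward so envelope
  timing is undistorted. This doubles effective ripple and attenuation;
  contracts are stated against the doubled figures (e.g. a pass-band
  tone may sit 4 dB down). Zero-phase application also leaves a
  boundary ring-down (~0.6 s for the notch bandwidth), so steady-state
  attenuation is measured on the signal interior.
- **Noise floor**: subtraction happens at the integrated-activity
  level. The floor's mean rectified amplitude and mean-square power are
  stored as scalars; Δ-integrated activity subtracts the former, and
  additive signal power is recovered as E[(s+n)²] − E[n²]. Sample-wise
  subtraction would be wrong: an independent floor waveform is
  uncorrelated with the signal.

One acquisition subtlety is deliberately surfaced rather than hidden:
data acquired with a 100–1,000 Hz hardware band-pass and later
down-sampled to 1 kHz would fold 500–1,000 Hz content; the resampler
therefore always low-passes below the target Nyquist before
decimation.

## Envelope channel

The default envelope is the centred sliding-window RMS over 50 samples
(50 ms at 1 kHz) — the estimator that carries an explicit parameter in
the protocol — with shrunken windows at the edges to avoid group
delay. The Hilbert analytic envelope is provided and selectable; for a
sinusoidal carrier the two differ by exactly √2 (RMS vs instantaneous
amplitude), which the tests pin down. The Hilbert envelope of an
offset signal is offset-dominated, so a mean-removal flag exists (off
by default). Pipeline order is fixed as filter → envelope.

## Spectral estimation

A window covering 0.5 % of the recording slides with 20 % overlap
(3,000-sample windows, 2,400-sample steps and exactly
⌊(N−w)/step⌋+1 = 249 rows for N = 600,000). Each window is demeaned,
Hann-tapered and transformed with nfft = next power of two; density
scaling makes the row integral equal the windowed-segment variance
(Parseval, exact up to trapezoid end corrections). The inner estimator
is a single periodogram per window, not a nested Welch average: the
sliding rows themselves are the averaging, and keeping them un-averaged
is what provides "trials" to the discriminant analysis. With 3,000
samples at 1 kHz, resolution (0.33 Hz native, 0.24 Hz on the padded
grid) separates the 0.5 and 1.5 Hz disinhibition peaks.

Band powers integrate over half-open [low, high) intervals with linear
interpolation at the edges, so [0,4)+[4,10) equals [0,10) exactly.
Peak frequency is the in-band argmax with ties broken toward the lower
frequency. Group-mean PSDs pool all windows of all animals (equal
window weight) with a per-bin t-interval of the mean; per-animal
weighting is a documented alternative the data layout supports.

## Canonical discriminant analysis

Features are log10 PSD values (spectral power is multiplicative and
heavy-tailed; linear mode is selectable) at the grid bins inside the
channel's range — 0–10 Hz for the envelope channel, 1–200 Hz for the
burst channel. Trials are sliding-window PSDs pooled across animals
within a (group, nerve) class; analyses run separately per condition.

Because bins can outnumber trials, features are first projected onto
the principal components retaining 99 % variance (capped at
n − n_classes so W stays full rank); the canonical directions are
mapped back to frequency space afterwards. The generalized eigenproblem
B v = λ W v is solved with a symmetric-definite solver; diagonal
shrinkage of W (ε = 10⁻⁸ · tr W / m) is the fallback if the reduced
problem is still singular, with a warning. Canonical vectors are scaled
so the pooled within-class covariance of scores is the identity
(Euclidean distance in score space is then a Mahalanobis-type
separation) and signed so the largest-magnitude coefficient is
positive, making runs reproducible.

Dimensionality is tested with sequential Wilks' Λ,
Λ_d = Π_{i≥d} (1+λ_i)⁻¹, using Bartlett's chi-square approximation
with (p−d+1)(c−d) degrees of freedom.

Centroids are per-class mean score vectors on the first k (default 3)
canonical variables; distances are raw Euclidean in those coordinates
(no further standardisation). The contraction statistic is the
elementwise ratio d_BAS/d_BIC with per-pair table and maximum; a zero
BIC distance reports an infinite ratio with a flag. Note each
condition's geometry lives in its own canonical space — the ratio
compares within-space separations, not positions across spaces.

Held-out evaluation supports window-level holdout (every 5th window)
and stratified per-animal holdout; the latter guards against the
pseudo-replication of correlated windows from one animal appearing on
both sides of the split.

## Statistical dispatch

Normality is gated per group with the Lilliefors-corrected KS test
(parameters are estimated from the data, so plain KS would be too
lenient); Shapiro–Wilk covers n = 3, below the Lilliefors table.
All groups normal → ANOVA (3+ groups) or t-test (2), with
Bonferroni-adjusted pairwise t-tests post hoc; otherwise
Kruskal–Wallis / Mann–Whitney with Bonferroni-adjusted pairwise
Mann–Whitney. Bonferroni is min(1, m·p) with m = C(groups, 2).
Family-wise correction applies only within one comparison's post-hoc
family, not across bands or nerves. Descriptives are mean ± t-CI or
median ± 2,000-resample bootstrap percentile CI (fixed seed). Paired
variants (paired t, Wilcoxon) are exposed; unpaired is the default
because the pairing structure across conditions is a design choice
left to the user. A zero-variance group on the parametric branch
triggers a warned switch to the rank branch; fully constant data
returns "no difference" rather than an error.

## Pipeline and problem sizes

The default study is 3 × 2 × 5 animals recorded in both conditions —
60 traces of 600 s at 1 kHz — and runs end to end in about a minute on
one CPU, writing deterministic CSV/JSON artifacts (full-precision
floats, sorted JSON keys; rerunning with the same seed is
byte-identical). Test-suite simulations use reduced sizes chosen to
keep each check statistically decisive: null-calibration replicates
use 60-s recordings and 2 animals per class (the sliding window is a
fraction of the signal, so row counts are duration-invariant), the
convergence sweep uses 300-s recordings and 3 animals per class, and
parameter-recovery cohorts use 3 animals.

## Known limitations

- The carrier is stationary shaped noise; it reproduces burst *spectra*
  but not discrete burst events, so no burst-time statistics
  (inter-burst intervals, synchronicity) are available.
- Carrier peak positions are recovered to within half the configured
  bandwidth, not to one frequency bin: the argmax of a band-limited
  noise PSD wanders over the near-flat peak top at any realistic
  averaging depth.
- The equiripple band-pass makes the conditioning chain non-idempotent
  at the ripple scale; re-application costs ripple-shaped band power by
  design.
- Wilks' chi-square calibration assumes independent trials; the 20 %
  window overlap introduces a small positive correlation between
  adjacent rows that the null simulations show to be negligible at the
  default settings.
- Phase-amplitude-coupling statistics are out of scope: the analysis
  treats the two channels separately and never quantifies their
  coupling.
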