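# Methods

## The envelope spectrum

A band-limited EEG signal `x_b(t)` has analytic representation
`x_b + i H[x_b]`; its modulus `e_b(t)` is the instantaneous amplitude.
The power spectral density of `e_b` describes the rhythmicity of
amplitude fluctuations: slow-wave activity pulsing every 20 s appears as
a ~0.05 Hz envelope peak, spindle trains every 4 s as ~0.25 Hz.  Because
these rhythms live far below 1 Hz, their estimation needs windows of
order 100 s — long enough that ordinary discard-on-artifact windowing
becomes wasteful.  Everything in this package exists around that tension.

Eight analysis bands are canonical: low delta 0.5–2, high delta 2–4,
theta 4–7, alpha 7–10, low sigma 10–12.5, high sigma 12.5–16, beta
16–30, gamma 30–49 Hz.  The two-band demonstration signal uses a wider
delta (1–4 Hz) and sigma (10–16 Hz) pair, chosen so each band holds
exactly one modulated component.

## Filtering and envelope extraction

Band filtering is a least-squares FIR design applied forward and
backward (zero phase).  Defaults: `5 * rate / low_edge` taps (five
cycles of the lowest pass-band frequency, forced odd), 0.25 fractional
transition bands, pass band weighted 10× in the least-squares fit.
These were chosen so that after the forward–backward pass the interior
pass-band gain is within ~3% of unity for every canonical band at
250 Hz while tones one transition width outside the band are suppressed
by far more than 30 dB; a shorter 3-cycle design left 7–22% pass-band
power ripple.  `numtaps` is configurable.  Recordings shorter than three
filter lengths are rejected with advice rather than silently padded.

Envelopes are computed once on the continuous filtered recording (no
per-window re-filtering, which would add edge transients inside every
window).  The Hilbert transform uses no padding; the few samples at the
recording edges carry a small transient bias.  Windows beginning at
t = 0 or ending at the recording end do include these samples; with
100-s windows the bias affects well under 1% of any window's samples and
is ignored.

MUA is `|raw|` low-passed at 20 Hz (4th-order Butterworth, zero phase) —
a standard firing-rate proxy for high-rate (300–5000 Hz) intracortical
data.  For coupling with band b it is further smoothed by a centered
moving average of `round(rate / high_edge_b)` samples (shrinking at the
edges), removing MUA fluctuations faster than the band envelope can
follow.

## The colliding-window estimator

Candidate 100-s windows start on the absolute 20-s grid inside each
contiguous artifact-free, single-state run (the artifact mask has 4-s
cells, staging 20-s epochs; the planner works on their union at 4-s
resolution, and stage boundaries obstruct windows exactly like
artifacts).  A candidate that would cross an obstruction is truncated to
end at it; below the 20-s minimum it is dropped and placement resumes at
the next clean in-state 20-s grid point.  A second pass runs backward
from the recording end (implemented as the forward pass on the
time-reversed mask), so data just *after* an obstruction is sampled as
densely as data before it.  Both passes are pooled; a window emitted
identically by both counts once — the backward pass exists for coverage
balance, not double weighting.  At the recording ends no truncation
occurs (the mirrored pass covers the opposite edge), except that a clean
run bounded by the recording end too short for any full window emits its
single maximal truncated window, so sub-100-s recordings remain usable.
Consequences: on clean data whose duration is a multiple of 20 s the two
passes emit identical window sets and the estimate reduces to a plain
100-s/20-s-step weighted Welch average, and an isolated short artifact
leaves at most 20 s of clean signal uncovered instead of up to 100 s.

Each window of length L seconds is linearly detrended (which includes
demeaning), Hamming-tapered, and evaluated at exactly 0.01–4.00 Hz in
0.01 Hz steps via the chirp-z transform — the DTFT at the requested
frequencies, equivalent to a frequency-vector periodogram, regardless of
whether they are Fourier bins of the segment.  Bins below 1/L Hz carry
no information for a window of length L and are excluded.  Aggregation
is a per-frequency weighted mean with weight L/100, restricted to
windows supporting that frequency; per-bin total weight is recorded and
zero-weight bins flagged missing.

The averaged spectrum is Savitzky–Golay smoothed (polynomial order 10
over a 21-bin / 0.21 Hz frame — the smallest odd frame comfortably above
the order, preserving the ~0.05 and ~0.25 Hz peaks while suppressing
bin noise), `log10`-transformed, and z-scored across the 0.01–2 Hz
analysis sub-grid per band × channel (the analyzed feature space ends at
2 Hz; the 2–4 Hz estimation margin is kept but not standardized
against).  Densities driven non-positive by smoothing overshoot are
clipped to the spectrum's smallest positive density (logged); a spectrum
whose post-log spread is below 1e-6 (the jitter the ill-conditioned
order-10 fit leaves on an exactly constant input) cannot be z-scored and
raises.  Missing bins inside the sub-grid are linearly interpolated and
logged.  Grossly abnormal cohort spectra are flagged — not dropped — when
more than 10% of a band's bins lie over 5 cohort SDs from the cohort
mean, a reproducible screen standing in for visual inspection.

## Coupling statistics and inference

Per 20-s artifact-free NREM segment, three statistics relate a band
envelope to smoothed MUA, each averaged across segments:

* **Cross-correlation**: both series linearly detrended, coefficient
  normalization by the zero-lag energies, lags −1…+1 s; a positive-lag
  extremum means the firing pattern trails the envelope.
* **Coherence**: Welch magnitude-squared coherence with 10-s Hamming
  sub-windows at 50% overlap (three per segment — the minimum giving the
  0.1 Hz native resolution that puts 0.1…1.0 Hz on exact bins).  With so
  few sub-windows the estimator has a substantial positive bias under
  independence (~0.35, established by simulation); comparisons against
  surrogate nulls share this bias and remain valid.
* **Phase–amplitude profile**: instantaneous phase from the analytic
  signal of the demeaned smoothed MUA — phase 0° at the positive peak,
  left-closed 30° bins — and mean within-segment-z-scored envelope
  amplitude per bin.  Empty bins in a segment are excluded from that
  bin's average.

Significance uses surrogate re-pairing: each envelope segment is matched
with a uniformly drawn (with replacement; self-pairing's probability
vanishes with segment count) MUA segment, the segment-averaged statistic
recomputed, 1000 times by default.  The empirical two-sided p-value
carries the +1 correction, `p = (1 + #{|surr| ≥ |obs|}) / (n + 1)`,
bounding p away from zero — standard for permutation tests, and the one
deliberate deviation from defining p as a bare proportion.  Because all
three statistics are averages of per-pair values, the implementation
precomputes the segment-pair matrix once and each surrogate reduces to
indexing, which is what makes calibration suites (200 surrogates × 200
replicates) run in about a second.

Per-subject p-values pool by averaging standard-normal deviates,
`pooled = 1 − Φ(mean Φ⁻¹(1 − p_i))` — unweighted, so pooling never
manufactures power a single subject lacked; zero p-values are floored to
`1/(n_surr + 1)` first.  Families (lags, frequencies, phase bins) are
corrected with Benjamini–Hochberg step-up FDR (via statsmodels;
oracle-checked against a brute-force step-up in the tests).

Respiration coupling uses 100-s windows at 50% overlap, per-window
coherence plus a Kullback–Leibler modulation index (normalized entropy of
the 12-bin mean-amplitude-by-respiration-phase distribution), averaged
and compared with window-shuffled surrogates.  Note the surrogates only
destroy phase alignment if respiratory rate drifts across windows, as it
does physiologically; a perfectly periodic respiration trace defeats
window shuffling, which is why the synthetic checks use a
frequency-drifting trace.  Constant respiration has no phase and raises.

## Reliability

Even–odd reliability thins windows to every fifth (consecutive retained
windows are then 100 s apart, so halves share no samples; thinning
anchors at the first window), splits the thinned sequence by parity,
aggregates each half, and compares halves across subjects per frequency
with an intraclass correlation: Pearson's formula with the mean and SD
pooled over both measurements, `Σ(a−m)(b−m) / (n s²)` with grand mean m
and pooled population variance s².  This is algebraically the
two-measurement one-way ANOVA ICC `(MSB − MSW)/(MSB + MSW)` with
population mean squares, and — unlike the ordinary Pearson coefficient —
is depressed by a systematic mean difference between halves.  Split-half
reliability (first vs last 50% of windows) expects exactly such a
difference from overnight drift and therefore uses the ordinary Pearson
coefficient.  Coefficients are reported unsquared, the conservative
convention.

The ordinary signal PSD is a Welch average over clean in-state 4-s
Hamming epochs at 50% overlap (0.25 Hz resolution), 0–48 Hz inclusive
(193 bins), log10-transformed.  Cross-measure correlation maps correlate
every envelope-spectrum bin (0.01–1 Hz) with every signal-spectrum bin
across subjects.  Univariate phenotype correlations are Pearson r with
pairwise deletion of missing phenotypes and BH FDR applied within
channel.

## Phenotype prediction

Features are the 0.01–1.00 Hz envelope spectrum (100 bins × 8 bands =
800 predictors) for one channel and state.  The validation split orders
subjects by the phenotype (stable tie-break on subject id) and holds out
every 8th starting from the first — a maximal-variance hold-out; 176
subjects give 22 validation / 154 training.  Training standardizes
columns with training-set statistics only, then fits an elastic net
(L1–L2 mixture 0.5) along a 100-point log-spaced penalty path from the
data-derived maximum down by 1e-4, choosing the penalty by minimum
fivefold cross-validated squared error (minimum-CV rather than
one-standard-error, favouring accuracy); folds are seeded and stratified
by phenotype quantile.  Binary sex is regressed as a continuous 0/1
variable, making its validation correlation a point-biserial
coefficient.  Fits that raise convergence warnings or produce non-finite
paths are marked non-converged: they report accuracy 0 and are excluded
from cross-channel averages.

## Synthetic data

The generators define the package's test conditions; all are seeded and
bit-reproducible.

* **Two-component test signal**: `Σ_k a_k m_k(t) sin(2π f_k t)` with the
  non-negative modulation law `m(t) = 1 − d + d (1 + sin(2π c t))/2`,
  defaults `(f, c) = (2, 0.2)` and `(12, 1)` Hz at depth 1 and unit
  amplitude, plus 1/f noise of total SD 1 (pink noise by spectral
  shaping of seeded white Gaussian noise, `f^(−exponent/2)` scaling and
  zeroed DC, giving exact slope control).  SD 1 puts the in-band noise
  power within ~1.5 dB of the delta component's power over a 300-s
  record — carriers are recoverable but visibly noisy.  Depth, amplitudes
  and noise level are free parameters; the defaults are declared choices,
  not values inferred from any reference data.
* **Coupled ECoG/MUA pair**: the ECoG is pink noise; the oscillatory
  phase of its band envelope drives a rectified-Gaussian MUA through the
  gain `clip(1 + strength · Re(A(t) e^{iθ}) / SD, 0, ∞)` (A the analytic
  signal of the demeaned envelope, θ the preferred phase), delayed by
  the requested lag.  Strength 0 yields exactly independent signals.
  The lag is recovered by the cross-correlation extremum when θ = 0;
  a nonzero θ rotates where the extremum sits, as it should.
* **Cohort**: log10-scale spectra `−log10(f)` plus per-bin residuals of
  scale `noise_sd` (0.3 log10 units by default).  At a declared effect
  locus the residual is `Σ β_p z_p + sqrt(1 − Σβ²) η`, so the expected
  feature–phenotype correlation equals the declared β exactly;
  `Σβ² > 1` at any bin is rejected as unattainable.  Phenotypes: age
  uniform 17–69 years, sex Bernoulli(0.5) coded 0/1, IQ normal(100, 15).
  Default cohort size 176.

What the generators do *not* emulate: realistic all-night sleep
architecture (stage cycling, arousals), 1/f-deviating spectral shapes,
channel covariance across a montage, cardiac/movement artifacts, or
nonstationarity within a night.  Passing recovery tests therefore shows
the estimators are correct and calibrated under their stated model, not
that real recordings satisfy that model.

## Numerical choices and problem sizes

Intervals are half-open, times in seconds from recording start, sample i
covering `[i/rate, (i+1)/rate)`; this fixes every grid-alignment
ambiguity (a grid-aligned 4-s artifact marks one mask cell, an off-grid
one marks two).  Determinism: same seed ⇒ identical output; the
acceptance script (`scripts/acceptance.py --seed N --out f.json`)
regenerates the carrier-recovery and window-coverage quantities from
scratch in a few seconds.  Test suites run the inferential calibrations
at deliberately modest sizes — 200 surrogates × 200 replicates for the
type-I check, 50 seeded cohorts for the elastic-net null, 600–2000 s of
simulated signal for coupling recovery — sizes at which the relevant
sampling bands are already narrow.  "Peak" readouts are the largest
*local maximum* of a spectrum below a stated bound, so a monotone 1/f
background cannot masquerade as a peak.

## Known limitations

* The pooled-SD ICC assumes exactly two measurements; k > 2 halves are
  out of scope.
* Coherence values from 20-s segments carry the documented small-sample
  bias; only surrogate-relative statements are calibrated.
* The elastic-net "converged" flag inherits scikit-learn's convergence
  diagnostics; a fit that converges to a useless model is still
  "converged" (its validation r speaks for itself).
* EDF reading requires mne and is exercised only for error paths in the
  test suite, since no EDF writer is available to build fixtures; the
  CSV + JSON side-car route is the fully tested interchange format.
* Re-referencing (linked earlobes, contralateral mastoid) is accepted as
  given in input files and never re-derived.
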