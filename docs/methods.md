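# Methods

## Signal model

The simulator implements the standard CW Doppler phase-modulation model of
chest-wall motion.  Displacement is the sum of a respiration harmonic
series and a heartbeat sinusoid,

    x(t) = a_r · Σ_k w_k sin(2π k f_r t + φ_r),   y(t) = a_h sin(2π f_h t + φ_h),

and the received quadrature pair is

    I = A cos Φ + d_I + n_I,   Q = A g sin(Φ + ε) + d_Q + n_Q,
    Φ(t) = 4π d₀/λ + (4π/λ)(x + y) + Δφ(t),

with amplitude `A`, DC offsets `d_I, d_Q`, gain imbalance `g`, quadrature
skew `ε`, white thermal noise `n`, and oscillator phase noise `Δφ`.

Choices worth stating:

- **Propagation speed defaults to 3.0 × 10⁸ m/s**, so λ = 12.5 cm exactly
  and the null spacing is exactly 3.125 cm at 2.4 GHz; it is configurable.
- **Displacement amplitudes default to 4 mm (respiration) and 0.3 mm
  (heartbeat)** — the order of magnitude reported throughout the
  radar-vital-signs literature.  They are configuration, not constants.
- **The respiration waveform defaults to a pure sinusoid.**  The harmonic
  weights exist to reproduce the interference mechanism by which
  respiration harmonics landing inside the heart band capture the HR peak.
- **Phase noise is a Gaussian random walk** (integrated white noise,
  1/f² spectrum) — a deliberate, simple stand-in for close-in VCO/PLL
  noise; no specific oscillator spectrum is modeled.
- **The receiver is modeled directly at baseband.**  A real low-IF
  front end (IF ≈ 1 kHz) exists to escape 1/f noise; after final
  downconversion the vital-signs data path sees exactly the 200 Hz
  baseband I/Q modeled here, so the IF stage adds nothing testable.
- The range phase is taken as the round-trip path phase 4π d₀/λ.

## Demodulation

`arctan_demodulate` computes the four-quadrant arctangent atan2(Q, I) and
unwraps it (2π corrections at jumps larger than π).  Unwrapping is
required because realistic chest excursions exceed ±π/2 of phase; a
plain single-branch arctangent would be discontinuous.

Known DC offsets are subtracted exactly when supplied.  Estimating the
offsets as per-channel time averages is available but **off by default**:
for a modulated record the channel mean contains a signal-dependent term
(the centroid of an arc, not the circle centre), so mean subtraction
*biases* an offset-free record — with it enabled the noiseless
reconstruction error would be far above numerical precision.  Circle
fitting, the principled offset estimator, is out of scope.

`remove_dc_streaming` reproduces the deployed system's bookkeeping: blocks
of `sample_rate/refresh_rate` samples (8 at defaults) are appended to a
growing buffer; each block is emitted minus the buffer mean, so the DC
estimate refreshes every 0.04 s.  The growing buffer matches the
description of the stored dataset; an optional sliding window bounds the
memory and tracks drift faster.  The growing mean converges like
ln(T)/(ωT) for a tone at angular frequency ω, which sets how long a
record must be before the emitted tail is mean-free to a given tolerance.

`single_channel_phase` is the small-signal linear demodulator used only to
*demonstrate* null points: around the operating point,
I ≈ A cos θ − A sin θ · δ, so the mean-removed I channel scaled by
−1/(A sin θ) approximates the phase.  The conversion factor A·|sin θ|
is reported as `sensitivity`; below 10⁻⁶ the record is flagged
`degenerate` (output zeroed) rather than dividing by ≈ 0.

## Rate estimation

`spectral_rate` band-passes (zero-phase Butterworth, order 4 forward and
backward — the zero-phase pass squares the magnitude response), removes
the mean, and evaluates the power spectrum as the DFT of the zero-padded
two-sided *biased* autocorrelation.  The biased estimator guarantees a
positive-semidefinite spectrum; by Wiener–Khinchin the whole construction
equals |DFT(x, nfft)|²/n for nfft ≥ 2n−1, and that single-FFT form is
what runs (the equivalence is asserted against the explicit
autocorrelation path in the tests).  Zero-padding is ≥ 8× the window, so
a 30 s window's 2 BPM raw bin becomes a 0.25 BPM grid; three-point
log-parabolic interpolation around the peak then delivers < 0.2 BPM error
on pure tones.  Without sub-bin interpolation a 30 s window could never
meet a 0.5 BPM respiration accuracy target.

Numerical/detection choices:

- **Bands**: respiration 0.05–0.5 Hz, heart 0.8–2.0 Hz (high edge
  configurable up to 2.5 Hz), within the overall 0.05–2 Hz system range.
  The heart low edge of 0.8 Hz (48 BPM) excludes respiration fundamentals.
- **Prominence floor**: a peak is accepted only if it exceeds 50× the
  in-band median power.  Calibrated against the generator: band-limited
  white noise reaches chance peak/median ratios of ≈ 40 in the narrow
  respiration band (the periodogram of noise is exponentially
  distributed per bin), while genuine vital tones at realistic SNR sit at
  ratios of 70 to several thousand.  The estimator deliberately prefers
  reporting *no rate* (NaN at that tick) over hallucinating one at
  borderline SNR (per-bin SNR below roughly 35).
- **Minimum duration**: 1.5 cycles of the band's low edge — exactly the
  default 30 s window at the 0.05 Hz respiration edge, which is a
  DC-rejection corner rather than a plausible breathing rate.
- **Ties** in the peak search break toward the lower frequency; the
  interpolated frequency is clipped to the band.
- **Streaming**: the record is band-passed once per band (the filter is
  LTI, so filtering before windowing is equivalent up to edge
  transients); each refresh tick re-analyses the trailing window.  Ticks
  before one full window are NaN (warm-up).
- `harmonic_mask` (optional, off by default) zeroes bins within
  ±0.03 Hz of respiration-harmonic frequencies inside the heart band
  before peak finding — the rescue path for harmonic interference.

## Signal quality

Swings are measured as the 99th-minus-1st percentile per channel (robust
to isolated spikes, unlike min/max), combined as sqrt((I² + Q²)/2).  The
printed form of the combined-magnitude formula is ambiguous between this
RMS reading and sqrt(I² + Q²)/2 — they differ by √2 — but either leaves
the posture conclusion (5–10× amplitude ratio ⇒ 14–20 dB SNR difference,
20·log₁₀) unchanged; RMS is adopted.  The Good/Bad label applies a strict
`> 3 mV` rule to the combined swing.

## Trial evaluation

`generate_cohort` samples covariates uniformly (weight 123–285.8 lb,
height 57–73 in, age 29–79 yr), genders 8 male / 12 female at n = 20
(alternating otherwise), true RR uniform 12–25 BPM and HR 55–120 BPM,
with per-subject seeds derived from the cohort seed.  By construction no
covariate influences accuracy (errors depend on noise only); a
`covariate_effect` hook scales thermal noise with normalised weight for
power studies.  `run_trial` composes the full pipeline and reports the
median of the post-warm-up streaming estimates; the reference is the
generator's ground truth, standing in for a nurse-measured HR and a
manually counted RR (`manual_count_rr` emulates the latter's whole-breath
quantisation).  A Bad-posture subject's received amplitude is divided by
5, with noise unchanged.

`error_stats` reports signed-error medians, sample standard deviations
(n−1 denominator), and five-number boxplot summaries, grouped by gender,
posture, or binned/median-split numeric covariates; absolute-error
medians are carried alongside because accuracy claims are quoted on
absolute errors while boxplots use signed errors.  `drop_outliers`
formalises discarding the single worst |HR error|.  Note that removing
that point does not *mathematically* guarantee a smaller remaining
standard deviation (counterexample: errors 10, 10, 10, 10, −1), though it
does in the clinically motivated one-gross-outlier situation.

## Problem sizes and the accuracy experiment

The lab-conditions experiment uses 30 subjects, 120 s records and a 30 s
window — about 2250 refresh ticks × 2 bands × one 48 000-point FFT per
trial, a bit under 3 s per trial.  `scripts/acceptance.py` reruns it from
a single seed and reports the median absolute RR/HR errors; under these
conditions they land near 0.01 BPM, far inside the ~0.5 / ~3 BPM lab
accuracy envelope.

## What the generator does and does not emulate

It reproduces the measurement *physics* (phase modulation, nulls,
offsets, imbalance, oscillator and thermal noise) and the processing
chain's bookkeeping, so passing tests validate the algorithms and their
implementation.  It does not model body-type-dependent reflectivity,
multipath/wall reflections, body-motion artifacts, antenna patterns, or
non-simultaneous reference measurements — the factors that dominate error
in a real clinic.  Simulated accuracies are therefore upper bounds:
clinical HR errors in particular are expected to be an order of magnitude
larger than the synthetic ones, for reasons entirely outside this model.

## Known limitations

- The arctangent path assumes offsets are known or negligible; no
  circle-fitting calibration is provided.
- The prominence floor is a single global constant; adaptive noise-floor
  tracking would serve low-SNR records better.
- The single-channel demodulator is first-order; its 5 % small-signal
  tolerance degrades for excursions approaching a radian.
- Respiration and heart rates are assumed quasi-stationary within the
  analysis window; rate transients smear the autocorrelation spectrum.
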