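# Methods

## The problem and the model

A zero-mean periodic signal with period 1/f₀ that is not a pure sinusoid
has Fourier energy at integer multiples of f₀, phase-locked to the base
component. In resting EEG, strong nonsinusoidal alpha rhythms (8–13 Hz)
therefore produce beta-band peaks (at ~2×f₀ ≈ 16–26 Hz) that are not
independent oscillations. The package implements three complementary
screens for this confound, all operating on power spectra of short
segments of a single channel or spatial component:

1. **Percentile spectrum.** Segments (contiguous, non-overlapping, default
   3 s) are ranked by mean power density in a sorting band (beta,
   16–30 Hz) and split into `n_groups` contiguous rank blocks (extra
   segments go to the lowest blocks, so group sizes differ by at most
   one). The per-group arithmetic mean spectrum visualizes how the rest of
   the spectrum co-varies with beta power.
2. **1/f-corrected dependence.** Each group-mean spectrum gets its own
   aperiodic fit; the corrected alpha and beta band powers are Spearman
   rank-correlated across groups. For a harmonic, alpha and beta power
   share one amplitude envelope, so ρ → +1; an alpha rhythm competing with
   a genuine beta rhythm gives ρ → −1; unrelated rhythms give ρ ≈ 0 (with
   sampling noise of sd ≈ 1/√(n_groups−1) under the null — about 0.23 at
   20 groups, which is why the regime thresholds sit at ±0.5).
3. **Peak-ratio verdict.** From the mean spectrum of the top-fraction
   (default 20 %) alpha-power segments: fit the aperiodic background, gate
   on alpha SNR (> 5 dB), find the alpha and beta peak frequencies as the
   strongest corrected local maxima in each band, and call the beta peak
   harmonic iff |f_β − 2 f_α| ≤ tol_bins × bin width (default one bin).

## Spectral estimation

Per-segment spectra are Hann-windowed, mean-removed periodograms with
density normalization (scipy.signal.periodogram), so the integral over
frequency approximates the segment variance and the bin width is
1/seg_len. The aperiodic component is fit by ordinary least squares of
log₁₀ power on log₁₀ frequency over 1–45 Hz, excluding the alpha and beta
bands widened by 2 bins (all configurable); zero-power bins are floored at
10⁻³⁰ before the log. The fit is exact on noiseless power-law input and
recovers the exponent of simulated 1/f noise to well within ±0.1 when ≥ 50
segment spectra are averaged.

Two 1/f-correction conventions coexist and serve different purposes:

* `corrected_power` / `snr_db` work in the **log domain** (dB relative to
  the fit). The SNR gate and all dB quantities reported in verdicts use
  this convention; it is scale-free and matches how peak visibility is
  judged.
* The **dependence statistic defaults to the linear domain**: corrected
  band power = mean over band bins of (power − fit prediction). A harmonic
  is spectrally narrow (~3 bins of a 43-bin beta band); averaging dB
  ratios lets the ~40 background bins and the per-group fit jitter drown
  the peak (measured on simulated data, the corrected power of the sorting
  band itself then tracks group rank at only ρ ≈ 0.75, versus ≈ 0.99 in
  the linear domain). Linear subtraction keeps the peak's full weight, and
  Spearman's rank invariance preserves the scale-freedom of the result.
  The domain is an explicit argument (`correction="linear"|"log"`).

Band intervals are closed on both ends, with a bin-relative tolerance of
10⁻⁶ so that grid positions like 48 × (1/3 Hz) count as 16 Hz. Peak
detection requires a strict local maximum against both grid neighbours
(band-edge argmax artifacts never qualify); exact ties resolve to the
lower frequency.

## The synthetic generator

The generator is phenomenological: it reproduces the spectral and
envelope structure the screens key on, not the biophysics.

* **Rhythms** are a unit base sinusoid plus phase-locked harmonics
  (harmonic k: rel_amplitude × sin(kθ + phase_lag), θ the base phase), or,
  for genuine rhythms without a fixed waveform, a stochastic carrier
  band-limited to base_freq ± bandwidth/2 and RMS-matched to a
  unit-amplitude sinusoid. Genuine beta thus shows the broad peak typical
  of real beta rhythms, against the narrow peaks of harmonics.
* **Envelopes** are |0.3 Hz-low-passed Gaussian noise| normalized to mean
  1 (correlation time a few seconds, matching waxing/waning of resting
  rhythms). The low-pass is applied with 4-time-constant warm-up padding
  trimmed from both ends; without it the zero-phase filter's edge
  transient dominates the envelope's dynamic range.
* **Background noise** is 1/f: white Gaussian noise shaped in the
  frequency domain to a one-sided density scale × (f/1 Hz)^(−exponent),
  held flat below 1 Hz, DC removed — exact expected slope, fully seeded.
* **Regimes.** `harmonic`: one nonsinusoidal alpha rhythm, beta content
  solely its second harmonic. `independent`: sinusoidal alpha plus a
  genuine beta rhythm with an independently seeded envelope.
  `anticorrelated`: the beta envelope is the countermonotone copy of the
  alpha envelope — its values reverse-rank-matched onto the same marginal
  distribution, giving rank correlation exactly −1 *and* the same
  modulation depth. (The simpler `max(env) − env` construction was
  measured to transmit only ~⅓ of the relative modulation, because the
  envelope maximum is an extreme-value outlier; it anticorrelates the
  sources in name but barely in band power.)

Default study conditions (all overridable in `make_scenario`): 5 min at
250 Hz; alpha 10 Hz, amplitude 10 µV, harmonic (2, 0.5, 0); genuine beta
amplitude 5 µV, bandwidth 4 Hz, centre frequency drawn uniformly from
16–30 Hz per seed; noise exponent 1.5, scale 100 µV²/Hz at 1 Hz. These
give an alpha SNR of ~20 dB in high-alpha segments and realistic
beta-band signal-to-background ratios near 1. A genuine beta whose drawn
centre lands within a bin of 20 Hz is misclassified as harmonic — that is
a property of the peak-ratio rule itself, and it bounds the method's
specificity at roughly 95 % under these conditions.

What the generator does **not** emulate: multiple simultaneous rhythms per
channel, nonstationary 1/f slopes, artifacts (eye blinks, muscle), alpha
frequency drift, or task-related burst structure. Tests passing on this
substrate therefore validate the machinery and its statistical behaviour
under the stated regimes, not performance on arbitrary real EEG.

## SSD

Spatio-spectral decomposition solves S w = λ N w with S the covariance of
the signal-band-filtered data (8–13 Hz) and N the summed covariance of two
flank-filtered copies (6–7 and 14–15 Hz), all filters zero-phase
Butterworth order 4. N is shrunk toward a trace-scaled identity
(coefficient 10⁻⁶) for stability; rank-deficient input is projected onto
its principal subspace first (with a warning) and filters mapped back.
Components are ordered by eigenvalue, but the component used downstream is
selected by explicit alpha-band SNR of its spectrum, which is robust to
eigenvalue ordering quirks. Activation patterns are S·W (defined up to
column scaling).

## Pipeline and reproducibility

`run_recording` composes segmentation → percentile spectrum → dependence →
verdict under one `AnalysisConfig` (YAML-serializable; every parameter
echoed into `run_record.json`). Identical input and config produce
byte-identical CSV/JSON outputs; wall-clock timestamps go to `run.log`
only. `seglen_sweep` repeats the analysis over segment lengths (default
0.5–4 s) to confirm conclusions are not a segmentation artifact — note
that at 0.5 s the bins are 2 Hz wide, so the one-bin harmonic tolerance is
coarse there. Multichannel recordings default to channel C3 (the standard
left-central site for sensorimotor analyses); any label is selectable.
Export formats are FIF and a raw float64 binary + JSON sidecar (exact
round-trip); readers additionally accept BrainVision and EDF.

## Problem sizes and tolerances used in validation

The test suite and `scripts/acceptance.py` run entirely on synthetic
data: 50 seeds per regime of 5-minute single-channel recordings for regime
and verdict recovery, 100 averaged segments for aperiodic-exponent
recovery (±0.1), 500 random tied/untied pairs for the Spearman check
against a brute-force rank-then-Pearson reference (10⁻¹² agreement),
8-channel/4-source mixtures over 60 s for SSD recovery (|r| > 0.95), and
10 seeds × 4 segment lengths for the robustness sweep. These sizes keep a
full validation run under a minute on one CPU while leaving the binomial
noise of the reported percentages at a few points.

## Known limitations

* The dependence screen sees only monotone group-level coupling; mixtures
  (genuine beta bursts overlapping harmonics) and concurrent 1/f changes
  can produce intermediate ρ that fits no regime cleanly.
* The peak-ratio rule cannot, even in principle, separate a genuine beta
  oscillator that happens to sit at exactly twice the alpha frequency;
  phase-based measures (bicoherence, cross-frequency lagged coherence)
  are the appropriate follow-up and are out of scope here.
* The aperiodic model is a single power law without a knee; fits over
  ranges with a spectral knee will bias the exponent.
* EDF export is not provided (only reading); FIF and the binary sidecar
  format cover export.
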