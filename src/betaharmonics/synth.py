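"""Synthetic EEG generator with controlled waveform shape and band coupling.

Signals are built from three phenomenological ingredients:

* narrowband rhythms — a base sinusoid plus optional phase-locked harmonics
  at integer multiples of the base frequency (the spectral signature of a
  nonsinusoidal waveform), or a stochastic broadband carrier for genuine
  rhythms without a fixed waveform;
* 1/f (pink) background noise synthesized by frequency-domain shaping of
  white Gaussian noise, giving an exact expected power-law spectrum;
* slow amplitude envelopes (low-pass-filtered rectified Gaussian noise)
  that induce the segment-to-segment band-power fluctuations the percentile
  spectrum analysis feeds on.

Three scenario regimes tie these together: a nonsinusoidal alpha rhythm
whose second harmonic lands in the beta band (``harmonic``), and a
sinusoidal alpha plus an independent genuine beta rhythm whose envelopes
are either unrelated (``independent``) or mirror images of each other
(``anticorrelated``).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .timeseries import TimeSeries

__all__ = [
    "Harmonic",
    "EnvelopeSpec",
    "RhythmSpec",
    "NoiseSpec",
    "ScenarioSpec",
    "REGIMES",
    "gen_pink_noise",
    "gen_rhythm",
    "gen_scenario",
    "make_scenario",
    "mix_forward",
    "segment_envelope_power",
]

REGIMES = ("anticorrelated", "independent", "harmonic")

# Study-condition defaults (resting EEG scale, see docs/methods.md).
DEFAULT_RATE = 250.0  # Hz
DEFAULT_DURATION = 300.0  # s
ALPHA_FREQ = 10.0  # Hz
ALPHA_AMPLITUDE = 10.0  # µV
HARMONIC_REL_AMPLITUDE = 0.5
HARMONIC_PHASE_LAG = 0.0  # rad
BETA_AMPLITUDE = 5.0  # µV
BETA_BANDWIDTH = 4.0  # Hz — broad peak of a genuine beta rhythm
BETA_FREQ_RANGE = (16.0, 30.0)  # Hz, genuine-beta centre frequency draw
NOISE_SCALE = 100.0  # µV²/Hz at 1 Hz
NOISE_EXPONENT = 1.5
ENVELOPE_CUTOFF = 0.3  # Hz


@dataclass(frozen=True)
class Harmonic:
    """One phase-locked harmonic of a base rhythm.

    ``phase_lag`` is the constant offset of the harmonic's phase relative to
    ``multiple`` times the base phase, so phi(k*f0) - k*phi(f0) == phase_lag
    at every sample by construction.
    """

    multiple: int
    rel_amplitude: float
    phase_lag: float = 0.0

    def __post_init__(self) -> None:
        if int(self.multiple) != self.multiple or self.multiple < 2:
            raise ValueError(f"harmonic multiple must be an integer >= 2, got {self.multiple}")
        if self.rel_amplitude < 0:
            raise ValueError("rel_amplitude must be >= 0")


@dataclass(frozen=True)
class EnvelopeSpec:
    """Amplitude envelope descriptor.

    ``constant`` keeps amplitude fixed; ``random`` draws Gaussian noise,
    low-passes it at ``cutoff_hz``, rectifies and normalizes to mean 1,
    yielding a slow waxing-and-waning envelope with correlation time of a
    few seconds at the default 0.3 Hz cutoff.
    """

    kind: str = "constant"
    cutoff_hz: float = ENVELOPE_CUTOFF

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "random"):
            raise ValueError(f"unknown envelope kind {self.kind!r}")
        if self.cutoff_hz <= 0:
            raise ValueError("envelope cutoff must be positive")


@dataclass(frozen=True)
class RhythmSpec:
    """One rhythm: base sinusoid (+ harmonics) or a broadband carrier.

    Parameters
    ----------
    base_freq
        Base (centre) frequency in Hz.
    amplitude
        Peak amplitude in µV of the base component (RMS-matched for a
        broadband carrier).
    harmonics
        Phase-locked harmonics; all multiples distinct. Empty tuple means
        the rhythm is sinusoidal.
    envelope
        Common amplitude envelope applied to base and harmonics alike.
    bandwidth
        0 for a deterministic sinusoidal carrier; > 0 for a stochastic
        carrier band-limited to base_freq ± bandwidth/2 (genuine rhythms
        show such broad peaks). Harmonics require bandwidth == 0.
    phase
        Initial phase in radians; None draws it uniformly from the seed.
    """

    base_freq: float
    amplitude: float = 1.0
    harmonics: tuple[Harmonic, ...] = ()
    envelope: EnvelopeSpec = field(default_factory=EnvelopeSpec)
    bandwidth: float = 0.0
    phase: Optional[float] = None

    def __post_init__(self) -> None:
        if self.base_freq <= 0:
            raise ValueError("base_freq must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        object.__setattr__(self, "harmonics", tuple(self.harmonics))
        multiples = [h.multiple for h in self.harmonics]
        if len(set(multiples)) != len(multiples):
            raise ValueError("harmonic multiples must be distinct")
        if self.bandwidth < 0:
            raise ValueError("bandwidth must be >= 0")
        if self.bandwidth > 0 and self.harmonics:
            raise ValueError("harmonics are only defined for a sinusoidal carrier (bandwidth == 0)")

    @property
    def is_sinusoidal(self) -> bool:
        return all(h.rel_amplitude == 0 for h in self.harmonics)


@dataclass(frozen=True)
class NoiseSpec:
    """1/f background noise: one-sided PSD = scale * (f / f_ref)**(-exponent).

    Below ``f_min`` the shaping is flattened (held at the f_min value) to
    keep the variance finite; f_ref and f_min default to 1 Hz.
    """

    exponent: float = NOISE_EXPONENT
    scale: float = NOISE_SCALE
    seed: int = 0
    f_ref: float = 1.0
    f_min: float = 1.0

    def __post_init__(self) -> None:
        if self.exponent < 0:
            raise ValueError("exponent must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.f_ref <= 0 or self.f_min <= 0:
            raise ValueError("f_ref and f_min must be positive")


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative description of one simulated regime with ground truth.

    Invariants: ``harmonic`` means beta content comes solely from the
    phase-locked harmonics of ``alpha_rhythm`` (``beta_rhythm`` absent);
    ``anticorrelated`` / ``independent`` require a genuine ``beta_rhythm``
    and a harmonic-free alpha.
    """

    regime: str
    alpha_rhythm: RhythmSpec
    beta_rhythm: Optional[RhythmSpec] = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    duration: float = DEFAULT_DURATION
    rate: float = DEFAULT_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if self.duration <= 0 or self.rate <= 0:
            raise ValueError("duration and rate must be positive")
        if self.regime == "harmonic":
            if self.beta_rhythm is not None:
                raise ValueError("harmonic regime must not carry an independent beta rhythm")
            if not any(h.rel_amplitude > 0 for h in self.alpha_rhythm.harmonics):
                raise ValueError("harmonic regime requires alpha harmonics with nonzero amplitude")
        else:
            if self.beta_rhythm is None:
                raise ValueError(f"{self.regime} regime requires a genuine beta rhythm")
            if self.alpha_rhythm.harmonics:
                raise ValueError(f"{self.regime} regime requires a harmonic-free alpha rhythm")
        amps = [self.alpha_rhythm.amplitude]
        if self.beta_rhythm is not None:
            amps.append(self.beta_rhythm.amplitude)
        if all(a == 0 for a in amps):
            raise ValueError("degenerate scenario: no rhythm has nonzero amplitude")


def _envelope_samples(env: EnvelopeSpec, n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    if env.kind == "constant":
        return np.ones(n)
    # warm-up padding of several filter time constants on both sides keeps
    # the zero-phase filter's edge transients out of the returned envelope
    pad = int(np.ceil(4.0 / env.cutoff_hz * rate))
    x = rng.standard_normal(n + 2 * pad)
    sos = butter(2, env.cutoff_hz, btype="low", fs=rate, output="sos")
    e = np.abs(sosfiltfilt(sos, x))[pad : pad + n]
    m = e.mean()
    if m <= 0:
        raise ValueError("degenerate envelope (zero mean)")
    return e / m


def _carrier(spec: RhythmSpec, n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-amplitude carrier: sinusoid (+ harmonics) or band-limited noise."""
    t = np.arange(n) / rate
    phase0 = rng.uniform(0.0, 2.0 * np.pi) if spec.phase is None else spec.phase
    if spec.bandwidth == 0:
        theta = 2.0 * np.pi * spec.base_freq * t + phase0
        x = np.sin(theta)
        for h in spec.harmonics:
            x = x + h.rel_amplitude * np.sin(h.multiple * theta + h.phase_lag)
        return x
    lo = spec.base_freq - spec.bandwidth / 2.0
    hi = spec.base_freq + spec.bandwidth / 2.0
    if lo <= 0 or hi >= rate / 2.0:
        raise ValueError("carrier band must lie strictly inside (0, Nyquist)")
    sos = butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    rms = x.std()
    if rms == 0:
        raise ValueError("degenerate broadband carrier")
    # RMS-match a unit-amplitude sinusoid so `amplitude` means the same thing
    return x * (1.0 / np.sqrt(2.0)) / rms


def _rhythm_samples(
    spec: RhythmSpec,
    n: int,
    rate: float,
    rng: np.random.Generator,
    envelope: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    if envelope is None:
        envelope = _envelope_samples(spec.envelope, n, rate, rng)
    x = spec.amplitude * envelope * _carrier(spec, n, rate, rng)
    return x, envelope


def gen_rhythm(
    spec: RhythmSpec,
    duration: float,
    rate: float,
    seed: int = 0,
    envelope_samples: Optional[np.ndarray] = None,
) -> TimeSeries:
    """Generate one rhythm as a single-channel time series.

    The output is ``amplitude * envelope(t) * carrier(t)`` where the carrier
    is the base sinusoid plus its phase-locked harmonics (or a band-limited
    stochastic carrier for bandwidth > 0). Deterministic for a given seed.
    ``envelope_samples`` overrides the envelope with a precomputed array
    (used by :func:`gen_scenario` to couple rhythms).
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    if duration < 1.0 / spec.base_freq:
        raise ValueError("duration shorter than one base period")
    n = int(round(duration * rate))
    rng = np.random.default_rng(seed)
    if envelope_samples is not None:
        envelope_samples = np.asarray(envelope_samples, dtype=float)
        if envelope_samples.shape != (n,):
            raise ValueError("envelope_samples length must match duration * rate")
    x, _ = _rhythm_samples(spec, n, rate, rng, envelope_samples)
    meta = {"kind": "rhythm", "spec": dataclasses.asdict(spec), "seed": seed}
    return TimeSeries(x, rate, ["SIM"], meta)


def gen_pink_noise(n_samples: int, rate: float, noise: NoiseSpec) -> TimeSeries:
    """1/f noise by frequency-domain shaping of white Gaussian noise.

    The expected one-sided PSD is ``scale * (f / f_ref)**(-exponent)`` for
    f >= f_min; below f_min the density is held flat at the f_min value and
    the DC component is zeroed. Deterministic for a given NoiseSpec.seed.
    """
    if n_samples < 2:
        raise ValueError(f"n_samples must be >= 2, got {n_samples}")
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(noise.seed)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / rate)
    f_eff = np.maximum(freqs, noise.f_min)
    gain = (f_eff / noise.f_ref) ** (-noise.exponent / 2.0)
    gain[0] = 0.0  # mean-free
    # unit-variance white noise has one-sided PSD 2/rate
    gain *= np.sqrt(noise.scale * rate / 2.0)
    x = np.fft.irfft(spec * gain, n=n_samples)
    meta = {"kind": "pink_noise", "spec": dataclasses.asdict(noise)}
    return TimeSeries(x, rate, ["SIM"], meta)


def make_scenario(
    regime: str,
    seed: int = 0,
    duration: float = DEFAULT_DURATION,
    rate: float = DEFAULT_RATE,
    alpha_freq: float = ALPHA_FREQ,
    alpha_amplitude: float = ALPHA_AMPLITUDE,
    harmonic_rel_amplitude: float = HARMONIC_REL_AMPLITUDE,
    harmonic_phase_lag: float = HARMONIC_PHASE_LAG,
    beta_amplitude: float = BETA_AMPLITUDE,
    beta_bandwidth: float = BETA_BANDWIDTH,
    beta_freq: Optional[float] = None,
    noise_scale: float = NOISE_SCALE,
    noise_exponent: float = NOISE_EXPONENT,
) -> ScenarioSpec:
    """Build a ScenarioSpec under the study's default conditions.

    For non-harmonic regimes the genuine-beta centre frequency is drawn
    uniformly from 16-30 Hz using ``seed`` unless ``beta_freq`` is given;
    the draw is materialized into the returned spec, so identical specs
    always regenerate identical data.
    """
    rng = np.random.default_rng(seed)
    noise_seed = int(rng.integers(2**31))
    noise = NoiseSpec(exponent=noise_exponent, scale=noise_scale, seed=noise_seed)
    if regime == "harmonic":
        alpha = RhythmSpec(
            base_freq=alpha_freq,
            amplitude=alpha_amplitude,
            harmonics=(Harmonic(2, harmonic_rel_amplitude, harmonic_phase_lag),),
            envelope=EnvelopeSpec("random"),
        )
        return ScenarioSpec(regime, alpha, None, noise, duration, rate, seed)
    alpha = RhythmSpec(
        base_freq=alpha_freq,
        amplitude=alpha_amplitude,
        envelope=EnvelopeSpec("random"),
    )
    if beta_freq is None:
        beta_freq = float(rng.uniform(*BETA_FREQ_RANGE))
    beta = RhythmSpec(
        base_freq=beta_freq,
        amplitude=beta_amplitude,
        bandwidth=beta_bandwidth,
        envelope=EnvelopeSpec("random"),
    )
    return ScenarioSpec(regime, alpha, beta, noise, duration, rate, seed)


def gen_scenario(spec: ScenarioSpec) -> tuple[TimeSeries, dict]:
    """Generate a scenario recording and its ground truth.

    Returns the single-channel time series (alpha + beta + pink noise) and a
    ground-truth dict with the regime label, the source amplitude envelopes,
    and the genuine-beta centre frequency (if any). For the anticorrelated
    regime the beta envelope is the countermonotone (reverse-rank-matched)
    copy of the alpha envelope: same marginal distribution, rank
    correlation exactly -1.
    """
    n = int(round(spec.duration * spec.rate))
    master = np.random.default_rng(spec.seed)
    rng_alpha = np.random.default_rng(int(master.integers(2**31)))
    rng_beta = np.random.default_rng(int(master.integers(2**31)))

    env_a = _envelope_samples(spec.alpha_rhythm.envelope, n, spec.rate, rng_alpha)
    alpha, _ = _rhythm_samples(spec.alpha_rhythm, n, spec.rate, rng_alpha, env_a)

    beta_freq = None
    if spec.regime == "harmonic":
        beta = np.zeros(n)
        env_b = env_a
    else:
        assert spec.beta_rhythm is not None
        beta_freq = spec.beta_rhythm.base_freq
        if spec.regime == "anticorrelated":
            # countermonotone copy of the alpha envelope: reverse-rank-match
            # onto its own marginal, so beta waxes exactly when alpha wanes
            # with the same modulation depth (rank correlation exactly -1)
            order = np.argsort(env_a, kind="stable")
            env_b = np.empty_like(env_a)
            env_b[order] = np.sort(env_a)[::-1]
        else:  # independent
            env_b = _envelope_samples(spec.beta_rhythm.envelope, n, spec.rate, rng_beta)
        beta, _ = _rhythm_samples(spec.beta_rhythm, n, spec.rate, rng_beta, env_b)

    noise_ts = gen_pink_noise(n, spec.rate, spec.noise)
    samples = alpha + beta + noise_ts.samples[0]
    meta = {
        "kind": "scenario",
        "regime": spec.regime,
        "seed": spec.seed,
        "spec": dataclasses.asdict(spec),
    }
    ts = TimeSeries(samples, spec.rate, ["C3"], meta)
    truth = {
        "regime": spec.regime,
        "alpha_envelope": env_a,
        "beta_envelope": env_b,
        "beta_base_freq": beta_freq,
        "alpha_base_freq": spec.alpha_rhythm.base_freq,
        "seed": spec.seed,
    }
    return ts, truth


def segment_envelope_power(envelope: np.ndarray, rate: float, seg_len: float) -> np.ndarray:
    """Per-segment mean squared envelope — the band-power target implied by
    an amplitude envelope under the same segmentation as the analysis."""
    n_per = int(round(seg_len * rate))
    n_seg = len(envelope) // n_per
    if n_seg == 0:
        raise ValueError("envelope shorter than one segment")
    e = envelope[: n_seg * n_per].reshape(n_seg, n_per)
    return (e**2).mean(axis=1)


def mix_forward(
    sources: TimeSeries,
    mixing: np.ndarray,
    sensor_noise_std: float = 0.0,
    seed: int = 0,
    channel_labels: Optional[list[str]] = None,
) -> TimeSeries:
    """Project source time series through a forward mixing matrix.

    ``mixing`` has shape (n_channels, n_sources); optional white sensor
    noise of the given standard deviation (µV) is added per channel.
    """
    mixing = np.asarray(mixing, dtype=float)
    if mixing.ndim != 2:
        raise ValueError("mixing must be a 2-D matrix")
    if mixing.shape[1] != sources.n_channels:
        raise ValueError(
            f"mixing has {mixing.shape[1]} columns but there are "
            f"{sources.n_channels} sources"
        )
    out = mixing @ sources.samples
    if sensor_noise_std > 0:
        rng = np.random.default_rng(seed)
        out = out + sensor_noise_std * rng.standard_normal(out.shape)
    if channel_labels is None:
        channel_labels = [f"CH{i + 1}" for i in range(mixing.shape[0])]
    meta = {"kind": "mixed", "n_sources": sources.n_channels, "seed": seed}
    return TimeSeries(out, sources.rate, channel_labels, meta)
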