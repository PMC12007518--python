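"""Segmentation, per-segment power spectra, band power and 1/f correction.

Spectra are Hann-windowed, mean-removed periodograms with density
normalization (µV²/Hz), so the integral over frequency approximates the
segment variance. The aperiodic (1/f) component is fit by ordinary least
squares of log10(power) on log10(frequency) over a configurable range with
the oscillatory bands excluded; "corrected" power is the dB ratio of the
spectrum to the fitted aperiodic level, and band SNR is the maximum of that
ratio over the band.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import periodogram

from .timeseries import TimeSeries

__all__ = [
    "BandDefinition",
    "ALPHA_BAND",
    "BETA_BAND",
    "SegmentSet",
    "Spectrum",
    "AperiodicFit",
    "FitConfig",
    "segment",
    "segment_spectrum",
    "spectra",
    "mean_spectrum",
    "band_mask",
    "band_power",
    "fit_aperiodic",
    "fit_aperiodic_excluding",
    "corrected_spectrum_db",
    "corrected_power",
    "snr_db",
]


@dataclass(frozen=True)
class BandDefinition:
    """Closed frequency interval [f_lo, f_hi] in Hz with a name."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"require 0 < f_lo < f_hi, got [{self.f_lo}, {self.f_hi}]")

    def expand(self, margin_hz: float) -> "BandDefinition":
        return BandDefinition(self.name, max(self.f_lo - margin_hz, 1e-12), self.f_hi + margin_hz)


ALPHA_BAND = BandDefinition("alpha", 8.0, 13.0)
BETA_BAND = BandDefinition("beta", 16.0, 30.0)


@dataclass
class SegmentSet:
    """Contiguous, non-overlapping fixed-length segments of one channel."""

    segments: np.ndarray  # (n_segments, n_samples) µV
    rate: float
    seg_len: float
    source_label: str = ""

    def __post_init__(self) -> None:
        self.segments = np.atleast_2d(np.asarray(self.segments, dtype=float))
        n_per = int(round(self.seg_len * self.rate))
        if self.segments.shape[1] != n_per:
            raise ValueError(
                f"segments have {self.segments.shape[1]} samples, expected "
                f"round(seg_len * rate) = {n_per}"
            )

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def resolution(self) -> float:
        """Frequency resolution of per-segment spectra, Hz."""
        return self.rate / self.segments.shape[1]


@dataclass
class Spectrum:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray  # Hz, ascending
    power: np.ndarray  # µV²/Hz

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape or self.freqs.ndim != 1:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly ascending")
        if not np.all(np.isfinite(self.power)) or np.any(self.power < 0):
            raise ValueError("power must be finite and non-negative")

    @property
    def resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def segment(ts: TimeSeries, seg_len: float) -> SegmentSet:
    """Cut a single-channel recording into floor(duration/seg_len) contiguous
    non-overlapping segments; the trailing remainder is discarded."""
    if ts.n_channels != 1:
        raise ValueError("segment() expects a single-channel TimeSeries; use .pick(label)")
    if seg_len <= 0:
        raise ValueError("seg_len must be positive")
    if ts.duration < seg_len:
        raise ValueError(
            f"recording ({ts.duration:.3g} s) shorter than one segment ({seg_len:g} s)"
        )
    n_per = int(round(seg_len * ts.rate))
    n_seg = ts.n_samples // n_per
    segs = ts.samples[0, : n_seg * n_per].reshape(n_seg, n_per)
    return SegmentSet(segs, ts.rate, seg_len, source_label=ts.channel_labels[0])


def segment_spectrum(seg: np.ndarray, rate: float) -> Spectrum:
    """Hann-windowed, mean-removed periodogram of one segment (density)."""
    seg = np.asarray(seg, dtype=float)
    if seg.ndim != 1 or seg.size < 2:
        raise ValueError("segment must be a 1-D array with >= 2 samples")
    freqs, pxx = periodogram(
        seg, fs=rate, window="hann", detrend="constant", scaling="density"
    )
    return Spectrum(freqs, pxx)


def spectra(segset: SegmentSet) -> tuple[np.ndarray, np.ndarray]:
    """All per-segment periodograms at once: (freqs, power[n_segments, n_freqs])."""
    freqs, pxx = periodogram(
        segset.segments,
        fs=segset.rate,
        window="hann",
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return freqs, pxx


def mean_spectrum(segset: SegmentSet) -> Spectrum:
    """Arithmetic mean of the per-segment power spectra."""
    freqs, pxx = spectra(segset)
    return Spectrum(freqs, pxx.mean(axis=0))


def band_mask(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Boolean mask of bins with f_lo <= f <= f_hi (closed on both ends).

    A small grid-relative tolerance absorbs floating-point bin positions
    (e.g. 48 * (1/3) != 16 exactly).
    """
    freqs = np.asarray(freqs)
    tol = (freqs[1] - freqs[0]) * 1e-6 if len(freqs) > 1 else 1e-9
    return (freqs >= band.f_lo - tol) & (freqs <= band.f_hi + tol)


def band_power(spec: Spectrum, band: BandDefinition) -> float:
    """Mean power density over the band's bins (closed interval)."""
    mask = band_mask(spec.freqs, band)
    if not mask.any():
        raise ValueError(
            f"band {band.name} [{band.f_lo}, {band.f_hi}] Hz contains no bins "
            f"of the grid (max {spec.freqs[-1]:g} Hz)"
        )
    return float(spec.power[mask].mean())


@dataclass(frozen=True)
class AperiodicFit:
    """log10-log10 linear fit of the aperiodic spectral background.

    ``exponent`` is the negative slope, so the predicted density is
    ``10**offset * f**(-exponent)``.
    """

    offset: float
    exponent: float
    fit_range: tuple[float, float]
    excluded_bands: tuple[BandDefinition, ...] = ()

    def predict(self, freqs: np.ndarray) -> np.ndarray:
        freqs = np.asarray(freqs, dtype=float)
        out = np.full_like(freqs, np.nan)
        pos = freqs > 0
        out[pos] = 10.0 ** (self.offset - self.exponent * np.log10(freqs[pos]))
        return out


@dataclass(frozen=True)
class FitConfig:
    """Aperiodic-fit settings: range, band-exclusion margin and log floor."""

    fit_range: tuple[float, float] = (1.0, 45.0)
    margin_bins: int = 2
    eps: float = 1e-30


def fit_aperiodic(
    spec: Spectrum,
    fit_range: tuple[float, float] = (1.0, 45.0),
    excluded: Sequence[BandDefinition] = (),
    eps: float = 1e-30,
) -> AperiodicFit:
    """OLS of log10(power) on log10(f) over fit_range, skipping excluded bands.

    Zero-power bins are floored at ``eps`` before taking the log. Requires at
    least 5 bins after exclusion. Exact (machine precision) on noiseless
    power-law input.
    """
    lo, hi = fit_range
    if not (0 < lo < hi):
        raise ValueError("fit_range must satisfy 0 < lo < hi")
    freqs = spec.freqs
    tol = spec.resolution * 1e-6
    mask = (freqs >= lo - tol) & (freqs <= hi + tol) & (freqs > 0)
    for band in excluded:
        mask &= ~band_mask(freqs, band)
    if mask.sum() < 5:
        raise ValueError(f"only {int(mask.sum())} bins remain for the aperiodic fit (need >= 5)")
    x = np.log10(freqs[mask])
    y = np.log10(np.maximum(spec.power[mask], eps))
    slope, intercept = np.polyfit(x, y, 1)
    return AperiodicFit(float(intercept), float(-slope), (lo, hi), tuple(excluded))


def fit_aperiodic_excluding(
    spec: Spectrum,
    bands: Iterable[BandDefinition],
    cfg: FitConfig = FitConfig(),
) -> AperiodicFit:
    """Fit the aperiodic component excluding the given oscillatory bands,
    each widened by ``cfg.margin_bins`` frequency bins on both sides."""
    margin = cfg.margin_bins * spec.resolution
    excluded = tuple(b.expand(margin) for b in bands)
    return fit_aperiodic(spec, cfg.fit_range, excluded, cfg.eps)


def corrected_spectrum_db(spec: Spectrum, fit: AperiodicFit, eps: float = 1e-30) -> np.ndarray:
    """10*log10(power / aperiodic prediction) per bin; -inf at f == 0."""
    pred = fit.predict(spec.freqs)
    out = np.full(spec.freqs.shape, -np.inf)
    ok = spec.freqs > 0
    out[ok] = 10.0 * np.log10(np.maximum(spec.power[ok], eps) / pred[ok])
    return out


def corrected_power(spec: Spectrum, fit: AperiodicFit, band: BandDefinition) -> float:
    """1/f-corrected band power: mean over band bins of the dB ratio of the
    spectrum to the aperiodic fit. Zero when the spectrum equals the fit."""
    mask = band_mask(spec.freqs, band)
    if not mask.any():
        raise ValueError(f"band {band.name} contains no bins")
    return float(corrected_spectrum_db(spec, fit)[mask].mean())


def corrected_power_linear(spec: Spectrum, fit: AperiodicFit, band: BandDefinition) -> float:
    """1/f-corrected band power by linear subtraction: mean over band bins of
    (power - aperiodic prediction), in µV²/Hz. Can be negative when the band
    dips below the fitted background. Unlike the dB variant, a narrow peak
    riding on many background bins is not diluted by the log transform."""
    mask = band_mask(spec.freqs, band)
    if not mask.any():
        raise ValueError(f"band {band.name} contains no bins")
    pred = fit.predict(spec.freqs)
    return float((spec.power[mask] - pred[mask]).mean())


def snr_db(spec: Spectrum, fit: AperiodicFit, band: BandDefinition) -> float:
    """Band SNR: max over band bins of the dB ratio to the aperiodic fit."""
    mask = band_mask(spec.freqs, band)
    if not mask.any():
        raise ValueError(f"band {band.name} contains no bins")
    return float(corrected_spectrum_db(spec, fit)[mask].max())
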