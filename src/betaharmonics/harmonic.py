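"""Harmonic-vs-genuine classification of beta-band spectral peaks.

A beta peak is called harmonic when, in the mean spectrum of the highest
alpha-power segments, the beta-band peak frequency sits within a tolerance
of one frequency bin of exactly twice the alpha-band peak frequency.
Recordings whose alpha rhythm is too weak (band SNR at or below a dB
threshold over the fitted 1/f background) are excluded rather than
classified, because peak frequencies are unreliable at low SNR.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .spectral import (
    ALPHA_BAND,
    BETA_BAND,
    AperiodicFit,
    BandDefinition,
    FitConfig,
    SegmentSet,
    Spectrum,
    band_mask,
    corrected_spectrum_db,
    fit_aperiodic_excluding,
    mean_spectrum,
    segment,
    spectra,
    snr_db,
)
from .timeseries import TimeSeries

__all__ = [
    "HarmonicConfig",
    "HarmonicVerdict",
    "select_high_alpha_segments",
    "find_peak",
    "classify_harmonic",
    "participant_verdict",
    "cohort_summary",
]


@dataclass(frozen=True)
class HarmonicConfig:
    """Settings for the per-recording harmonic classification pipeline."""

    alpha: BandDefinition = ALPHA_BAND
    beta: BandDefinition = BETA_BAND
    fraction: float = 0.2  # top alpha-power fraction of segments
    snr_threshold_db: float = 5.0
    tol_bins: int = 1
    fit: FitConfig = field(default_factory=FitConfig)


@dataclass(frozen=True)
class HarmonicVerdict:
    """Per-recording classification outcome.

    ``verdict`` is one of ``"harmonic"``, ``"non-harmonic"``, ``"excluded"``.
    Peaks are None when not found (or not estimated for excluded
    recordings); ``ratio`` is f_beta / f_alpha when both exist.
    """

    f_alpha: Optional[float]
    f_beta: Optional[float]
    ratio: Optional[float]
    bin_width: float
    tol_bins: int
    alpha_snr: float
    verdict: str

    @property
    def is_harmonic(self) -> Optional[bool]:
        """True/False for classified recordings, None when excluded."""
        if self.verdict == "excluded":
            return None
        return self.verdict == "harmonic"


def select_high_alpha_segments(
    segset: SegmentSet,
    alpha: BandDefinition = ALPHA_BAND,
    fraction: float = 0.2,
) -> SegmentSet:
    """Keep the ceil(fraction * n) segments with the highest alpha power.

    Ties are broken toward the earlier segment (stable sort by index). The
    selected segments keep their original temporal order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    freqs, pxx = spectra(segset)
    mask = band_mask(freqs, alpha)
    if not mask.any():
        raise ValueError(f"band {alpha.name} contains no bins")
    power = pxx[:, mask].mean(axis=1)
    k = math.ceil(fraction * segset.n_segments)
    chosen = np.sort(np.argsort(-power, kind="stable")[:k])
    return SegmentSet(
        segset.segments[chosen],
        segset.rate,
        segset.seg_len,
        source_label=segset.source_label,
    )


def find_peak(
    spec: Spectrum,
    band: BandDefinition,
    fit: AperiodicFit,
) -> Optional[float]:
    """Frequency of the strongest 1/f-corrected local maximum within a band.

    A bin qualifies only if its corrected power strictly exceeds both grid
    neighbours (so band-edge argmax artifacts never count as peaks); the
    first and last grid bins never qualify. Returns None when the band holds
    no local maximum; exact ties resolve toward the lower frequency.
    """
    c = corrected_spectrum_db(spec, fit)
    local_max = np.zeros(len(c), dtype=bool)
    local_max[1:-1] = (c[1:-1] > c[:-2]) & (c[1:-1] > c[2:])
    candidates = np.flatnonzero(local_max & band_mask(spec.freqs, band))
    if candidates.size == 0:
        return None
    best = candidates[np.argmax(c[candidates])]  # argmax -> first, i.e. lowest f
    return float(spec.freqs[best])


def classify_harmonic(
    f_alpha: float,
    f_beta: float,
    bin_width: float,
    tol_bins: int = 1,
) -> bool:
    """True iff the beta peak is within tol_bins frequency bins of 2*f_alpha."""
    if bin_width <= 0 or tol_bins < 0:
        raise ValueError("bin_width must be positive and tol_bins >= 0")
    # absolute slack at double precision so |20.33 - 20| <= 1/3 holds at bin precision
    return abs(f_beta - 2.0 * f_alpha) <= tol_bins * bin_width + 1e-9


def participant_verdict(
    source: Union[TimeSeries, SegmentSet],
    cfg: HarmonicConfig = HarmonicConfig(),
    seg_len: float = 3.0,
) -> HarmonicVerdict:
    """Run the full per-recording harmonic classification.

    Pipeline: segment the recording, keep the top-fraction alpha-power
    segments, average their spectra, fit the aperiodic background (alpha and
    beta excluded), gate on alpha SNR, locate alpha and beta peaks on the
    corrected spectrum, and apply the one-bin peak-ratio rule.
    """
    if isinstance(source, TimeSeries):
        segset = segment(source, seg_len)
    else:
        segset = source
    selected = select_high_alpha_segments(segset, cfg.alpha, cfg.fraction)
    ms = mean_spectrum(selected)
    bin_width = ms.resolution
    # spectral resolution is tied to the segment length by construction
    assert abs(bin_width - 1.0 / segset.seg_len) <= 1e-9 * bin_width + 1e-12

    fit = fit_aperiodic_excluding(ms, (cfg.alpha, cfg.beta), cfg.fit)
    alpha_snr = snr_db(ms, fit, cfg.alpha)
    if alpha_snr <= cfg.snr_threshold_db:
        return HarmonicVerdict(
            None, None, None, bin_width, cfg.tol_bins, alpha_snr, "excluded"
        )
    f_alpha = find_peak(ms, cfg.alpha, fit)
    f_beta = find_peak(ms, cfg.beta, fit)
    if f_alpha is None:
        # SNR gate passed but no isolated alpha maximum: no usable base peak
        return HarmonicVerdict(
            None, f_beta, None, bin_width, cfg.tol_bins, alpha_snr, "excluded"
        )
    if f_beta is None:
        return HarmonicVerdict(
            f_alpha, None, None, bin_width, cfg.tol_bins, alpha_snr, "non-harmonic"
        )
    harmonic = classify_harmonic(f_alpha, f_beta, bin_width, cfg.tol_bins)
    return HarmonicVerdict(
        f_alpha,
        f_beta,
        f_beta / f_alpha,
        bin_width,
        cfg.tol_bins,
        alpha_snr,
        "harmonic" if harmonic else "non-harmonic",
    )


def cohort_summary(verdicts: Sequence[HarmonicVerdict]) -> dict:
    """Aggregate verdicts into cohort proportions.

    The harmonic percentage is computed among recordings passing the SNR
    gate (non-excluded); it is None when every recording was excluded.
    """
    if len(verdicts) == 0:
        raise ValueError("cohort_summary needs at least one verdict")
    n = len(verdicts)
    n_harm = sum(v.verdict == "harmonic" for v in verdicts)
    n_non = sum(v.verdict == "non-harmonic" for v in verdicts)
    n_excl = sum(v.verdict == "excluded" for v in verdicts)
    included = n_harm + n_non
    return {
        "n": n,
        "n_harmonic": n_harm,
        "n_non_harmonic": n_non,
        "n_excluded": n_excl,
        "pct_harmonic": 100.0 * n_harm / included if included else None,
        "pct_non_harmonic": 100.0 * n_non / included if included else None,
        "pct_excluded": 100.0 * n_excl / n,
    }
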