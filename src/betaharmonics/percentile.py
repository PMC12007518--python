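"""Percentile spectra and cross-band power-dependence screening.

Segments are ranked by power in a sorting band (beta, 16-30 Hz, by default)
and binned into contiguous rank groups; the mean spectrum per group is the
"percentile spectrum". If a beta peak is a harmonic of alpha, sorting by
beta power also sorts alpha power, so the Spearman rank correlation between
1/f-corrected alpha- and beta-power across groups is strongly positive;
genuine independent beta gives rho near 0, and alpha/beta competition gives
negative rho.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .spectral import (
    ALPHA_BAND,
    BETA_BAND,
    BandDefinition,
    FitConfig,
    SegmentSet,
    Spectrum,
    band_mask,
    corrected_power,
    corrected_power_linear,
    fit_aperiodic_excluding,
    spectra,
)

__all__ = [
    "PercentileSpectrum",
    "RegimeCall",
    "build_percentile_spectrum",
    "spearman_rho",
    "alpha_beta_dependence",
]


@dataclass
class PercentileSpectrum:
    """Group-mean spectra after sorting segments by sort-band power.

    Groups are ordered by ascending sort-band power; sizes differ by at most
    one (extra segments go to the lowest-rank groups).
    """

    n_groups: int
    sort_band: BandDefinition
    freqs: np.ndarray
    group_mean_power: np.ndarray  # (n_groups, n_freqs)
    group_sort_power: np.ndarray  # raw mean sort-band power per group, ascending
    group_sizes: np.ndarray
    # per-band corrected dB values, filled by alpha_beta_dependence
    group_corrected: dict = field(default_factory=dict)

    def group_spectrum(self, g: int) -> Spectrum:
        return Spectrum(self.freqs, self.group_mean_power[g])


@dataclass(frozen=True)
class RegimeCall:
    """Dependence verdict: Spearman rho over groups plus thresholded regime."""

    rho: float
    regime: str  # anticorrelated | independent | positive
    threshold: float


def build_percentile_spectrum(
    segset: SegmentSet,
    sort_band: BandDefinition = BETA_BAND,
    n_groups: int = 20,
) -> PercentileSpectrum:
    """Sort segments by sort-band power and average spectra within rank groups.

    Ranking uses the raw (uncorrected) per-segment band power; ties are
    broken by segment index (stable sort). With ``n`` segments and ``g``
    groups, the lowest ``n % g`` groups receive one extra segment.
    """
    n = segset.n_segments
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if n < n_groups:
        raise ValueError(f"{n} segments cannot be split into {n_groups} groups")
    freqs, pxx = spectra(segset)
    mask = band_mask(freqs, sort_band)
    if not mask.any():
        raise ValueError(f"sort band {sort_band.name} contains no bins")
    sort_power = pxx[:, mask].mean(axis=1)
    order = np.argsort(sort_power, kind="stable")

    base, extra = divmod(n, n_groups)
    sizes = np.full(n_groups, base, dtype=int)
    sizes[:extra] += 1
    bounds = np.concatenate(([0], np.cumsum(sizes)))

    group_mean = np.empty((n_groups, len(freqs)))
    group_sort = np.empty(n_groups)
    for g in range(n_groups):
        idx = order[bounds[g] : bounds[g + 1]]
        group_mean[g] = pxx[idx].mean(axis=0)
        group_sort[g] = sort_power[idx].mean()
    # monotone by construction; guard against bookkeeping regressions
    assert np.all(np.diff(group_sort) >= -1e-12 * max(group_sort.max(), 1.0))
    return PercentileSpectrum(n_groups, sort_band, freqs, group_mean, group_sort, sizes)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a rank correlation")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


def alpha_beta_dependence(
    ps: PercentileSpectrum,
    alpha: BandDefinition = ALPHA_BAND,
    beta: BandDefinition = BETA_BAND,
    fit_cfg: FitConfig = FitConfig(),
    threshold: float = 0.5,
    correction: str = "linear",
) -> RegimeCall:
    """Correlate 1/f-corrected alpha- and beta-power across percentile groups.

    Each group-mean spectrum gets its own aperiodic fit (alpha and beta bands
    excluded, widened by the configured margin); corrected band powers are
    rank-correlated across groups. ``correction`` selects the domain:
    ``"linear"`` subtracts the 1/f estimate from the spectrum before taking
    band power (the default — a narrow harmonic peak keeps its full weight),
    ``"log"`` uses the mean dB ratio to the fit. Regime: ``positive`` if
    rho >= threshold, ``anticorrelated`` if rho <= -threshold, else
    ``independent``. The threshold is a screening convention, not an
    empirical quantity.
    """
    if ps.n_groups < 3:
        raise ValueError("need at least 3 groups to correlate band powers")
    if correction not in ("linear", "log"):
        raise ValueError("correction must be 'linear' or 'log'")
    corr_fn = corrected_power_linear if correction == "linear" else corrected_power
    alpha_p = np.empty(ps.n_groups)
    beta_p = np.empty(ps.n_groups)
    for g in range(ps.n_groups):
        spec = ps.group_spectrum(g)
        fit = fit_aperiodic_excluding(spec, (alpha, beta), fit_cfg)
        alpha_p[g] = corr_fn(spec, fit, alpha)
        beta_p[g] = corr_fn(spec, fit, beta)
    ps.group_corrected = {alpha.name: alpha_p, beta.name: beta_p}
    rho = spearman_rho(alpha_p, beta_p)
    if rho >= threshold:
        regime = "positive"
    elif rho <= -threshold:
        regime = "anticorrelated"
    else:
        regime = "independent"
    return RegimeCall(rho, regime, threshold)
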