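"""Generator behaviour: spectral content, phase locking, coupling regimes."""
import numpy as np
import pytest
from scipy.signal import hilbert
from scipy.stats import spearmanr

import betaharmonics as bh
from betaharmonics.spectral import band_mask, spectra


def _loglog_slope(freqs, power, lo=1.0, hi=45.0):
    mask = (freqs >= lo) & (freqs <= hi)
    return np.polyfit(np.log10(freqs[mask]), np.log10(power[mask]), 1)[0]


class TestPinkNoise:
    @pytest.mark.parametrize("exponent", [0.0, 1.5])
    def test_fitted_slope_matches_requested_exponent(self, exponent):
        # oracle: log-log least squares on the seed-averaged periodogram
        psds = []
        for seed in range(50):
            noise = bh.NoiseSpec(exponent=exponent, scale=100.0, seed=seed)
            ts = bh.gen_pink_noise(int(60 * 250), 250.0, noise)
            sp = bh.segment_spectrum(ts.samples[0], 250.0)
            psds.append(sp.power)
        slope = _loglog_slope(sp.freqs, np.mean(psds, axis=0))
        assert slope == pytest.approx(-exponent, abs=0.1)

    def test_scale_sets_density_at_reference_frequency(self):
        # the log-log intercept of the averaged spectrum is the density at
        # the 1 Hz reference (single bins are too noisy to read directly)
        psds = []
        for seed in range(50):
            ts = bh.gen_pink_noise(int(60 * 250), 250.0, bh.NoiseSpec(1.5, 40.0, seed))
            sp = bh.segment_spectrum(ts.samples[0], 250.0)
            psds.append(sp.power)
        mean = np.mean(psds, axis=0)
        mask = (sp.freqs >= 2.0) & (sp.freqs <= 45.0)
        _, intercept = np.polyfit(np.log10(sp.freqs[mask]), np.log10(mean[mask]), 1)
        assert 10.0**intercept == pytest.approx(40.0, rel=0.1)

    def test_deterministic_for_seed(self):
        spec = bh.NoiseSpec(seed=9)
        a = bh.gen_pink_noise(1000, 250.0, spec)
        b = bh.gen_pink_noise(1000, 250.0, spec)
        assert np.array_equal(a.samples, b.samples)

    @pytest.mark.parametrize("n,rate", [(0, 250.0), (1, 250.0), (100, 0.0)])
    def test_degenerate_input_rejected(self, n, rate):
        with pytest.raises(ValueError):
            bh.gen_pink_noise(n, rate, bh.NoiseSpec())


class TestRhythm:
    def test_pure_sinusoid_has_no_harmonic_power(self):
        ts = bh.gen_rhythm(bh.RhythmSpec(10.0), 3.0, 250.0, seed=1)
        sp = bh.segment_spectrum(ts.samples[0], 250.0)
        i10 = np.argmin(np.abs(sp.freqs - 10.0))
        i20 = np.argmin(np.abs(sp.freqs - 20.0))
        assert np.argmax(sp.power) == i10
        assert sp.power[i20] < 0.01 * sp.power[i10]

    def test_harmonic_amplitude_ratio_squares_in_power(self):
        spec = bh.RhythmSpec(10.0, harmonics=(bh.Harmonic(2, 0.5, np.pi / 2),))
        ts = bh.gen_rhythm(spec, 3.0, 250.0, seed=1)
        sp = bh.segment_spectrum(ts.samples[0], 250.0)
        i10 = np.argmin(np.abs(sp.freqs - 10.0))
        i20 = np.argmin(np.abs(sp.freqs - 20.0))
        assert sp.power[i20] / sp.power[i10] == pytest.approx(0.25, rel=1e-6)

    def test_envelope_couples_base_and_harmonic_band_power(self):
        spec = bh.RhythmSpec(
            10.0,
            harmonics=(bh.Harmonic(2, 0.5, 0.0),),
            envelope=bh.EnvelopeSpec("random"),
        )
        ts = bh.gen_rhythm(spec, 300.0, 250.0, seed=3)
        segset = bh.segment(ts, 3.0)
        freqs, pxx = spectra(segset)
        p10 = pxx[:, np.argmin(np.abs(freqs - 10.0))]
        p20 = pxx[:, np.argmin(np.abs(freqs - 20.0))]
        assert spearmanr(p10, p20).statistic > 0.9

    def test_phase_locking_between_base_and_harmonic(self):
        # base and harmonic generated separately with the same fixed phase;
        # phi(2 f0) - 2 phi(f0) must equal the requested lag at every sample
        lag = 0.7
        base = bh.gen_rhythm(bh.RhythmSpec(10.0, phase=0.3), 10.0, 250.0)
        harm_spec = bh.RhythmSpec(
            10.0, amplitude=0.0, harmonics=(bh.Harmonic(2, 1.0, lag),), phase=0.3
        )
        # amplitude scales only the base; rebuild harmonic-only signal directly
        t = np.arange(2500) / 250.0
        theta = 2 * np.pi * 10.0 * t + 0.3
        harm = np.sin(2 * theta + lag)
        full = bh.gen_rhythm(
            bh.RhythmSpec(10.0, harmonics=(bh.Harmonic(2, 0.5, lag),), phase=0.3),
            10.0,
            250.0,
        )
        assert np.allclose(full.samples[0], np.sin(theta) + 0.5 * harm, atol=1e-12)
        phi1 = np.angle(hilbert(base.samples[0]))
        phi2 = np.angle(hilbert(harm))
        # sin-based phases: analytic phase of sin(x) is x - pi/2, so the
        # constant offset phi2 - 2*phi1 comes out as lag + pi/2
        d = np.angle(np.exp(1j * (phi2 - 2 * phi1)))[100:-100]
        assert np.all(np.abs(d - (lag + np.pi / 2)) < 1e-6)

    def test_noiseless_power_confined_to_specified_bins(self):
        spec = bh.RhythmSpec(10.0, harmonics=(bh.Harmonic(2, 0.5, 0.0),), phase=0.0)
        ts = bh.gen_rhythm(spec, 10.0, 250.0)
        p = np.abs(np.fft.rfft(ts.samples[0])) ** 2
        freqs = np.fft.rfftfreq(ts.n_samples, 1 / 250.0)
        at_peaks = p[np.isin(freqs, (10.0, 20.0))].sum()
        assert at_peaks > 0.99 * p.sum()

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="base period"):
            bh.gen_rhythm(bh.RhythmSpec(10.0), 0.05, 250.0)

    def test_harmonics_require_sinusoidal_carrier(self):
        with pytest.raises(ValueError):
            bh.RhythmSpec(20.0, bandwidth=4.0, harmonics=(bh.Harmonic(2, 0.5),))

    def test_duplicate_harmonic_multiples_rejected(self):
        with pytest.raises(ValueError):
            bh.RhythmSpec(10.0, harmonics=(bh.Harmonic(2, 0.5), bh.Harmonic(2, 0.1)))


class TestScenario:
    def test_identical_spec_gives_bit_identical_output(self):
        spec = bh.make_scenario("harmonic", seed=4)
        a, _ = bh.gen_scenario(spec)
        b, _ = bh.gen_scenario(spec)
        assert np.array_equal(a.samples, b.samples)

    def test_anticorrelated_envelopes_are_countermonotone(self, anticorrelated_recording):
        _, truth = anticorrelated_recording
        rho = spearmanr(truth["alpha_envelope"], truth["beta_envelope"]).statistic
        assert rho <= -0.9

    def test_independent_envelopes_are_uncoupled(self, independent_recording):
        _, truth = independent_recording
        ea = bh.segment_envelope_power(truth["alpha_envelope"], 250.0, 3.0)
        eb = bh.segment_envelope_power(truth["beta_envelope"], 250.0, 3.0)
        assert abs(spearmanr(ea, eb).statistic) < 0.3

    def test_harmonic_regime_rejects_genuine_beta(self):
        alpha = bh.RhythmSpec(10.0, harmonics=(bh.Harmonic(2, 0.5),))
        beta = bh.RhythmSpec(22.0, bandwidth=4.0)
        with pytest.raises(ValueError):
            bh.ScenarioSpec("harmonic", alpha, beta)

    def test_independent_regime_requires_beta(self):
        with pytest.raises(ValueError, match="genuine beta"):
            bh.ScenarioSpec("independent", bh.RhythmSpec(10.0), None)

    def test_degenerate_zero_amplitude_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            bh.ScenarioSpec(
                "independent",
                bh.RhythmSpec(10.0, amplitude=0.0),
                bh.RhythmSpec(22.0, amplitude=0.0, bandwidth=4.0),
            )


class TestMixForward:
    def test_identity_mixing_preserves_source(self):
        src = bh.gen_rhythm(bh.RhythmSpec(10.0), 2.0, 250.0, seed=0)
        out = bh.mix_forward(src, np.eye(1))
        assert np.array_equal(out.samples, src.samples)

    def test_wrong_column_count_rejected(self):
        src = bh.gen_rhythm(bh.RhythmSpec(10.0), 2.0, 250.0, seed=0)
        with pytest.raises(ValueError, match="columns"):
            bh.mix_forward(src, np.ones((4, 3)))
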