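"""Zero-phase band-pass and spatio-spectral decomposition."""
import numpy as np
import pytest

import betaharmonics as bh
from betaharmonics.ssd import FLANK_HI, FLANK_LO, apply_filters


def _sinusoid_ts(freq, duration=10.0, rate=250.0):
    t = np.arange(int(duration * rate)) / rate
    return bh.TimeSeries(np.sin(2 * np.pi * freq * t), rate, ["CH1"])


def _alpha_mixing_sim(seed, n_ch=8, n_noise=3, dur=60.0, rate=250.0, sensor_noise=1.0):
    rng = np.random.default_rng(seed)
    alpha = bh.gen_rhythm(
        bh.RhythmSpec(10.0, amplitude=10.0, envelope=bh.EnvelopeSpec("random")),
        dur,
        rate,
        seed=seed,
    )
    rows = [alpha.samples[0]]
    for k in range(n_noise):
        rows.append(
            bh.gen_pink_noise(
                alpha.n_samples, rate, bh.NoiseSpec(1.5, 25.0, seed=seed * 100 + k + 1)
            ).samples[0]
        )
    sources = bh.TimeSeries(np.vstack(rows), rate, [f"S{i}" for i in range(len(rows))])
    mixing = rng.standard_normal((n_ch, len(rows)))
    mixed = bh.mix_forward(sources, mixing, sensor_noise_std=sensor_noise, seed=seed + 7)
    return alpha, sources, mixing, mixed


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        out = bh.bandpass(_sinusoid_ts(10.0), bh.ALPHA_BAND)
        mid = out.samples[0][500:-500]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.01)

    def test_stopband_attenuated_beyond_20_db(self):
        out = bh.bandpass(_sinusoid_ts(25.0), bh.ALPHA_BAND)
        mid = out.samples[0][500:-500]
        assert 20 * np.log10(np.abs(mid).max()) < -20.0

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bh.bandpass(_sinusoid_ts(10.0), bh.BandDefinition("hf", 100.0, 130.0))

    def test_length_preserved(self):
        ts = _sinusoid_ts(10.0)
        assert bh.bandpass(ts, bh.ALPHA_BAND).n_samples == ts.n_samples


class TestSSDDecompose:
    def test_recovers_single_alpha_source(self):
        alpha, _, _, mixed = _alpha_mixing_sim(seed=0)
        res = bh.ssd_decompose(mixed)
        comp = apply_filters(res, mixed).samples[0]
        assert abs(np.corrcoef(comp, alpha.samples[0])[0, 1]) > 0.95

    def test_alpha_component_prefers_alpha_over_beta_source(self):
        rate, dur = 250.0, 60.0
        alpha = bh.gen_rhythm(
            bh.RhythmSpec(10.0, amplitude=10.0, envelope=bh.EnvelopeSpec("random")),
            dur, rate, seed=1,
        )
        beta = bh.gen_rhythm(
            bh.RhythmSpec(22.0, amplitude=10.0, bandwidth=4.0, envelope=bh.EnvelopeSpec("random")),
            dur, rate, seed=2,
        )
        sources = bh.TimeSeries(
            np.vstack([alpha.samples[0], beta.samples[0]]), rate, ["a", "b"]
        )
        rng = np.random.default_rng(3)
        mixed = bh.mix_forward(sources, rng.standard_normal((8, 2)), 0.5, seed=4)
        res = bh.ssd_decompose(mixed)
        comp = apply_filters(res, mixed).samples[0]
        c_alpha = abs(np.corrcoef(comp, alpha.samples[0])[0, 1])
        c_beta = abs(np.corrcoef(comp, beta.samples[0])[0, 1])
        assert c_alpha > c_beta

    def test_generalized_eigenvalue_residual(self):
        _, _, _, mixed = _alpha_mixing_sim(seed=5)
        sig = bh.bandpass(mixed, bh.ALPHA_BAND)
        S = np.cov(sig.samples)
        lo = bh.bandpass(mixed, FLANK_LO)
        hi = bh.bandpass(mixed, FLANK_HI)
        N = np.cov(lo.samples) + np.cov(hi.samples)
        res = bh.ssd_decompose(mixed, shrinkage=0.0)
        for k in range(res.n_components):
            w = res.filters[:, k]
            resid = np.linalg.norm(S @ w - res.eigenvalues[k] * (N @ w))
            assert resid <= 1e-8 * np.linalg.norm(w) * np.linalg.norm(S)

    def test_eigenvalues_descending_and_patterns_consistent(self):
        _, _, _, mixed = _alpha_mixing_sim(seed=6)
        res = bh.ssd_decompose(mixed)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        S = np.cov(bh.bandpass(mixed, bh.ALPHA_BAND).samples)
        np.testing.assert_allclose(res.patterns, S @ res.filters, rtol=1e-8)

    def test_channel_permutation_leaves_components_unchanged(self):
        _, _, _, mixed = _alpha_mixing_sim(seed=7)
        res = bh.ssd_decompose(mixed)
        comp = apply_filters(res, mixed).samples[0]
        perm = np.random.default_rng(0).permutation(mixed.n_channels)
        permuted = bh.TimeSeries(
            mixed.samples[perm], mixed.rate, [mixed.channel_labels[i] for i in perm]
        )
        res_p = bh.ssd_decompose(permuted)
        comp_p = apply_filters(res_p, permuted).samples[0]
        assert abs(np.corrcoef(comp, comp_p)[0, 1]) > 1 - 1e-9

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="2 channels"):
            bh.ssd_decompose(_sinusoid_ts(10.0))

    def test_overlapping_flank_rejected(self):
        _, _, _, mixed = _alpha_mixing_sim(seed=8)
        with pytest.raises(ValueError, match="overlap"):
            bh.ssd_decompose(mixed, flank_lo=bh.BandDefinition("f", 7.0, 9.0))

    def test_rank_deficient_input_warns_and_reduces(self):
        _, _, _, mixed = _alpha_mixing_sim(seed=9, n_ch=4)
        dup = bh.TimeSeries(
            np.vstack([mixed.samples, mixed.samples[:1]]),
            mixed.rate,
            mixed.channel_labels + ["DUP"],
        )
        with pytest.warns(RuntimeWarning, match="rank"):
            res = bh.ssd_decompose(dup)
        assert res.n_components < dup.n_channels


class TestBestAlphaComponent:
    def test_matches_highest_alpha_snr(self):
        alpha, _, _, mixed = _alpha_mixing_sim(seed=10)
        res = bh.ssd_decompose(mixed)
        best = bh.best_alpha_component(res, mixed)
        snrs = bh.component_snr(res, mixed)
        assert best.meta["component_index"] == int(np.argmax(snrs))
        assert abs(np.corrcoef(best.samples[0], alpha.samples[0])[0, 1]) > 0.95

    def test_component_ordering_does_not_fool_selection(self):
        # filters deliberately ordered noise-first: selection must pick the
        # alpha channel by SNR, not by position
        rate = 250.0
        alpha = bh.gen_rhythm(bh.RhythmSpec(10.0, amplitude=10.0), 60.0, rate, seed=1)
        noise = bh.gen_pink_noise(alpha.n_samples, rate, bh.NoiseSpec(1.5, 25.0, seed=2))
        ts = bh.TimeSeries(
            np.vstack([noise.samples[0], alpha.samples[0]]), rate, ["N", "A"]
        )
        res = bh.SSDResult(
            filters=np.eye(2),
            patterns=np.eye(2),
            eigenvalues=np.array([1.0, 0.5]),
            signal_band=bh.ALPHA_BAND,
            channel_labels=["N", "A"],
        )
        best = bh.best_alpha_component(res, ts)
        assert best.meta["component_index"] == 1

    def test_empty_result_rejected(self):
        ts = _sinusoid_ts(10.0)
        res = bh.SSDResult(
            filters=np.empty((1, 0)),
            patterns=np.empty((1, 0)),
            eigenvalues=np.empty(0),
            signal_band=bh.ALPHA_BAND,
            channel_labels=["CH1"],
        )
        with pytest.raises(ValueError, match="no components"):
            bh.best_alpha_component(res, ts)
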