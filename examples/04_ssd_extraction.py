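"""Recover an alpha source from an 8-channel mixture with SSD.

One alpha rhythm plus three 1/f noise sources are mixed into 8 channels
with sensor noise; spatio-spectral decomposition maximizes 8-13 Hz power
against the 6-7 / 14-15 Hz flanks, and the component with the highest
alpha-band SNR is compared against the ground-truth source.
"""
import numpy as np

import betaharmonics as bh

rate, dur, seed = 250.0, 60.0, 7
rng = np.random.default_rng(seed)

alpha = bh.gen_rhythm(
    bh.RhythmSpec(10.0, amplitude=10.0, envelope=bh.EnvelopeSpec("random")),
    dur, rate, seed=seed,
)
rows = [alpha.samples[0]] + [
    bh.gen_pink_noise(alpha.n_samples, rate, bh.NoiseSpec(1.5, 25.0, seed=seed + k)).samples[0]
    for k in range(1, 4)
]
sources = bh.TimeSeries(np.vstack(rows), rate, ["alpha", "n1", "n2", "n3"])
mixed = bh.mix_forward(sources, rng.standard_normal((8, 4)), sensor_noise_std=1.0, seed=seed)

res = bh.ssd_decompose(mixed)
best = bh.best_alpha_component(res, mixed)
corr = np.corrcoef(best.samples[0], alpha.samples[0])[0, 1]

print(f"SSD eigenvalues (signal/flank power ratios): {np.round(res.eigenvalues, 2)}")
print(f"selected component: #{best.meta['component_index'] + 1}, "
      f"alpha SNR {best.meta['alpha_snr_db']:.1f} dB")
print(f"|correlation| with ground-truth alpha source: {abs(corr):.4f}")
print("\nValues near 1 mean the spatial filter isolated the rhythm from the mixture.")
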