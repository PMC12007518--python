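"""Percentile spectrum of a nonsinusoidal alpha rhythm, as a figure.

Segments of a harmonic-regime recording are sorted by beta-band power into
5 groups; one mean spectrum per group is plotted (dark = low beta power,
bright = high). Because the 20 Hz peak is the alpha rhythm's harmonic, the
10 Hz peak grows in lockstep with it across groups.
"""
from pathlib import Path

import betaharmonics as bh

ts, _ = bh.gen_scenario(bh.make_scenario("harmonic", seed=7))
ps = bh.build_percentile_spectrum(bh.segment(ts, seg_len=3.0), bh.BETA_BAND, n_groups=5)

out = Path(__file__).parent / "percentile_spectrum.png"
bh.plot_percentile_spectrum(ps, out)
print(f"wrote {out}")
for g in range(ps.n_groups):
    print(
        f"group {g + 1}: mean beta-band power {ps.group_sort_power[g]:6.2f} µV²/Hz "
        f"({ps.group_sizes[g]} segments)"
    )
print("\nbeta-band power per group is non-decreasing by construction;")
print("the figure shows the alpha peak rising with it.")
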