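"""Infraslow band power around a surrogate seizure, before and after inverse filtering.

A surrogate ictal recording (pre-onset DC shift, 8 Hz ictal burst,
post-ictal slow wave) passes through the 0.1 Hz high-pass chain, which
strips the sub-0.1 Hz content.  A Morlet-wavelet band-power time course
shows the reconstruction regaining ictal infraslow power that the raw
recording lacks — the contrast a reviewer of seizure-onset-zone candidates
would look for.
"""

import numpy as np

from isarestore import (band_power_timecourse, characterize_uir, default_chain,
                        downsample, inverse_filter, make_step,
                        make_surrogate_seizure, simulate_recording)

rate = 1000.0
chain = default_chain(0.1)
uir = characterize_uir(simulate_recording(make_step(rate, 60.0, 10.0), chain))

sur = make_surrogate_seizure(rate, duration_s=600.0, onset_s=200.0, offset_s=320.0, seed=3)
recorded = simulate_recording(sur.signal, chain)
recon = inverse_filter(recorded, uir)


def isa_contrast(ts, name):
    bp = band_power_timecourse(downsample(ts, 8.0), f_lo=0.03, f_hi=0.1, n_cycles=5)
    t = bp.times
    base = bp.samples[(t >= 130) & (t < 190)].mean()
    ictal = bp.samples[(t >= 200) & (t < 320)].mean()
    print(f"{name:>14}: baseline {base:8.4f}  ictal {ictal:8.4f}  contrast {ictal - base:+8.4f}")
    return ictal - base


print("sub-0.1 Hz band power (0.03-0.1 Hz, arbitrary units^2):")
c_rec = isa_contrast(recorded, "recorded")
c_recon = isa_contrast(recon, "reconstruction")
print()
print(f"The reconstruction's ictal infraslow contrast is {c_recon / c_rec:.1f}x the")
print("recorded one: the DC shift the high-pass removed is visible again,")
print("time-locked to seizure onset.")
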