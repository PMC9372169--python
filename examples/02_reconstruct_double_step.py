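"""Reconstruct a DC-shift-like double step from its high-pass-filtered recording.

The double step stands in for ictal DC shifts: sustained baseline
displacements that an AC-coupled system turns into decaying transients.
Deconvolution by the system's UIR restores the flat plateaus, even with
noise added to the recording.
"""

import numpy as np

from isarestore import (NoiseSpec, add_noise, characterize_uir, default_chain,
                        downsample, inverse_filter, make_double_step, make_step,
                        simulate_recording)

rate = 1000.0
analysis_rate = 256.0  # correlations computed at the usual analysis rate
chain = default_chain(0.1)
uir = characterize_uir(simulate_recording(make_step(rate, 60.0, 10.0), chain))

truth = make_double_step(rate, 60.0, 10.0, 20.0, 30.0, 40.0)
recorded = simulate_recording(truth, chain)
truth_lo = downsample(truth, analysis_rate)

print("Pearson r with the true double step (at 256 samples/s):")
rec_lo = downsample(recorded, analysis_rate)
print(f"  recorded output          r = {np.corrcoef(truth_lo.samples, rec_lo.samples)[0, 1]:.4f}")

for snr in (np.inf, 10.0, 1.0):
    noisy = add_noise(recorded, NoiseSpec(snr_linear=snr, seed=0))
    recon = inverse_filter(noisy, uir, force=True)  # 60 s < 600 s rule, hence force
    recon_lo = downsample(recon, analysis_rate)
    r = np.corrcoef(truth_lo.samples, recon_lo.samples)[0, 1]
    label = "clean" if np.isinf(snr) else f"SNR {snr:g}"
    print(f"  reconstruction ({label:>7}) r = {r:.4f}")

print()
print("The recording correlates poorly with the truth (the plateaus decayed")
print("away); reconstructions stay faithful even at SNR 1.")
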