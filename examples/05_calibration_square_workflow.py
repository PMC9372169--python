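"""The clinical route: characterize the UIR from a square-wave calibration signal.

Bedside EEG systems cannot be fed bench step functions, but they ship a
built-in square-wave calibration output — and a square wave is a series of
steps.  Averaging three rising-edge responses gives the same UIR as the
bench measurement, which can then be saved and reused for every recording
made on that machine.
"""

import numpy as np

from isarestore import (characterize_uir, default_chain, make_square_calibration,
                        make_step, save_uir, simulate_recording)

rate = 1000.0
chain = default_chain(0.1)

# bench route: one clean measured step
uir_step = characterize_uir(
    simulate_recording(make_step(rate, 60.0, 10.0), chain), mode="measured_step")

# clinical route: 3 cycles of the system's calibration square wave
calibration = make_square_calibration(rate, period_s=40.0, n_cycles=3)
recorded_cal = simulate_recording(calibration, chain)
uir_cal = characterize_uir(recorded_cal, mode="calibration_square")

n = min(uir_step.h.size, uir_cal.h.size)
rms = np.sqrt(np.mean((uir_step.h[:n] - uir_cal.h[:n]) ** 2))
rms_ref = np.sqrt(np.mean(uir_step.h[:n] ** 2))
print(f"measured-step UIR:  {uir_step.h.size} taps, norm {uir_step.norm:.4f}")
print(f"calibration UIR:    {uir_cal.h.size} taps, norm {uir_cal.norm:.4f}")
print(f"relative RMS difference: {rms / rms_ref:.2e}  (routes agree)")

save_uir(uir_cal, "calibration_uir.json")
print("saved to calibration_uir.json — reusable until the amplifier is swapped")
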