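"""Empirical power-rejection measurement with a pink-noise stimulus.

Replays the same pseudo-random 1/f aberration sequence through an open
branch and a closed ultrafast loop, estimates both PSDs, and compares the
closed/open ratio (the measured power rejection curve) with the analytic
form.  This mirrors how a real system's temporal performance is measured.
"""

import numpy as np

from aoloop import (PinkNoiseSpec, TimingConfig, WavefrontSeries,
                    derive_timing, estimate_psd, gen_pink_noise,
                    measure_rejection_curve, rejection_power_curve,
                    simulate_tracking, ultrafast_loop)

cfg = TimingConfig()
rate = derive_timing(cfg)["loop_rate"]
stimulus = gen_pink_noise(PinkNoiseSpec(n_steps=4096, sample_rate=rate,
                                        amplitude_rms=0.1, seed=0,
                                        n_channels=8))
series = WavefrontSeries(times=np.arange(4096) / rate, values=stimulus,
                         sample_rate=rate)
out = simulate_tracking(cfg, gain=1.0, aberration_series=series)

skip = 64  # drop the lock-in transient
open_s = WavefrontSeries(out["open_series"].times[skip:],
                         out["open_series"].values[:, skip:], rate)
closed_s = WavefrontSeries(out["closed_series"].times[skip:],
                           out["closed_series"].values[:, skip:], rate)
measured = measure_rejection_curve(estimate_psd(open_s), estimate_psd(closed_s))
theory = rejection_power_curve(ultrafast_loop(), measured.frequencies)

print("freq (Hz)   measured |H|^2   analytic |H|^2")
for f_target in (1.0, 5.0, 20.0, 35.0, 50.0):
    i = np.argmin(np.abs(measured.frequencies - f_target))
    print(f"{measured.frequencies[i]:8.1f}   {measured.power_rejection[i]:12.4f}"
          f"   {theory.power_rejection[i]:12.4f}")

crossing = measured.frequencies[measured.power_rejection >= 1.0]
print(f"\nempirical bandwidth (first unity crossing): {crossing[0]:.1f} Hz; "
      "the analytic prediction is 35.0 Hz.  Values below 1 mean the loop is "
      "suppressing aberration power at that frequency.")
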