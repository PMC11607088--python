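"""Analytic loop analysis: rejection curves, bandwidth, noise propagation.

Evaluates the closed-loop power rejection curve and its first unity
crossing (the AO bandwidth) for the ultrafast discontinuous-exposure loop,
the continuous-exposure loop at its optimal gain, and a conventional
ophthalmic AO mimic, then propagates the measured sensing noise through
the ultrafast loop.
"""

import numpy as np

from aoloop import (ao_bandwidth, continuous_loop, conventional_loop,
                    low_frequency_rejection_ratio, noise_propagated_rms,
                    rejection_power_curve, ultrafast_loop)

for name, cfg in [("ultrafast discontinuous (233 Hz, gain 1.0)", ultrafast_loop()),
                  ("continuous exposure   (342 Hz, gain 0.45)", continuous_loop()),
                  ("conventional mimic    (10 Hz,  gain 1.0)", conventional_loop())]:
    bw = ao_bandwidth(cfg)
    print(f"{name}: bandwidth {bw.f_c:5.1f} Hz "
          f"(rate-gain product {cfg.rate_gain_product:.1f} Hz)")

print()
curve = rejection_power_curve(ultrafast_loop(), np.array([1.0, 10.0, 35.0]))
for f, h2 in zip(curve.frequencies, curve.power_rejection):
    print(f"|H_reject({f:4.0f} Hz)|^2 = {h2:.2e}")
print("-> aberration power at 1 Hz is suppressed ~1400x; at the 35 Hz "
      "bandwidth the loop stops helping.")

ratio = low_frequency_rejection_ratio(conventional_loop(), ultrafast_loop())
print(f"\nUltrafast rejects {ratio:.0f}x more aberration power than the "
      "conventional loop wherever the latter corrects at all.")

rms_nm = noise_propagated_rms(0.100, ultrafast_loop(), 790.0)
print(f"0.100 rad of sensing noise -> {rms_nm:.1f} nm residual wavefront "
      "error: far below the 56 nm diffraction limit, so sensor noise does "
      "not limit performance.")
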