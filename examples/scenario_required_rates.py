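"""Ocular-aberration scenarios and the loop rate needed to correct them.

Synthesises wavefront time series from parametric PSD models of several
clinically relevant conditions (all illustrative presets on the documented
10-100x scale above the normal condition), estimates their spectra, and
predicts the smallest AO loop rate whose residual temporal error stays
below the diffraction limit.
"""

import numpy as np

from aoloop import (SCENARIO_PRESETS, diffraction_threshold_psd, estimate_psd,
                    fig_rate_family_loop, noise_floor_rms, required_loop_rate,
                    synthesize_series_from_psd, ultrafast_loop)

THRESHOLD_UM = 0.79 / 14  # diffraction limit at 790 nm
rates = np.arange(5.0, 455.0, 5.0)

print(f"diffraction limit: {THRESHOLD_UM * 1e3:.0f} nm; loop family: "
      "integration = half the loop period, discontinuous, gain 1\n")
print(f"{'scenario':>20s}  {'series RMS (nm)':>15s}  {'required rate (Hz)':>18s}")
for tag, model in SCENARIO_PRESETS.items():
    series = synthesize_series_from_psd(model, duration=5.0, n_channels=4,
                                        seed=1)
    spec = estimate_psd(series)
    rate = required_loop_rate(spec, THRESHOLD_UM, rates)
    rms = series.values.std()
    print(f"{tag:>20s}  {rms * 1e3:15.1f}  {rate:18.0f}")

sigma_w = noise_floor_rms(SCENARIO_PRESETS["normal"].noise_floor, 342.0)
print(f"\nmeasurement noise floor of the presets: sigma_W = "
      f"{sigma_w * 1e3:.1f} nm (sqrt(PSD_noise x 171 Hz))")

ultra = diffraction_threshold_psd(ultrafast_loop(), threshold=THRESHOLD_UM)
slow = diffraction_threshold_psd(fig_rate_family_loop(10.0),
                                 threshold=THRESHOLD_UM)
margin = ultra.psd[0] / slow.psd[0]
print(f"threshold input spectra: the ultrafast loop can barely correct an "
      f"input {margin:.0f}x stronger than a 10 Hz loop can (at "
      f"{ultra.frequencies[0]:.1f} Hz).  Larger required rates mean harder "
      "scenarios.")
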