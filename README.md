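# aoloop

Analysis and simulation toolkit for the temporal behaviour of closed-loop
adaptive optics (AO), built around the regime of ultrafast ophthalmic AO:
sub-millisecond wavefront-sensor exposures, hundreds of corrections per
second, and aberration dynamics measured in clinically relevant conditions
(no cycloplegia, blinks, contact lenses, nystagmus).

It is a library for researchers designing or characterising AO control
loops — in retinal imaging, vision science or microscopy — who need to
answer questions like: *what closed-loop bandwidth does a given set of loop
timings buy, which exposure scheme is better, how does sensor noise
propagate into residual wavefront error, and how fast must a loop run to
correct a measured aberration spectrum to the diffraction limit?*

## The model

A sampled integral-controller AO loop is characterised by five parameters:
the sensor integration time `T_int`, the combined readout/transfer/
processing delay `T_delay`, the deformable-mirror (DM) actuation time
constant `T_dm`, the loop rate and the loop gain.  With `s = i2πf` the
open-loop transfer is

```
G(s) = (1 − e^(−sT_int))/(sT_int) · e^(−sT_delay)/s · 1/(1 + T_dm f)
       · (loop rate × loop gain)
```

and the **power rejection curve** — the ratio of residual to input
aberration power spectral density — is `|H_reject(f)|² = 1/|1 + G|²`.
The **AO bandwidth** `f_c` is the lowest frequency at which the rejection
magnitude first reaches 1; it solves the transcendental equation

```
T_int (2πf_c)² (1 + T_dm f_c) sin[πf_c(2T_delay + T_int)]
    − (loop rate × loop gain) sin(πf_c T_int) = 0
```

so, for fixed delays, the bandwidth depends on the loop only through the
**rate–gain product**.  Around this core the package provides:

- `aoloop.control` — analytic rejection/noise transfer curves, the
  bandwidth solver, rejection-ratio comparisons, noise propagation;
- `aoloop.loopsim` — a discrete-event simulator of the continuous- and
  discontinuous-exposure schemes (latency, convergence, DM-transient
  corruption of exposures, exposure-delay optimisation, tracking);
- `aoloop.shws` — a Shack–Hartmann forward model (20×20 lenslets, 300
  active), two-step thresholding centre-of-gravity (TCoG) centroiding,
  blink detection, 63-mode Zernike least-squares reconstruction and the
  photon/readout sensing-noise budget;
- `aoloop.dm` — a 97-actuator mirror model with Gaussian influence
  functions and an SVD-truncated (85-mode) direct-slope controller;
- `aoloop.aberrations` — pink-noise stimuli and parametric ocular-
  aberration PSD scenarios;
- `aoloop.spectra` — PSD estimation, empirical rejection measurement,
  residual temporal error and required-loop-rate prediction.

## Worked example

```python
import numpy as np
from aoloop import (ultrafast_loop, continuous_loop, ao_bandwidth,
                    noise_propagated_rms, TimingConfig, simulate_convergence,
                    time_to_threshold)

print(ao_bandwidth(ultrafast_loop()).f_c)    # 35.015
print(ao_bandwidth(continuous_loop()).f_c)   # 28.259
print(noise_propagated_rms(0.100, ultrafast_loop(), 790.0))  # 12.788

trace = simulate_convergence(TimingConfig(), gain=1.0, initial_rms=0.35,
                             duration=0.05)
print(time_to_threshold(trace, 0.79 / 14) * 1e3)  # 4.2918
```

The first two numbers are the closed-loop bandwidths (Hz) of the
discontinuous-exposure loop (233 Hz × gain 1.0) and the continuous-exposure
loop (342 Hz × gain 0.45): although the discontinuous scheme cycles 32%
slower, its higher usable gain gives it the larger rate–gain product and
hence ~24% more bandwidth.  The third number says that 0.100 rad of
wavefront-sensing noise leaves only ~12.8 nm of residual wavefront error —
far below the λ/14 = 56 nm diffraction limit at 790 nm, so even 0.126 ms
exposures (≈2000 photons per lenslet) do not make the loop noise-limited.
The last line runs the discrete-event simulator on a static 0.35 µm
aberration: the loop confirms a diffraction-limited residual 4.29 ms after
the first exposure — one loop period.

The `examples/` directory holds short narrative scripts, one per
capability (`bandwidth_and_rejection.py`, `convergence_two_schemes.py`,
`measure_rejection_curve.py`, `shws_roundtrip.py`, `dm_modal_control.py`,
`scenario_required_rates.py`); each builds its own input, runs the method
and prints what the numbers mean.  A thin CLI mirrors the most common
calls: `aoloop bandwidth`, `aoloop rejection-curve`, `aoloop simulate-loop`,
`aoloop psd`, `aoloop required-rate`, `aoloop run <experiment>`.

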