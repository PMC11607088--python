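# Methods

This note records the models behind `aoloop`, the calibration decisions
taken where the physical system is under-determined, and what the synthetic
data can and cannot say about real instruments.

## Loop transfer model

The analytic machinery (`aoloop.control`) treats the AO loop as a sampled
integral controller with no leak.  The open-loop transfer at `s = i2πf` is
the product of four factors: exposure averaging `(1 − e^(−sT_int))/(sT_int)`,
the readout/processing delay and controller integration `e^(−sT_delay)/s`,
a DM low-pass factor, and the rate–gain product.  Two readings of the DM
factor are possible; we implement the *literal* one, `1/(1 + T_dm·f)`, a
real attenuation, because only that reading is consistent with the
`(1 + T_dm·f_c)` term of the closed-form bandwidth equation, and because it
reproduces the reference bandwidths (35.0 Hz at rate–gain 233, 28.2 Hz at
153.9) to three digits.  A conventional complex first-order pole differs
negligibly below ~100 Hz for `T_dm` = 0.55 ms.

The bandwidth solver brackets the first sign change of the transcendental
bandwidth function on a 2000-point logarithmic grid from 0.01 Hz to the
loop Nyquist frequency and refines it with Brent's method to 1e-3 Hz.  A
`unity_crossing` method does the same on `|H_reject|² − 1` directly; the two
agree to well under 0.1 Hz everywhere we test.  A delay-free loop is a pure
integrator whose rejection never reaches 1; the solver raises
`NoBandwidthError` rather than fabricating a crossing.

**Noise propagation.**  Sensing noise of σ rad is converted to residual
wavefront error as `opd(σ·κ)`, where `κ² = mean of |H_noise|²` over the
closed-loop band `(0, f_c]` (4096-point linear grid) and
`H_noise = G/(1+G)`.  Averaging over the closed-loop band (rather than to
the loop Nyquist) expresses that noise injected inside the correction band
is what the loop actually writes onto the mirror; for the ultrafast
discontinuous configuration κ = 1.02, i.e. essentially no amplification,
and 0.100 rad maps to 12.8 nm at 790 nm.

**Conventional-AO mimic.**  The slow comparison loop uses a 45 ms
integration time, 10 Hz loop rate and gain 1.  Its readout/processing delay
is not separately published for such systems; we let it fill the other half
of the 100 ms loop period (`t_delay` = 45 ms), which makes the bandwidth
equation yield 1.4 Hz — the theoretical maximum quoted for conventional
ophthalmic AO — and places the low-frequency rejection-ratio minimum
against the ultrafast loop at its asymptote (233/10)² ≈ 543.  Keeping the
ultrafast `t_delay` = 2.42 ms instead gives a 2.3 Hz bandwidth and a
mid-band ratio minimum of ~270; both readings are accessible since
`t_delay` is an ordinary field of `LoopConfig`.

## Discrete-event loop simulation

`aoloop.loopsim` simulates one scalar aberration mode per channel in
continuous time with exact first-order DM transients (no time-stepping
error).  Cycle layout for the discontinuous scheme: exposure of length
`t_integration` → readout/transfer/processing `t_readout_transfer_process`
→ trigger/software overhead → DM command write → settle window
`t_dm_settle` → `exposure_delay` → next exposure.  The measurement of each
exposure is the time-average of (input − effective DM correction) over the
exposure window, so a DM transient that leaks into the window corrupts the
measurement exactly as in hardware.

Three constants here are calibrations, not published values:

- **Trigger overhead** (0.896 ms): the printed cycle components
  (0.126 + 2.42 + 0.55 + 0.3 ms) alone imply a 294 Hz loop; the overhead is
  the single per-cycle constant that makes the discontinuous loop rate
  exactly 233 Hz.  It is placed between processing end and the DM write;
  the continuous (internal-trigger) scheme has none.
- **DM time constant** τ = `t_dm_settle`/2, i.e. the mirror reaches 86% of
  a step within its nominal settle window.  This single value makes the
  simulator reproduce all of the observed qualitative loop behaviours at
  once: the continuous scheme overshoots at gain 0.55 but not 0.45, the
  exposure-delay optimum lands at 0.3 ms, and the tracking simulation
  agrees with the analytic rejection curve to ≲16% below a quarter of the
  loop rate (empirical bandwidth ≈37 Hz against the 35 Hz analytic value —
  the same direction and size of gap as between measured and predicted
  bandwidths on hardware).
- **Overshoot floor** for the exposure-delay scan: rebounds smaller than
  the loop's own noise-propagated residual (~12.9 nm for the default
  sensing budget) are treated as zero, since a real system could not
  distinguish them from sensing noise.  On a 0.1 ms delay grid the shortest
  delay whose rebound is below that floor is 0.3 ms; shorter delays trade
  loop rate for measurable DM-transient overshoot.

The continuous scheme free-runs at the camera's 342 Hz with a one-frame
pipeline: the correction from frame *n* is written as soon as processing
finishes, 0.38 ms before frame *n+1* exposes, so each exposure sees a
partially settled mirror — the mechanism behind that scheme's lower usable
gain.  A two-frame-delay variant (`continuous_two_frame_loop`) reproduces
the strong noise amplification of astronomy-style continuous loops at
gain 1.

`simulate_tracking` replays an identical injected sequence through an open
and a closed branch, sampling both at the exposure times; the ratio of
their periodogram averages is the empirical power rejection curve.  The
first ~64 samples carry the loop lock-in transient and are discarded before
spectral estimation.

**Time stamps.**  Measurements are stamped at exposure start.  Latency is
`t_integration + t_readout_transfer_process + t_dm_settle` (3.1 ms) for
both schemes.  `time_to_threshold` reports the first measurement that
confirms the residual at or below threshold and stays there — for the
gain-1 discontinuous loop on a static aberration this is the second
exposure, one loop period (4.29 ms) after the first.

## Shack–Hartmann model

Geometry: a 20×20 array of 0.5 mm square lenslets, 13.9 mm focal length,
45×45 super-pixels per sub-aperture.  An "active" lenslet is one whose full
square aperture lies inside the pupil image.  With a 6.7 mm pupil placed
directly on the array only ~112 lenslets qualify, far short of the 300 the
sensor uses, so the model relay-magnifies the pupil to 10.35 mm at the
array (magnification ≈1.54), which yields exactly 300 fully-inside
lenslets.  Wavefronts live on the unit pupil in µm; slopes are
displacement/focal-length (dimensionless); the same sub-aperture-mean
analytic Zernike gradients drive both the forward model and the
least-squares reconstructor.

Zernike modes use the ANSI/OSA single-index ordering and are RMS-normalised
(unit variance over the pupil), so the Euclidean norm of a coefficient
vector *is* the RMS wavefront error.  The default reconstruction basis is
63 modes (radial orders 2–10, piston/tip/tilt excluded).

**Spot model.**  Focal spots are Gaussians with σ = 1.0 super-pixel
(11 µm), matching the diffraction-limited lenslet spot (FWHM λf/d ≈ 22 µm).
Photon counts are Poisson per pixel around an expected total of 1962
photons per lenslet per frame; read noise is 2 e⁻ RMS Gaussian per
super-pixel; the digital conversion is 7 DN/e⁻ clipped and quantised to
12 bits.

**TCoG centroiding** follows the four-step recipe exactly: calibration +
global-threshold subtraction; per-sub-aperture peak location (row-major tie
break); subtraction of 30% of the peak inside an 11×11 window centred on
the peak pixel (clipped at sub-aperture borders), negatives set to zero;
centre of gravity of the window.  Because the threshold is anchored to the
*discrete* peak pixel, TCoG has a small periodic bias against sub-pixel
spot position (≤0.01 px at σ = 1.0, growing to ~0.04 px at σ = 1.5) and a
photon-noise floor ~1.7× the plain CoG value σ_spot/√N; both behaviours are
properties of the algorithm, reproduced faithfully rather than patched.

**Noise budget.**  `sensing_noise_budget` converts centroid errors to the
phase difference across one lenslet pitch via
`(2π/λ)·pitch·superpixel/f`.  The photon term scales as σ_spot/√N and the
readout term as `(read_noise/N)·sqrt(Σ offsets²)` over the window; each
carries one dimensionless calibration constant (1.3934 and 0.08873) fixed
so that the defaults reproduce the reference budget of 0.100 rad photon
and 0.010 rad readout error.  The photon constant >1 reflects TCoG's
noisy-threshold excess over plain CoG; the readout constant <1 reflects
that the adaptive threshold zeroes most of the window before the CoG.
These constants are calibrations of otherwise standard formulas — the
first-principles versions of the underlying error equations are not
published.

A blink is declared when at least half of the active lenslets have spot
peaks below 700 DN (boundary inclusive); the controller then holds the DM
at the last non-blink shape.

## Deformable mirror and controller

97 actuators on an 11×11 grid cropped to a disk (rows 5-7-9-11-11-11-11-
11-9-7-5), pitch 2/11 of the pupil; influence functions are Gaussians whose
width gives 30% coupling at one pitch — a typical value for magnetic
membrane mirrors, since the real influence data is proprietary.  The
control matrix is the SVD pseudo-inverse of the slope influence matrix with
the 12 smallest-singular-value system modes removed (85 retained; 12 kept
as a default, not derived — the conditioning that motivates it is
hardware-specific).  The integral law is leakless:
`commands ← commands − gain·(C·slopes)`, clipped to command limits.  The
temporal response uses the same τ = `t_dm`/2 first-order model as the loop
simulator.

## Synthetic aberration inputs

`gen_pink_noise` synthesises 1/f sequences in the frequency domain
(amplitude ∝ f^(−1/2), uniform random phases, zero DC — the 1/f law
diverges at DC and the loop removes it anyway), rescaled to a requested
RMS.  `synthesize_series_from_psd` draws series whose one-sided PSD equals
a parametric model `A·f^(−α) + bump + floor`; synthesis is fixed-amplitude
random-phase, so the periodogram of every realization equals the model
exactly and generator/estimator round trips are sharp.  The Nyquist bin is
real-valued with a random sign at the correct one-sided power.

Scenario presets are **illustrative placeholders**: the clinical spectra
they emulate are not published as numbers.  The normal condition uses
α = 1.5 with the noise floor set so the plateau RMS σ_W = √(PSD·BW) is
23 nm over the 171 Hz bandwidth; the six clinical presets carry 10–100×
the 1 Hz amplitude with steeper decay (α = 2.0–2.5, reflecting dominance of
slow events such as blinks, lens settling and accommodation drift), and the
nystagmus preset adds a Gaussian bump at 5 Hz producing a local PSD maximum
in the 3–8 Hz band.  With these defaults the required-loop-rate machinery
predicts ~10 Hz for the normal condition and ~55–270 Hz across the
clinical presets.  Users fitting real spectra should override all four
parameters; nothing in the package depends on the preset values.

Channels are generated independently: spatial correlation between lenslets
is out of scope, which is acceptable because rejection measurement averages
PSDs across channels regardless.

## Spectral analysis

PSDs are plain (boxcar) one-sided periodograms — squared DFT magnitude
divided by the spectral resolution 1/T — averaged over channels, DC
excluded, so that the band integral equals the series variance (an optional
Hann window exists but is off by default, matching the estimation
convention the rejection measurement assumes).  The residual temporal error
is the band integral `σ² = Σ PSD(f)·|H_reject(f)|²·Δf` starting at the
lowest non-zero bin; `required_loop_rate` scans a rate grid over the loop
family in which integration fills half the loop period and
readout/processing the other half (discontinuous, gain 1), and
`diffraction_threshold_psd` inverts the same integral to scale a power-law
template so a given loop corrects it exactly to threshold.

## Problem sizes

The test suite and the acceptance script use: 2000-point log scans for
bandwidth bracketing; 4096-step, 8-channel tracking runs for empirical
rejection curves; 100 noisy frames for the sensor round trip; 50
realizations for generator/estimator consistency; 16 radial × 128 angular
quadrature nodes for Zernike orthonormality.  These sizes put sampling
error well below the tolerances being checked while keeping any single
test in seconds.

## Known limitations

- The loop simulator is modal and scalar per channel: no spatial coupling
  between sensing and correction, no aliasing of high-order spatial modes.
- No rolling-shutter row-by-row exposure model; latency uses the
  average-exposure-start abstraction.
- The DM model has no hysteresis or creep, and its Gaussian influence
  functions are synthetic.
- The analytic transfer model omits the zero-order-hold phase of the
  sampled controller, which is why simulated rejection exceeds the analytic
  curve by up to ~16% near the rejection peak — consistent with the
  hardware-vs-theory gap this class of model shows.
- Scenario presets emulate the *shape* of clinical aberration spectra, not
  any individual's data; conclusions about required loop rates transfer to
  real eyes only through user-supplied spectra.
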