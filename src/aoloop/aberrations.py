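"""Synthetic aberration inputs: pink-noise stimuli and scenario PSD models.

Two generators cover the toolkit's input needs.  ``gen_pink_noise`` makes
the pseudo-random 1/f command sequences used to measure a loop's power
rejection curve.  ``synthesize_series_from_psd`` draws wavefront time series
whose one-sided power spectral density follows a parameterised ocular-
aberration model: a power law ``amplitude * f**(-exponent)`` falling to a
noise-floor plateau, optionally with an oscillatory bump (3-8 Hz) emulating
nystagmus.  Scenario presets are illustrative defaults on the documented
10-100x scale above the normal condition; the exact spectra of the clinical
scenarios are not published, so every parameter is user-overridable.

Synthesis is fixed-amplitude random-phase: the periodogram of every
realization equals the target PSD exactly (only phases are random), which
makes generator/estimator round trips sharp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PinkNoiseSpec",
    "ScenarioPSDModel",
    "WavefrontSeries",
    "SCENARIO_PRESETS",
    "scenario_model",
    "gen_pink_noise",
    "synthesize_series_from_psd",
    "noise_floor_rms",
]


@dataclass(frozen=True)
class PinkNoiseSpec:
    """Pink-noise (PSD ~ 1/f) stimulus specification."""

    n_steps: int = 1024
    sample_rate: float = 233.0
    amplitude_rms: float = 0.1
    seed: int = 0
    n_channels: int = 1

    def __post_init__(self) -> None:
        if self.n_steps < 64:
            raise ValueError("n_steps must be >= 64")
        if self.amplitude_rms < 0:
            raise ValueError("amplitude_rms must be non-negative")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")


@dataclass(frozen=True)
class ScenarioPSDModel:
    """Parametric one-sided PSD: amplitude*f**(-exponent) + bump + floor.

    ``amplitude`` is the power-law PSD at 1 Hz (um^2/Hz); ``noise_floor`` the
    high-frequency plateau (um^2/Hz); the optional Gaussian bump models
    oscillatory eye motion.  342 Hz sampling matches high-speed wavefront
    sensing of ocular dynamics.
    """

    amplitude: float = 6e-4
    exponent: float = 1.5
    noise_floor: float = 3.1e-6
    bump_center: float = 0.0
    bump_width: float = 1.0
    bump_height: float = 0.0
    sample_rate: float = 342.0
    scenario_tag: str = "normal"

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.noise_floor < 0 or self.bump_height < 0:
            raise ValueError("PSD parameters must be non-negative")

    def psd(self, f) -> np.ndarray:
        """Model PSD (um^2/Hz) at frequencies f (Hz, positive)."""
        f = np.asarray(f, dtype=float)
        out = np.full(f.shape, self.noise_floor)
        if self.amplitude > 0:
            out = out + self.amplitude * f ** (-self.exponent)
        if self.bump_height > 0:
            out = out + self.bump_height * np.exp(
                -0.5 * ((f - self.bump_center) / self.bump_width) ** 2)
        return out


# Illustrative presets: clinically-relevant scenarios carry 10-100x the
# 1 Hz power-law amplitude of the normal (cyclopleged, steady-fixation)
# condition, with steeper decay (dominated by slow events such as blinks,
# contact-lens settling and accommodation drift).
SCENARIO_PRESETS: dict[str, ScenarioPSDModel] = {
    "normal": ScenarioPSDModel(scenario_tag="normal"),
    "no_cycloplegia": ScenarioPSDModel(amplitude=6e-3, exponent=2.0,
                                       scenario_tag="no_cycloplegia"),
    "sequential_fixation": ScenarioPSDModel(amplitude=1.2e-2, exponent=2.0,
                                            scenario_tag="sequential_fixation"),
    "artificial_tears": ScenarioPSDModel(amplitude=3.6e-2, exponent=2.2,
                                         scenario_tag="artificial_tears"),
    "myopia_cl": ScenarioPSDModel(amplitude=3.6e-2, exponent=2.5,
                                  scenario_tag="myopia_cl"),
    "keratoconus_cl": ScenarioPSDModel(amplitude=6e-2, exponent=2.2,
                                       scenario_tag="keratoconus_cl"),
    "nystagmus": ScenarioPSDModel(amplitude=1.8e-2, exponent=2.0,
                                  bump_center=5.0, bump_width=1.5,
                                  bump_height=3e-3, scenario_tag="nystagmus"),
}


def scenario_model(tag: str, **overrides) -> ScenarioPSDModel:
    """Look up a scenario preset, optionally overriding parameters."""
    try:
        model = SCENARIO_PRESETS[tag]
    except KeyError:
        raise ValueError(f"unknown scenario {tag!r}; "
                         f"choose from {sorted(SCENARIO_PRESETS)}") from None
    return replace(model, **overrides) if overrides else model


@dataclass
class WavefrontSeries:
    """Uniformly sampled multichannel wavefront time series (um)."""

    times: np.ndarray
    values: np.ndarray  # (n_channels, n_samples)
    sample_rate: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series values must be finite")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def gen_pink_noise(spec: PinkNoiseSpec) -> np.ndarray:
    """Pseudo-random pink-noise sequences, shape (n_channels, n_steps).

    Frequency-domain synthesis: spectral amplitude proportional to
    f**(-1/2) (so the PSD follows 1/f), uniform random phases, inverse
    transform, each channel rescaled to ``amplitude_rms``.  The DC bin is
    zeroed (the 1/f law diverges there and the loop removes DC anyway).
    Reproducible for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_steps
    freqs = np.fft.rfftfreq(n, 1.0 / spec.sample_rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(spec.n_channels, freqs.size))
    x = np.fft.irfft(amp * np.exp(1j * phases), n=n, axis=-1)
    if spec.amplitude_rms == 0:
        return np.zeros_like(x)
    std = x.std(axis=-1, keepdims=True)
    return x * (spec.amplitude_rms / std)


def synthesize_series_from_psd(model: ScenarioPSDModel, duration: float,
                               n_channels: int = 1, seed: int = 0) -> WavefrontSeries:
    """Draw a wavefront series whose one-sided PSD equals ``model.psd``.

    Each channel is an independent random-phase realization; the realized
    variance matches the band integral of the PSD up to discretisation.
    """
    n = int(round(duration * model.sample_rate))
    if n < 128:
        raise ValueError("duration * sample_rate must be >= 128")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, 1.0 / model.sample_rate)
    amp = np.zeros_like(freqs)
    # |X_k|^2 * 2 / (n * fs) = PSD  =>  |X_k| = sqrt(PSD * n * fs / 2)
    amp[1:] = np.sqrt(model.psd(freqs[1:]) * n * model.sample_rate / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_channels, freqs.size))
    spectrum = amp * np.exp(1j * phases)
    if n % 2 == 0:
        # the Nyquist bin must be real (its own conjugate) and carries no
        # one-sided doubling: use a random sign at the full amplitude
        spectrum[:, -1] = (amp[-1] * np.sqrt(2.0)
                           * np.sign(rng.standard_normal(n_channels)))
    values = np.fft.irfft(spectrum, n=n, axis=-1)
    times = np.arange(n) / model.sample_rate
    return WavefrontSeries(times=times, values=values,
                           sample_rate=model.sample_rate)


def noise_floor_rms(psd_noise: float, sample_rate: float) -> float:
    """Wavefront-noise RMS implied by a flat PSD plateau:
    sigma_W = sqrt(PSD_noise * BW) with BW = sample_rate / 2."""
    if psd_noise < 0:
        raise ValueError("psd_noise must be non-negative")
    return float(np.sqrt(psd_noise * sample_rate / 2.0))
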