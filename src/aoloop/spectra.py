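"""Temporal PSD estimation and loop-performance prediction.

The PSD convention is the plain (unwindowed) periodogram: squared magnitude
of the DFT of the wavefront sequence divided by the spectral resolution
(the reciprocal of the measurement duration), one-sided, averaged over
channels, with the DC bin excluded.  Under this normalisation the band
integral of the PSD equals the series variance.

From a measured/synthesised aberration spectrum PSD_eye(f) and a loop's
power rejection curve |H_reject(f)|^2, the residual temporal error is the
band integral

    sigma_temporal = sqrt( sum PSD_eye(f) * |H_reject(f)|^2 * df ),

which underlies the required-loop-rate prediction and the diffraction-limit
threshold spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

from .aberrations import WavefrontSeries
from .control import LoopConfig, RejectionCurve, fig_rate_family_loop, rejection_power_curve

__all__ = [
    "SpectrumRecord",
    "TemporalErrorResult",
    "estimate_psd",
    "measure_rejection_curve",
    "temporal_error",
    "required_loop_rate",
    "diffraction_threshold_psd",
    "RATE_NOT_FOUND",
]

RATE_NOT_FOUND = float("inf")


@dataclass
class SpectrumRecord:
    """One-sided temporal PSD (um^2/Hz) with its spectral resolution."""

    frequencies: np.ndarray
    psd: np.ndarray
    spectral_resolution: float
    n_channels_averaged: int = 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if np.any(self.psd < 0):
            raise ValueError("psd must be non-negative")


@dataclass(frozen=True)
class TemporalErrorResult:
    sigma_temporal: float
    loop_rate: float
    rejection_source: str = "analytic"


def estimate_psd(series: WavefrontSeries,
                 window: str = "boxcar") -> SpectrumRecord:
    """Channel-averaged one-sided periodogram of a wavefront series.

    Plain DFT (boxcar window) by default, density scaling, DC bin dropped;
    the spectral resolution is 1/(total measurement time).  Pass
    ``window="hann"`` for a tapered estimate when leakage matters more than
    matching the plain-DFT convention.
    """
    values = series.values
    n = values.shape[1]
    if n < 128:
        raise ValueError("need at least 128 samples")
    dt = np.diff(series.times)
    if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("series must be uniformly sampled")
    f, p = periodogram(values, fs=series.sample_rate, window=window,
                       axis=-1, scaling="density")
    return SpectrumRecord(frequencies=f[1:], psd=p[..., 1:].mean(axis=0),
                          spectral_resolution=series.sample_rate / n,
                          n_channels_averaged=values.shape[0])


def measure_rejection_curve(open_spec: SpectrumRecord,
                            closed_spec: SpectrumRecord) -> RejectionCurve:
    """Empirical power rejection: element-wise closed/open PSD ratio."""
    if (open_spec.frequencies.shape != closed_spec.frequencies.shape
            or not np.allclose(open_spec.frequencies, closed_spec.frequencies)):
        raise ValueError("open and closed spectra are on different grids")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(open_spec.psd > 0,
                         closed_spec.psd / np.where(open_spec.psd > 0,
                                                    open_spec.psd, 1.0),
                         0.0)
    return RejectionCurve(frequencies=open_spec.frequencies.copy(),
                          power_rejection=ratio)


def temporal_error(eye_spec: SpectrumRecord, rejection: RejectionCurve,
                   loop_rate: float = float("nan"),
                   rejection_source: str = "analytic") -> TemporalErrorResult:
    """Residual RMS after the loop filters the input spectrum.

    The rejection curve is interpolated onto the spectrum's bins over the
    common band (starting at the lowest non-zero bin) and the filtered PSD
    is integrated; bins outside the rejection curve's support are excluded.
    """
    f = eye_spec.frequencies
    band = (f >= rejection.frequencies[0]) & (f <= rejection.frequencies[-1])
    if not np.any(band):
        raise ValueError("no overlapping frequency support")
    h2 = np.interp(f[band], rejection.frequencies, rejection.power_rejection)
    var = float(np.sum(eye_spec.psd[band] * h2) * eye_spec.spectral_resolution)
    return TemporalErrorResult(sigma_temporal=float(np.sqrt(var)),
                               loop_rate=loop_rate,
                               rejection_source=rejection_source)


def _family_rejection(rate: float, frequencies: np.ndarray) -> RejectionCurve:
    cfg = fig_rate_family_loop(rate)
    return rejection_power_curve(cfg, frequencies)


def required_loop_rate(eye_spec: SpectrumRecord, threshold: float,
                       rate_grid) -> float:
    """Smallest loop rate in ``rate_grid`` whose residual temporal error is
    at or below ``threshold``.

    The loop family assigns half of each loop period to sensor integration
    and the other half to readout/transfer/processing (discontinuous
    exposure, gain 1).  Returns ``RATE_NOT_FOUND`` if no grid rate suffices.
    """
    rate_grid = np.asarray(rate_grid, dtype=float)
    if rate_grid.size == 0:
        raise ValueError("empty rate grid")
    if np.any(np.diff(rate_grid) <= 0):
        raise ValueError("rate grid must be increasing")
    for rate in rate_grid:
        rej = _family_rejection(rate, eye_spec.frequencies)
        res = temporal_error(eye_spec, rej, loop_rate=rate)
        if res.sigma_temporal <= threshold:
            return float(rate)
    return RATE_NOT_FOUND


def diffraction_threshold_psd(cfg: LoopConfig, template_exponent: float = 1.0,
                              threshold: float = 0.79 / 14,
                              frequencies=None) -> SpectrumRecord:
    """Power-law input spectrum that the given loop can barely correct.

    A template f**(-exponent) spectrum is scaled so that its residual after
    filtering by the loop's rejection curve equals ``threshold`` exactly;
    spectra below this curve are corrected to better than the threshold.
    """
    if frequencies is None:
        # 5-second measurement at 342 Hz convention: 0.2 Hz resolution
        frequencies = np.arange(1, 856) * 0.2
    frequencies = np.asarray(frequencies, dtype=float)
    df = frequencies[1] - frequencies[0]
    template = frequencies ** (-template_exponent)
    rej = rejection_power_curve(cfg, frequencies)
    var_unit = float(np.sum(template * rej.power_rejection) * df)
    scale = threshold ** 2 / var_unit
    return SpectrumRecord(frequencies=frequencies, psd=scale * template,
                          spectral_resolution=df)
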