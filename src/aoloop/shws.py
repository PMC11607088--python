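"""Shack-Hartmann wavefront sensor: forward model, centroiding, reconstruction.

The sensor is a 20x20 square microlens array (0.5 mm pitch, 13.9 mm focal
length) onto which the eye pupil is relay-imaged; 300 lenslets fall fully
inside the pupil image.  Each sub-aperture is sampled by 45x45 super-pixels
(2x2-binned camera pixels).  Centroids are computed with a two-step
thresholding centre-of-gravity (TCoG) method: calibration + global threshold
subtraction, per-sub-aperture peak location, adaptive threshold of 30% of the
peak within an 11x11 super-pixel window, then centre of gravity of that
window.  Wavefronts are reconstructed from slopes by least squares on the
analytic sub-aperture-mean gradients of an RMS-normalised Zernike basis.

Coordinates are 0-based, x rightward, y downward; a positive centroid
displacement corresponds to a positive local wavefront slope on the same
axis.  Displacement sign ties to slope via spot displacement =
focal_length * slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .optics import ZernikeBasis, WavefrontState

__all__ = [
    "LensletGeometry",
    "SensorConfig",
    "SensorFrame",
    "SlopeSet",
    "NoiseBudget",
    "render_frame",
    "render_calibration_frame",
    "centroid_tcog",
    "detect_blink",
    "reconstruct_wavefront",
    "sensing_noise_budget",
    "save_frame",
    "load_frame",
    "save_slopes",
]

# Calibration constants of the noise-budget formulas (see sensing_noise_budget)
K_PHOTON_CAL = 1.3934
K_READ_CAL = 0.08873


@dataclass(frozen=True)
class LensletGeometry:
    """Microlens array and pupil-image geometry (lengths in mm)."""

    grid: tuple = (20, 20)
    pitch_mm: float = 0.5
    focal_length_mm: float = 13.9
    pupil_diameter_at_array_mm: float = 10.35
    superpixels_per_subaperture: int = 45

    @property
    def superpixel_um(self) -> float:
        return self.pitch_mm * 1000.0 / self.superpixels_per_subaperture

    @property
    def pupil_radius_mm(self) -> float:
        return self.pupil_diameter_at_array_mm / 2.0

    def lenslet_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centres of every lenslet relative to the array centre."""
        ny, nx = self.grid
        cx = (np.arange(nx) - (nx - 1) / 2.0) * self.pitch_mm
        cy = (np.arange(ny) - (ny - 1) / 2.0) * self.pitch_mm
        return np.meshgrid(cx, cy)

    @property
    def active_mask(self) -> np.ndarray:
        """Lenslets whose square aperture lies fully inside the pupil image."""
        x, y = self.lenslet_centers_mm()
        half = self.pitch_mm / 2.0
        corner = np.hypot(np.abs(x) + half, np.abs(y) + half)
        return corner <= self.pupil_radius_mm

    @property
    def n_active(self) -> int:
        return int(self.active_mask.sum())

    def subaperture_sample_points(self, n_sub: int = 5):
        """Unit-pupil (u, v) sample grids, one (n_sub*n_sub) set per active
        lenslet, for sub-aperture-mean gradient evaluation."""
        x, y = self.lenslet_centers_mm()
        mask = self.active_mask
        offs = (np.arange(n_sub) + 0.5) / n_sub - 0.5  # fractions of a pitch
        du, dv = np.meshgrid(offs * self.pitch_mm, offs * self.pitch_mm)
        u = (x[mask][:, None] + du.ravel()[None, :]) / self.pupil_radius_mm
        v = (y[mask][:, None] + dv.ravel()[None, :]) / self.pupil_radius_mm
        return u, v


@dataclass(frozen=True)
class SensorConfig:
    """Camera/illumination/processing parameters."""

    integration_time: float = 0.126e-3
    photons_per_lenslet: float = 1962.0
    read_noise_e: float = 2.0
    bit_depth: int = 12
    camera_gain_dn_per_e: float = 7.0
    global_threshold: float = 10.0
    adaptive_fraction: float = 0.30
    window_superpixels: int = 11
    blink_peak_threshold: float = 700.0
    blink_fraction: float = 0.5
    spot_sigma: float = 1.0
    wavelength_um: float = 0.79

    def __post_init__(self) -> None:
        if not 0 < self.adaptive_fraction < 1:
            raise ValueError("adaptive_fraction must be in (0, 1)")
        if self.window_superpixels % 2 == 0:
            raise ValueError("window_superpixels must be odd")


@dataclass
class SensorFrame:
    """Super-pixel-resolution sensor image (integer DN)."""

    pixels: np.ndarray
    timestamp: float = 0.0


@dataclass
class SlopeSet:
    """Per-lenslet centroid displacements and slopes (active lenslets only)."""

    rows: np.ndarray
    cols: np.ndarray
    dx_px: np.ndarray
    dy_px: np.ndarray
    slopes_x: np.ndarray  # dimensionless (displacement / focal length)
    slopes_y: np.ndarray
    valid: np.ndarray
    peak_intensities: np.ndarray


@dataclass(frozen=True)
class NoiseBudget:
    """Wavefront sensing error budget in phase radians."""

    sigma_photon: float
    sigma_readout: float

    @property
    def sigma_total(self) -> float:
        return float(np.hypot(self.sigma_photon, self.sigma_readout))


def _mean_gradients(state_or_coeffs, basis: ZernikeBasis,
                    geom: LensletGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Sub-aperture-mean wavefront gradients (um per unit-pupil coordinate)
    per active lenslet for each basis mode: arrays (n_modes, n_active)."""
    u, v = geom.subaperture_sample_points()
    gx, gy = basis.gradients(u.ravel(), v.ravel())
    shape = (basis.mode_count,) + u.shape
    return gx.reshape(shape).mean(axis=-1), gy.reshape(shape).mean(axis=-1)


def _slope_unit_per_um_coeff(geom: LensletGeometry) -> float:
    """Dimensionless physical slope per (um gradient / unit-pupil coord)."""
    return 1e-3 / geom.pupil_radius_mm  # um/mm -> dimensionless


def render_frame(state: WavefrontState, basis: ZernikeBasis,
                 geom: LensletGeometry, cfg: SensorConfig, seed: int = 0,
                 add_noise: bool = True) -> SensorFrame:
    """Render a synthetic sensor frame for a given wavefront.

    Each active lenslet receives a Gaussian focal spot displaced by
    focal_length x (sub-aperture-mean wavefront slope), with Poisson photon
    statistics, Gaussian read noise, and 12-bit quantisation.  Deterministic
    for a given seed; ``add_noise=False`` renders the noise-free expectation.
    """
    if len(state.coefficients) != basis.mode_count:
        raise ValueError("wavefront coefficient length does not match basis")
    rng = np.random.default_rng(seed)
    n_spx = geom.superpixels_per_subaperture
    ny, nx = geom.grid
    img = np.zeros((ny * n_spx, nx * n_spx))

    gx, gy = _mean_gradients(state, basis, geom)
    to_slope = _slope_unit_per_um_coeff(geom)
    slopes_x = (state.coefficients @ gx) * to_slope
    slopes_y = (state.coefficients @ gy) * to_slope
    disp_px_x = slopes_x * geom.focal_length_mm * 1000.0 / geom.superpixel_um
    disp_px_y = slopes_y * geom.focal_length_mm * 1000.0 / geom.superpixel_um

    centre = (n_spx - 1) / 2.0
    pix = np.arange(n_spx)
    mask = geom.active_mask
    lens_rows, lens_cols = np.nonzero(mask)
    for k, (i, j) in enumerate(zip(lens_rows, lens_cols)):
        mx = centre + disp_px_x[k]
        my = centre + disp_px_y[k]
        profile = (np.exp(-0.5 * ((pix[:, None] - my) / cfg.spot_sigma) ** 2)
                   * np.exp(-0.5 * ((pix[None, :] - mx) / cfg.spot_sigma) ** 2))
        profile /= profile.sum()
        lam = cfg.photons_per_lenslet * profile
        electrons = rng.poisson(lam) if add_noise else lam
        img[i * n_spx:(i + 1) * n_spx, j * n_spx:(j + 1) * n_spx] = electrons

    dn = img * cfg.camera_gain_dn_per_e
    if add_noise:
        dn = dn + rng.normal(0.0, cfg.read_noise_e * cfg.camera_gain_dn_per_e,
                             size=dn.shape)
    dn = np.clip(np.rint(dn), 0, 2 ** cfg.bit_depth - 1).astype(np.int32)
    return SensorFrame(pixels=dn, timestamp=state.timestamp)


def render_calibration_frame(geom: LensletGeometry, cfg: SensorConfig) -> SensorFrame:
    """Dark calibration image (fixed-pattern reference, here identically zero)."""
    n_spx = geom.superpixels_per_subaperture
    ny, nx = geom.grid
    return SensorFrame(pixels=np.zeros((ny * n_spx, nx * n_spx), dtype=np.int32))


def centroid_tcog(frame: SensorFrame, geom: LensletGeometry, cfg: SensorConfig,
                  calibration: SensorFrame) -> SlopeSet:
    """Two-step thresholding centre-of-gravity centroiding.

    Steps, in order: (1) subtract the calibration image plus the global
    threshold; (2) locate the highest-intensity super-pixel of each active
    sub-aperture (ties broken by first occurrence in row-major order);
    (3) inside the 11x11 window centred on that pixel (clipped at
    sub-aperture borders), subtract 30% of the peak value and clip negatives
    to zero; (4) the centre of gravity of the window is the spot centroid.
    Displacements are measured from the sub-aperture reference centre;
    slopes are displacement / focal length.  A sub-aperture that is all zero
    after thresholding is marked invalid.
    """
    if frame.pixels.shape != calibration.pixels.shape:
        raise ValueError("calibration frame shape mismatch")
    work = frame.pixels.astype(float) - calibration.pixels.astype(float) - cfg.global_threshold
    n_spx = geom.superpixels_per_subaperture
    centre = (n_spx - 1) / 2.0
    half_w = cfg.window_superpixels // 2
    lens_rows, lens_cols = np.nonzero(geom.active_mask)
    n = len(lens_rows)
    dx = np.zeros(n)
    dy = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    peaks = np.zeros(n)
    xg, yg = np.meshgrid(np.arange(n_spx, dtype=float),
                         np.arange(n_spx, dtype=float))
    for k, (i, j) in enumerate(zip(lens_rows, lens_cols)):
        tile = work[i * n_spx:(i + 1) * n_spx, j * n_spx:(j + 1) * n_spx]
        flat = int(np.argmax(tile))
        py, px = divmod(flat, n_spx)
        peak = tile[py, px]
        peaks[k] = peak
        if peak <= 0:
            valid[k] = False
            continue
        y0, y1 = max(0, py - half_w), min(n_spx, py + half_w + 1)
        x0, x1 = max(0, px - half_w), min(n_spx, px + half_w + 1)
        win = tile[y0:y1, x0:x1] - cfg.adaptive_fraction * peak
        win = np.clip(win, 0.0, None)
        total = win.sum()
        if total <= 0:
            valid[k] = False
            continue
        cx = (win * xg[y0:y1, x0:x1]).sum() / total
        cy = (win * yg[y0:y1, x0:x1]).sum() / total
        dx[k] = cx - centre
        dy[k] = cy - centre
    disp_um_x = dx * geom.superpixel_um
    disp_um_y = dy * geom.superpixel_um
    f_um = geom.focal_length_mm * 1000.0
    return SlopeSet(rows=lens_rows, cols=lens_cols, dx_px=dx, dy_px=dy,
                    slopes_x=disp_um_x / f_um, slopes_y=disp_um_y / f_um,
                    valid=valid, peak_intensities=peaks)


def detect_blink(slopes: SlopeSet, cfg: SensorConfig) -> bool:
    """Blink rule: at least ``blink_fraction`` of the active lenslets have
    spot peak intensities below ``blink_peak_threshold`` (boundary counts
    as a blink)."""
    frac_dim = float(np.mean(slopes.peak_intensities < cfg.blink_peak_threshold))
    return frac_dim >= cfg.blink_fraction


def reconstruct_wavefront(slopes: SlopeSet, basis: ZernikeBasis,
                          geom: LensletGeometry,
                          timestamp: float = 0.0) -> WavefrontState:
    """Least-squares modal reconstruction from measured slopes.

    Fits the analytic sub-aperture-mean Zernike gradients to the valid
    measured slopes; coefficients come out in um on the RMS-normalised
    basis, so the coefficient norm is the RMS wavefront error.
    """
    gx, gy = _mean_gradients(None, basis, geom)
    to_slope = _slope_unit_per_um_coeff(geom)
    v = slopes.valid
    n_meas = 2 * int(v.sum())
    if n_meas < 2 * basis.mode_count:
        raise ValueError(
            f"need at least {2 * basis.mode_count} valid slope measurements, "
            f"got {n_meas}")
    design = np.concatenate([gx[:, v], gy[:, v]], axis=1).T * to_slope
    target = np.concatenate([slopes.slopes_x[v], slopes.slopes_y[v]])
    coeffs, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < basis.mode_count:
        raise np.linalg.LinAlgError("slope system is rank deficient")
    return WavefrontState(coefficients=coeffs, timestamp=timestamp)


def sensing_noise_budget(cfg: SensorConfig, geom: LensletGeometry) -> NoiseBudget:
    """Photon-shot and camera-readout wavefront sensing errors (rad).

    Standard centre-of-gravity error propagation: the photon-limited
    centroid error is spot_sigma/sqrt(N) super-pixels and the read-noise
    contribution is (read_noise/N) * sqrt(sum of squared pixel offsets over
    the window); both are converted to the phase difference across one
    lenslet pitch via (2*pi/lambda) * pitch * superpixel / focal_length.
    The two dimensionless prefactors are calibrated so that the defaults
    (1962 photons, 2 e-) reproduce 0.100 rad and 0.010 rad; the read-noise
    constant absorbs the window truncation by the adaptive threshold.
    """
    n = cfg.photons_per_lenslet
    if n <= 0:
        raise ValueError("photons_per_lenslet must be positive")
    chain = (2.0 * np.pi / cfg.wavelength_um) * (
        geom.pitch_mm * 1000.0 * geom.superpixel_um
        / (geom.focal_length_mm * 1000.0))
    sigma_photon = K_PHOTON_CAL * chain * cfg.spot_sigma / np.sqrt(n)
    w = cfg.window_superpixels
    sum_sq = w ** 2 * (w ** 2 - 1) / 12.0
    sigma_read = K_READ_CAL * chain * (cfg.read_noise_e / n) * np.sqrt(sum_sq)
    return NoiseBudget(sigma_photon=float(sigma_photon),
                       sigma_readout=float(sigma_read))


def save_frame(path, frame: SensorFrame) -> None:
    tifffile.imwrite(path, frame.pixels.astype(np.uint16))


def load_frame(path, timestamp: float = 0.0) -> SensorFrame:
    return SensorFrame(pixels=tifffile.imread(path).astype(np.int32),
                       timestamp=timestamp)


def save_slopes(path, slopes: SlopeSet) -> None:
    pd.DataFrame({
        "lenslet_row": slopes.rows, "lenslet_col": slopes.cols,
        "dx_px": slopes.dx_px, "dy_px": slopes.dy_px,
        "slope_x": slopes.slopes_x, "slope_y": slopes.slopes_y,
        "peak": slopes.peak_intensities, "valid": slopes.valid,
    }).to_csv(path, index=False)
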