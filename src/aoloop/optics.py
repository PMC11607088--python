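"""Pupil/wavefront representation, Zernike basis, and closed-form optical metrics.

Lengths are micrometres unless a name says otherwise.  Zernike modes follow
the ANSI/OSA single-index convention and are RMS-normalised (unit variance
over the unit pupil), so the Euclidean norm of a coefficient vector equals
the RMS wavefront error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "OpticalConfig",
    "ZernikeBasis",
    "WavefrontState",
    "build_zernike_basis",
    "evaluate_wavefront",
    "pupil_grid",
    "diffraction_limit_rms",
    "strehl_from_rms",
    "resolution_metrics",
    "phase_to_opd",
    "save_wavefront_map",
    "save_coefficients",
    "load_coefficients",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Source and eye-model parameters.

    Attributes
    ----------
    wavelength_um : central imaging/sensing wavelength (default 0.790 um).
    source_bandwidth_um : FWHM spectral bandwidth (default 42 nm).
    pupil_diameter_um : eye pupil diameter sampled by the system (6.7 mm).
    eye_focal_length_um : reduced-eye focal length (16.67 mm).
    tissue_index : refractive index of retinal tissue (1.38).
    vitreous_index : refractive index of the reduced eye (1.336).
    """

    wavelength_um: float = 0.790
    source_bandwidth_um: float = 0.042
    pupil_diameter_um: float = 6700.0
    eye_focal_length_um: float = 16670.0
    tissue_index: float = 1.38
    vitreous_index: float = 1.336

    def __post_init__(self) -> None:
        for name in ("wavelength_um", "source_bandwidth_um",
                     "pupil_diameter_um", "eye_focal_length_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tissue_index < 1 or self.vitreous_index < 1:
            raise ValueError("refractive indices must be >= 1")


def _radial_coeffs(n: int, m: int) -> np.ndarray:
    """Coefficients of rho**(n-2k) in the radial polynomial R_n^m."""
    coeffs = np.zeros(n + 1)
    for k in range((n - m) // 2 + 1):
        c = ((-1) ** k * math.factorial(n - k)
             / (math.factorial(k)
                * math.factorial((n + m) // 2 - k)
                * math.factorial((n - m) // 2 - k)))
        coeffs[n - 2 * k] = c
    return coeffs


@dataclass(frozen=True)
class ZernikeBasis:
    """ANSI/OSA-ordered, RMS-normalised Zernike basis on the unit pupil."""

    max_radial_order: int
    exclude_piston_tip_tilt: bool = True
    ordering: str = "ansi"
    nm_pairs: tuple = field(default=(), repr=False)

    @property
    def mode_count(self) -> int:
        return len(self.nm_pairs)

    def _norm(self, n: int, m: int) -> float:
        return math.sqrt(n + 1) if m == 0 else math.sqrt(2 * (n + 1))

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Evaluate every mode at (x, y); returns (mode_count, ...) array."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rho = np.hypot(x, y)
        theta = np.arctan2(y, x)
        out = np.empty((self.mode_count,) + rho.shape)
        powers = rho[None] ** np.arange(self.max_radial_order + 1).reshape(
            (-1,) + (1,) * rho.ndim)
        for i, (n, m) in enumerate(self.nm_pairs):
            coeffs = _radial_coeffs(n, abs(m))
            radial = np.tensordot(coeffs, powers[: n + 1], axes=(0, 0))
            if m == 0:
                ang = 1.0
            elif m > 0:
                ang = np.cos(m * theta)
            else:
                ang = np.sin(-m * theta)
            out[i] = self._norm(n, m) * radial * ang
        return out

    def gradients(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Analytic Cartesian gradients of every mode at (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rho = np.maximum(np.hypot(x, y), 1e-12)
        theta = np.arctan2(y, x)
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        dzdx = np.empty((self.mode_count,) + rho.shape)
        dzdy = np.empty_like(dzdx)
        nmax = self.max_radial_order
        powers = rho[None] ** np.arange(nmax + 1).reshape((-1,) + (1,) * rho.ndim)
        for i, (n, m) in enumerate(self.nm_pairs):
            coeffs = _radial_coeffs(n, abs(m))
            dcoeffs = coeffs * np.arange(n + 1)
            radial = np.tensordot(coeffs, powers[: n + 1], axes=(0, 0))
            # d/drho: sum c_k * k * rho**(k-1)
            dradial = np.tensordot(dcoeffs[1:], powers[: n], axes=(0, 0))
            norm = self._norm(n, m)
            ma = abs(m)
            if m == 0:
                ang, dang = 1.0, 0.0
            elif m > 0:
                ang, dang = np.cos(ma * theta), -ma * np.sin(ma * theta)
            else:
                ang, dang = np.sin(ma * theta), ma * np.cos(ma * theta)
            dz_drho = norm * dradial * ang
            dz_dtheta_over_rho = norm * (radial / rho) * dang
            dzdx[i] = cos_t * dz_drho - sin_t * dz_dtheta_over_rho
            dzdy[i] = sin_t * dz_drho + cos_t * dz_dtheta_over_rho
        return dzdx, dzdy


def build_zernike_basis(max_radial_order: int = 10,
                        exclude_piston_tip_tilt: bool = True) -> ZernikeBasis:
    """Build the ANSI/OSA Zernike basis up to ``max_radial_order``.

    With piston, tip and tilt excluded and order 10, the basis has 63 modes,
    the set used for real-time wavefront reconstruction and RMS monitoring.
    """
    if max_radial_order < 1:
        raise ValueError("max_radial_order must be >= 1")
    pairs = []
    for n in range(max_radial_order + 1):
        for m in range(-n, n + 1, 2):
            if exclude_piston_tip_tilt and n <= 1:
                continue
            pairs.append((n, m))
    return ZernikeBasis(max_radial_order=max_radial_order,
                        exclude_piston_tip_tilt=exclude_piston_tip_tilt,
                        nm_pairs=tuple(pairs))


@dataclass
class WavefrontState:
    """Zernike coefficient vector (um, RMS-normalised modes) at a time stamp."""

    coefficients: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)

    @property
    def rms(self) -> float:
        """RMS wavefront error in um (norm of the coefficient vector)."""
        return float(np.linalg.norm(self.coefficients))


def pupil_grid(resolution: int = 256) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-disk sampling grid: (x, y, inside-mask) at pixel centres."""
    c = (np.arange(resolution) + 0.5) / resolution * 2.0 - 1.0
    x, y = np.meshgrid(c, c)
    return x, y, x * x + y * y <= 1.0


def evaluate_wavefront(basis: ZernikeBasis, state: WavefrontState,
                       grid_resolution: int = 256) -> np.ndarray:
    """Render the wavefront map (um) on the unit pupil; NaN outside the disk."""
    if len(state.coefficients) != basis.mode_count:
        raise ValueError(
            f"coefficient length {len(state.coefficients)} does not match "
            f"basis mode count {basis.mode_count}")
    x, y, mask = pupil_grid(grid_resolution)
    modes = basis.evaluate(x[mask], y[mask])
    wf = np.full(mask.shape, np.nan)
    wf[mask] = state.coefficients @ modes
    return wf


def diffraction_limit_rms(cfg: OpticalConfig) -> float:
    """Marechal diffraction-limit criterion on RMS wavefront error: lambda/14."""
    return cfg.wavelength_um / 14.0


def strehl_from_rms(rms_um: float, wavelength_um: float) -> float:
    """Extended Marechal approximation S = exp(-(2*pi*sigma/lambda)**2)."""
    if rms_um < 0:
        raise ValueError("rms must be non-negative")
    return math.exp(-((2.0 * math.pi * rms_um / wavelength_um) ** 2))


def resolution_metrics(cfg: OpticalConfig) -> dict:
    """Closed-form resolution/defocus metrics for the reduced-eye model.

    Returns lateral Rayleigh resolution 1.22*lambda*f/D, coherence-gated
    axial resolution (2 ln2/pi)*lambda^2/(d_lambda*n_tissue), and the axial
    focal shift per dioptre of defocus n_vitreous*f^2 (all in um).
    """
    if cfg.pupil_diameter_um <= 0:
        raise ValueError("pupil diameter must be positive")
    lateral = 1.22 * cfg.wavelength_um * cfg.eye_focal_length_um / cfg.pupil_diameter_um
    axial = (2.0 * math.log(2.0) / math.pi) * cfg.wavelength_um ** 2 / (
        cfg.source_bandwidth_um * cfg.tissue_index)
    f_m = cfg.eye_focal_length_um * 1e-6
    microns_per_diopter = cfg.vitreous_index * f_m ** 2 * 1e6
    return {"lateral_um": lateral, "axial_um": axial,
            "microns_per_diopter": microns_per_diopter}


def phase_to_opd(phase_rad: float, wavelength: float) -> float:
    """Convert phase (rad) to optical path length, in the units of wavelength."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return phase_rad * wavelength / (2.0 * math.pi)


def save_wavefront_map(path, wavefront_map: np.ndarray) -> None:
    """Write a wavefront map as 32-bit float TIFF."""
    tifffile.imwrite(path, wavefront_map.astype(np.float32))


def save_coefficients(path, state: WavefrontState) -> None:
    pd.DataFrame({"mode_index": np.arange(len(state.coefficients)),
                  "coefficient_um": state.coefficients}).to_csv(path, index=False)


def load_coefficients(path) -> WavefrontState:
    df = pd.read_csv(path)
    return WavefrontState(coefficients=df["coefficient_um"].to_numpy())
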