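"""Deformable mirror model and direct-slope modal controller.

The mirror is a 97-actuator device laid out on an 11x11 square grid cropped
to a disk, with synthetic Gaussian influence functions whose width gives
~30% nearest-neighbour coupling (typical for magnetic membrane mirrors).
Control uses the direct-slope method: the slope response to unit pokes of
every actuator (the influence matrix) is inverted by truncated SVD, dropping
the most poorly sensed system modes, and commands are accumulated by a
leakless integral law.  During a blink the mirror holds the shape from the
last non-blink frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .loopsim import DM_TAU_RATIO
from .shws import LensletGeometry

__all__ = [
    "DMConfig",
    "ControlMatrix",
    "DMState",
    "actuator_layout_97",
    "build_influence_matrix",
    "build_control_matrix",
    "control_update",
    "dm_response",
    "save_matrix_h5",
    "load_matrix_h5",
    "save_commands",
]


def actuator_layout_97() -> np.ndarray:
    """(97, 2) actuator positions in unit-pupil coordinates.

    11x11 grid at pitch 2/11 of the pupil diameter, cropped to the disk of
    radius sqrt(29) grid units, which keeps exactly 97 actuators (rows of
    5, 7, 9, 11, 11, 11, 11, 11, 9, 7, 5).
    """
    idx = np.arange(-5, 6)
    gx, gy = np.meshgrid(idx, idx)
    keep = gx ** 2 + gy ** 2 <= 29
    pitch = 2.0 / 11.0
    return np.column_stack([gx[keep] * pitch, gy[keep] * pitch])


@dataclass(frozen=True)
class DMConfig:
    """Mirror geometry and dynamics."""

    n_actuators: int = 97
    actuator_positions: np.ndarray = field(
        default_factory=actuator_layout_97, repr=False)
    coupling: float = 0.30
    t_dm: float = 0.55e-3
    command_limits: tuple = (-5.0, 5.0)

    def __post_init__(self) -> None:
        if self.n_actuators < 1:
            raise ValueError("n_actuators must be >= 1")
        if len(self.actuator_positions) != self.n_actuators:
            raise ValueError("actuator_positions length must equal n_actuators")
        if not 0 < self.coupling < 1:
            raise ValueError("coupling must be in (0, 1)")

    @property
    def actuator_pitch(self) -> float:
        return 2.0 / 11.0

    @property
    def influence_sigma(self) -> float:
        """Gaussian width giving ``coupling`` at one actuator pitch."""
        return self.actuator_pitch / np.sqrt(2.0 * np.log(1.0 / self.coupling))

    @property
    def tau(self) -> float:
        """First-order response time constant derived from t_dm."""
        return DM_TAU_RATIO * self.t_dm


@dataclass
class ControlMatrix:
    """SVD-truncated pseudo-inverse mapping slopes to commands."""

    matrix: np.ndarray  # (n_actuators, n_slopes)
    retained_modes: int
    dropped_modes: int
    singular_values: np.ndarray = field(default=None, repr=False)


@dataclass
class DMState:
    """Command vector with the previous shape kept for the settle transient."""

    commands: np.ndarray
    previous_commands: np.ndarray
    last_update_time: float = 0.0
    held_for_blink: bool = False


def build_influence_matrix(dm: DMConfig, geom: LensletGeometry) -> np.ndarray:
    """Slope response (2 * n_active_lenslets, n_actuators) to unit pokes.

    Influence functions are Gaussians in unit-pupil coordinates; column j is
    the x- then y-slope response of every active lenslet to a unit command
    on actuator j, using the same sub-aperture-mean gradient convention and
    units as the reconstructor (commands in um of wavefront, slopes
    dimensionless).
    """
    u, v = geom.subaperture_sample_points()  # (n_active, n_sub^2)
    sig2 = dm.influence_sigma ** 2
    pos = dm.actuator_positions
    du = u[..., None] - pos[None, None, :, 0]
    dv = v[..., None] - pos[None, None, :, 1]
    g = np.exp(-(du ** 2 + dv ** 2) / (2.0 * sig2))
    gx = (-du / sig2) * g
    gy = (-dv / sig2) * g
    to_slope = 1e-3 / geom.pupil_radius_mm
    slopes_x = gx.mean(axis=1) * to_slope  # (n_active, n_act)
    slopes_y = gy.mean(axis=1) * to_slope
    return np.concatenate([slopes_x, slopes_y], axis=0)


def build_control_matrix(influence: np.ndarray, n_drop: int = 12) -> ControlMatrix:
    """Truncated pseudo-inverse of the influence matrix.

    Performs an SVD and removes the ``n_drop`` system modes with the
    smallest singular values; with the 97-actuator default this retains 85
    controlled modes.
    """
    n_act = influence.shape[1]
    if n_drop >= n_act:
        raise ValueError("n_drop must be smaller than the number of actuators")
    u, s, vt = np.linalg.svd(influence, full_matrices=False)
    keep = n_act - n_drop
    inv_s = np.zeros_like(s)
    inv_s[:keep] = 1.0 / s[:keep]
    ctrl = (vt.T * inv_s) @ u.T
    return ControlMatrix(matrix=ctrl, retained_modes=keep, dropped_modes=n_drop,
                         singular_values=s)


def control_update(state: DMState, slope_vector: np.ndarray,
                   ctrl: ControlMatrix, gain: float, blink: bool,
                   limits: tuple = (-5.0, 5.0),
                   t: float = 0.0) -> DMState:
    """Leakless integral control step: commands -= gain * (C @ slopes).

    During a blink the commands are held unchanged and the state is flagged.
    Commands are clipped to ``limits``.
    """
    if blink:
        return DMState(commands=state.commands.copy(),
                       previous_commands=state.previous_commands.copy(),
                       last_update_time=state.last_update_time,
                       held_for_blink=True)
    slope_vector = np.asarray(slope_vector, dtype=float)
    if slope_vector.shape[0] != ctrl.matrix.shape[1]:
        raise ValueError("slope vector dimension does not match control matrix")
    new = state.commands - gain * (ctrl.matrix @ slope_vector)
    new = np.clip(new, limits[0], limits[1])
    return DMState(commands=new, previous_commands=state.commands.copy(),
                   last_update_time=t, held_for_blink=False)


def dm_response(state: DMState, t_since_update: float, dm: DMConfig) -> np.ndarray:
    """Effective actuator vector during the first-order settle transient:
    previous + (commands - previous) * (1 - exp(-t/tau))."""
    if t_since_update < 0:
        raise ValueError("t_since_update must be non-negative")
    frac = 1.0 - np.exp(-t_since_update / dm.tau)
    return state.previous_commands + (state.commands - state.previous_commands) * frac


def save_matrix_h5(path, name: str, matrix: np.ndarray) -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        f.create_dataset(name, data=matrix)


def load_matrix_h5(path, name: str) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f[name][()]


def save_commands(path, commands: np.ndarray) -> None:
    pd.DataFrame({"actuator_index": np.arange(len(commands)),
                  "value": commands}).to_csv(path, index=False)
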