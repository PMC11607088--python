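"""Discrete-event simulation of the two AO operational schemes.

In the continuous-exposure scheme the wavefront-sensor camera free-runs at
its maximum frame rate; corrections computed from frame n are applied to the
DM as soon as processing completes, i.e. while the camera is already exposing
subsequent frames (one-frame pipeline).  In the discontinuous-exposure scheme
each exposure is triggered only after the previous correction has been
processed, written to the DM and allowed to settle, plus a programmable
exposure delay.  Both schemes share the same latency (integration + readout/
processing + DM settle) but differ in loop rate and in the usable loop gain.

Cycle layout (discontinuous): exposure [t0, t0+T_int] -> readout/transfer/
processing T_delay -> trigger/dispatch overhead -> DM command written ->
DM settle window t_dm_settle -> exposure_delay -> next exposure.  The DM is
modelled as a first-order lag with time constant tau = t_dm_settle/2, so a
short exposure delay leaves a measurable tail of the DM transient in the
next exposure; lengthening the delay suppresses that tail at the cost of
loop rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .aberrations import WavefrontSeries

__all__ = [
    "TimingConfig",
    "LoopTrace",
    "DM_TAU_RATIO",
    "TRIGGER_OVERHEAD_DEFAULT",
    "derive_timing",
    "simulate_convergence",
    "time_to_threshold",
    "loop_overshoot",
    "scan_exposure_delay",
    "simulate_tracking",
    "NOT_REACHED",
]

#: first-order DM time constant as a fraction of the nominal settle window
DM_TAU_RATIO = 0.5

#: per-cycle trigger/software overhead calibrated so that the default
#: discontinuous component times (0.126 + 2.42 + 0.55 + 0.3 ms) yield a
#: loop rate of exactly 233 Hz
TRIGGER_OVERHEAD_DEFAULT = 1.0 / 233.0 - (0.126e-3 + 2.42e-3 + 0.55e-3 + 0.3e-3)

#: sentinel returned by time_to_threshold when the threshold is never held
NOT_REACHED = math.inf


@dataclass(frozen=True)
class TimingConfig:
    """Loop timing parameters (seconds, Hz)."""

    scheme: str = "discontinuous"
    t_integration: float = 0.126e-3
    t_readout_transfer_process: float = 2.42e-3
    t_dm_settle: float = 0.55e-3
    exposure_delay: float = 0.3e-3
    trigger_overhead: float = TRIGGER_OVERHEAD_DEFAULT
    camera_max_rate: float = 342.0

    def __post_init__(self) -> None:
        for name in ("t_integration", "t_readout_transfer_process",
                     "t_dm_settle", "exposure_delay", "trigger_overhead"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.scheme not in ("continuous", "discontinuous"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def dm_tau(self) -> float:
        return DM_TAU_RATIO * self.t_dm_settle


@dataclass
class LoopTrace:
    """Record of one closed-loop run.

    ``residual_rms`` holds the wavefront error measured by each exposure,
    time-stamped at the exposure start (``measurement_times``);
    ``signed_residual`` keeps the sign so that overshoot past zero is
    visible.  ``update_times`` are the instants control voltages were sent
    to the DM.
    """

    measurement_times: np.ndarray
    residual_rms: np.ndarray
    signed_residual: np.ndarray
    update_times: np.ndarray
    events: list = field(default_factory=list)
    diverged: bool = False


class _FirstOrderDM:
    """Vectorised first-order-lag DM command state."""

    def __init__(self, n_channels: int, tau: float):
        self.tau = tau
        self.cmd = np.zeros(n_channels)
        self.start = np.zeros(n_channels)
        self.t_update = -np.inf

    def value(self, t: float) -> np.ndarray:
        if self.tau == 0:
            return self.cmd
        return self.cmd + (self.start - self.cmd) * np.exp(
            -(t - self.t_update) / self.tau)

    def window_mean(self, a: float, b: float) -> np.ndarray:
        """Time-average of the effective command over [a, b], a >= t_update."""
        if self.tau == 0 or b == a:
            return self.value(a)
        w = (self.tau / (b - a)) * (np.exp(-(a - self.t_update) / self.tau)
                                    - np.exp(-(b - self.t_update) / self.tau))
        return self.cmd + (self.start - self.cmd) * w

    def update(self, t: float, new_cmd: np.ndarray) -> None:
        self.start = self.value(t)
        self.cmd = np.array(new_cmd, dtype=float, copy=True)
        self.t_update = t


def derive_timing(cfg: TimingConfig) -> dict:
    """Loop rate and latency implied by the timing parameters.

    Latency is the delay from exposure start to completion of the DM update:
    t_integration + t_readout_transfer_process + t_dm_settle.  The
    discontinuous loop period is the sum of all five cycle components; the
    continuous loop rate equals the camera's maximum frame rate.
    """
    latency = (cfg.t_integration + cfg.t_readout_transfer_process
               + cfg.t_dm_settle)
    if cfg.scheme == "discontinuous":
        period = (cfg.t_integration + cfg.t_readout_transfer_process
                  + cfg.t_dm_settle + cfg.exposure_delay + cfg.trigger_overhead)
        rate = 1.0 / period
    else:
        rate = cfg.camera_max_rate
    return {"loop_rate": rate, "latency": latency}


def _update_offset(cfg: TimingConfig) -> float:
    """Exposure start -> DM command write delay for the scheme."""
    off = cfg.t_integration + cfg.t_readout_transfer_process
    if cfg.scheme == "discontinuous":
        off += cfg.trigger_overhead
    return off


def simulate_convergence(cfg: TimingConfig, gain: float, initial_rms: float,
                         duration: float) -> LoopTrace:
    """Close the loop on a static aberration and record the residual.

    A single static mode of amplitude ``initial_rms`` (um) is corrected by a
    leakless integral controller.  Each exposure measures the time-averaged
    difference between the aberration and the DM's effective (first-order
    lag) correction; the command update ``c += gain * measurement`` is
    written after readout/processing (plus trigger overhead under the
    discontinuous scheme).  Divergence (|residual| > 10x initial) is flagged
    on the trace rather than raised.
    """
    if gain < 0:
        raise ValueError("gain must be non-negative")
    if initial_rms <= 0:
        raise ValueError("initial_rms must be positive")
    timing = derive_timing(cfg)
    period = 1.0 / timing["loop_rate"]
    offset = _update_offset(cfg)
    n_steps = max(int(math.ceil(duration / period)), 1)
    dm = _FirstOrderDM(1, cfg.dm_tau)
    a0 = float(initial_rms)

    t_meas, signed, t_upd, events = [], [], [], []
    diverged = False
    for k in range(n_steps):
        t0 = k * period
        events.append((t0, "exposure_start"))
        m = a0 - dm.window_mean(t0, t0 + cfg.t_integration)[0]
        events.append((t0 + cfg.t_integration, "exposure_end"))
        events.append((t0, "measurement"))
        t_meas.append(t0)
        signed.append(m)
        if abs(m) > 10.0 * a0:
            diverged = True
        t_up = t0 + offset
        dm.update(t_up, dm.cmd + gain * m)
        t_upd.append(t_up)
        events.append((t_up, "dm_update"))
    signed = np.array(signed)
    return LoopTrace(measurement_times=np.array(t_meas),
                     residual_rms=np.abs(signed),
                     signed_residual=signed,
                     update_times=np.array(t_upd),
                     events=events, diverged=diverged)


def time_to_threshold(trace: LoopTrace, threshold: float) -> float:
    """First measurement time at which the residual is at or below
    ``threshold`` and stays there for the rest of the trace; ``NOT_REACHED``
    otherwise."""
    r = trace.residual_rms
    if r.size == 0:
        raise ValueError("empty trace")
    below = r <= threshold
    # last index where the residual is above threshold
    above = np.where(~below)[0]
    if above.size == 0:
        return float(trace.measurement_times[0])
    first_held = above[-1] + 1
    if first_held >= r.size:
        return NOT_REACHED
    return float(trace.measurement_times[first_held])


def loop_overshoot(trace: LoopTrace) -> float:
    """Peak rebound of the residual past the converged value: how far the
    signed residual crosses below zero, in the units of the trace."""
    return float(max(0.0, -np.min(trace.signed_residual)))


def scan_exposure_delay(cfg: TimingConfig, gain: float, delays,
                        initial_rms: float = 0.35,
                        overshoot_floor: float | None = None,
                        n_periods: int = 40) -> dict:
    """Overshoot-vs-exposure-delay scan for the discontinuous scheme.

    For each candidate delay the convergence simulation is run with the
    exposure window overlapping the tail of the DM transient; the overshoot
    is the peak rebound of the residual past its converged value.  Rebounds
    below ``overshoot_floor`` (default: the loop's own noise-propagated
    residual, since smaller rebounds are indistinguishable from sensing
    noise) count as zero.  Among the delays achieving minimal overshoot the
    one with the highest loop rate (the shortest delay) is reported.
    """
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0:
        raise ValueError("empty delay list")
    if np.any(delays < 0):
        raise ValueError("delays must be non-negative")
    if overshoot_floor is None:
        overshoot_floor = _default_overshoot_floor(cfg)
    overshoots = np.empty_like(delays)
    rates = np.empty_like(delays)
    for i, d in enumerate(delays):
        cfg_d = replace(cfg, exposure_delay=float(d))
        timing = derive_timing(cfg_d)
        rates[i] = timing["loop_rate"]
        duration = n_periods / timing["loop_rate"]
        trace = simulate_convergence(cfg_d, gain, initial_rms, duration)
        os_ = loop_overshoot(trace)
        overshoots[i] = 0.0 if os_ < overshoot_floor else os_
    best = np.min(overshoots)
    candidates = np.where(overshoots == best)[0]
    i_opt = candidates[np.argmax(rates[candidates])]
    return {"optimal_delay": float(delays[i_opt]), "delays": delays,
            "overshoots": overshoots, "loop_rates": rates,
            "overshoot_floor": float(overshoot_floor)}


def _default_overshoot_floor(cfg: TimingConfig) -> float:
    """Noise-propagated residual RMS (um) of the loop at the default sensing
    noise budget; rebounds below it are within the loop's own noise."""
    from .control import LoopConfig, noise_propagated_rms
    from .shws import LensletGeometry, SensorConfig, sensing_noise_budget

    timing = derive_timing(cfg)
    loop_cfg = LoopConfig(t_integration=cfg.t_integration,
                          t_delay=cfg.t_readout_transfer_process,
                          t_dm=cfg.t_dm_settle,
                          loop_rate=timing["loop_rate"], loop_gain=1.0,
                          scheme=cfg.scheme)
    budget = sensing_noise_budget(SensorConfig(), LensletGeometry())
    return noise_propagated_rms(budget.sigma_total, loop_cfg, 0.79)


def simulate_tracking(cfg: TimingConfig, gain: float,
                      aberration_series: WavefrontSeries) -> dict:
    """Track a time-varying aberration and return open/closed-loop series.

    The injected series (any number of independent channels) is replayed
    identically through an open branch (sensor only) and a closed branch
    (sensor + integral controller + first-order DM), both sampled at the
    exposure times, so that the ratio of their power spectral densities
    estimates the loop's power rejection curve.
    """
    if gain < 0:
        raise ValueError("gain must be non-negative")
    values = np.atleast_2d(np.asarray(aberration_series.values, dtype=float))
    fs_in = aberration_series.sample_rate
    timing = derive_timing(cfg)
    rate = timing["loop_rate"]
    if fs_in < rate * (1 - 1e-9):
        raise ValueError("aberration series must be sampled at >= loop rate")
    n_in = values.shape[1]
    duration = n_in / fs_in
    n_steps = int(duration * rate)
    if n_steps < 10:
        raise ValueError("series must span at least 10 loop periods")
    period = 1.0 / rate
    offset = _update_offset(cfg)
    dm = _FirstOrderDM(values.shape[0], cfg.dm_tau)

    open_out = np.empty((values.shape[0], n_steps))
    closed_out = np.empty_like(open_out)
    times = np.empty(n_steps)
    for k in range(n_steps):
        t0 = k * period
        idx = min(int(round(t0 * fs_in)), n_in - 1)
        a = values[:, idx]
        m = a - dm.window_mean(t0, t0 + cfg.t_integration)
        times[k] = t0
        open_out[:, k] = a
        closed_out[:, k] = m
        dm.update(t0 + offset, dm.cmd + gain * m)
    return {
        "open_series": WavefrontSeries(times=times, values=open_out,
                                       sample_rate=rate),
        "closed_series": WavefrontSeries(times=times, values=closed_out,
                                         sample_rate=rate),
    }
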