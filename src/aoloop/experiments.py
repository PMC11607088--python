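"""Reproducible end-to-end experiments tying the modules together.

Each experiment writes CSV/JSON results plus a provenance record (config
hash, seed, package/library versions) into an output directory, and returns
its headline numbers as a dict.  All randomness flows from the explicit
seed, so repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aberrations import PinkNoiseSpec, gen_pink_noise, WavefrontSeries
from .config import FullConfig, RunConfig, load_config
from .control import (ao_bandwidth, continuous_loop, conventional_loop,
                      noise_propagated_rms, rejection_power_curve, ultrafast_loop)
from .loopsim import (derive_timing, scan_exposure_delay, simulate_convergence,
                      simulate_tracking, time_to_threshold)
from .optics import (WavefrontState, build_zernike_basis, diffraction_limit_rms,
                     evaluate_wavefront)
from .shws import (centroid_tcog, render_calibration_frame, render_frame,
                   reconstruct_wavefront, sensing_noise_budget)
from .spectra import estimate_psd, measure_rejection_curve, required_loop_rate

__all__ = ["EXPERIMENTS", "run_experiment"]


def _provenance(cfg: FullConfig, run: RunConfig) -> dict:
    blob = json.dumps({name: dataclasses.asdict(getattr(cfg, name))
                       for name in ("optical", "sensor", "loop", "timing")},
                      sort_keys=True, default=str)
    return {"config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": run.seed, "aoloop_version": __version__,
            "numpy_version": np.__version__}


def _exp_bandwidth_table(cfg: FullConfig, run: RunConfig, outdir: Path) -> dict:
    rows = []
    for name, loop in (("ultrafast_discontinuous", ultrafast_loop()),
                       ("continuous_optimal_gain", continuous_loop()),
                       ("conventional_mimic", conventional_loop())):
        bw = ao_bandwidth(loop)
        rows.append({"configuration": name, "loop_rate_hz": loop.loop_rate,
                     "loop_gain": loop.loop_gain,
                     "rate_gain_product_hz": loop.rate_gain_product,
                     "bandwidth_hz": bw.f_c})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "bandwidth_table.csv", index=False)
    return {row["configuration"]: row["bandwidth_hz"] for row in rows}


def _exp_convergence(cfg: FullConfig, run: RunConfig, outdir: Path) -> dict:
    trace = simulate_convergence(cfg.timing, gain=1.0, initial_rms=0.35,
                                 duration=0.05)
    pd.DataFrame({"time_s": trace.measurement_times,
                  "event": "measurement",
                  "residual_rms_um": trace.residual_rms}).to_csv(
        outdir / "convergence_trace.csv", index=False)
    t_dl = time_to_threshold(trace, diffraction_limit_rms(cfg.optical))
    timing = derive_timing(cfg.timing)
    return {"time_to_diffraction_limit_ms": t_dl * 1e3,
            "latency_ms": timing["latency"] * 1e3,
            "loop_rate_hz": timing["loop_rate"]}


def _exp_rejection_measurement(cfg: FullConfig, run: RunConfig, outdir: Path) -> dict:
    timing = derive_timing(cfg.timing)
    rate = timing["loop_rate"]
    spec = PinkNoiseSpec(n_steps=4096, sample_rate=rate, amplitude_rms=0.1,
                         seed=run.seed, n_channels=8)
    stimulus = gen_pink_noise(spec)
    series = WavefrontSeries(times=np.arange(spec.n_steps) / rate,
                             values=stimulus, sample_rate=rate)
    out = simulate_tracking(cfg.timing, gain=cfg.loop.loop_gain, aberration_series=series)
    skip = 64
    open_s, closed_s = out["open_series"], out["closed_series"]
    open_s = WavefrontSeries(open_s.times[skip:], open_s.values[:, skip:], rate)
    closed_s = WavefrontSeries(closed_s.times[skip:], closed_s.values[:, skip:], rate)
    measured = measure_rejection_curve(estimate_psd(open_s), estimate_psd(closed_s))
    theory = rejection_power_curve(cfg.loop, measured.frequencies)
    pd.DataFrame({"frequency_hz": measured.frequencies,
                  "power_rejection_measured": measured.power_rejection,
                  "power_rejection_theory": theory.power_rejection}).to_csv(
        outdir / "rejection_curve.csv", index=False)
    above = measured.frequencies[measured.power_rejection >= 1.0]
    return {"empirical_bandwidth_hz": float(above[0]) if above.size else None,
            "theoretical_bandwidth_hz": ao_bandwidth(cfg.loop).f_c}


def _exp_exposure_delay_scan(cfg: FullConfig, run: RunConfig, outdir: Path) -> dict:
    delays = np.arange(0.0, 1.05e-3, 0.1e-3)
    scan = scan_exposure_delay(cfg.timing, gain=1.0, delays=delays)
    pd.DataFrame({"exposure_delay_ms": scan["delays"] * 1e3,
                  "overshoot_um": scan["overshoots"],
                  "loop_rate_hz": scan["loop_rates"]}).to_csv(
        outdir / "exposure_delay_scan.csv", index=False)
    return {"optimal_delay_ms": scan["optimal_delay"] * 1e3}


def _exp_scenario_prediction(cfg: FullConfig, run: RunConfig, outdir: Path) -> dict:
    from .aberrations import synthesize_series_from_psd
    series = synthesize_series_from_psd(cfg.scenario, duration=5.0,
                                        n_channels=4, seed=run.seed)
    spec = estimate_psd(series)
    threshold = diffraction_limit_rms(cfg.optical)
    rates = np.arange(5.0, 255.0, 5.0)
    rate = required_loop_rate(spec, threshold, rates)
    pd.DataFrame({"frequency_hz": spec.frequencies, "psd_um2_per_hz": spec.psd}
                 ).to_csv(outdir / "scenario_psd.csv", index=False)
    return {"scenario": cfg.scenario.scenario_tag,
            "required_loop_rate_hz": rate,
            "diffraction_limit_um": threshold}


def _exp_shws_roundtrip(cfg: FullConfig, run: RunConfig, outdir: Path) -> dict:
    basis = build_zernike_basis(10, exclude_piston_tip_tilt=True)
    rng = np.random.default_rng(run.seed)
    coeffs = rng.normal(0.0, 1.0, basis.mode_count)
    coeffs *= 0.3 / np.linalg.norm(coeffs)
    truth = WavefrontState(coefficients=coeffs)
    frame = render_frame(truth, basis, cfg.geometry, cfg.sensor,
                         seed=run.seed, add_noise=False)
    calib = render_calibration_frame(cfg.geometry, cfg.sensor)
    slopes = centroid_tcog(frame, cfg.geometry, cfg.sensor, calib)
    recon = reconstruct_wavefront(slopes, basis, cfg.geometry)
    err = np.linalg.norm(recon.coefficients - truth.coefficients)
    budget = sensing_noise_budget(cfg.sensor, cfg.geometry)
    noise_rms = noise_propagated_rms(budget.sigma_total, cfg.loop,
                                     cfg.optical.wavelength_um)
    pd.DataFrame({"mode_index": np.arange(basis.mode_count),
                  "injected_um": truth.coefficients,
                  "recovered_um": recon.coefficients}).to_csv(
        outdir / "roundtrip_coefficients.csv", index=False)
    return {"relative_coefficient_error": float(err / truth.rms),
            "sigma_photon_rad": budget.sigma_photon,
            "sigma_readout_rad": budget.sigma_readout,
            "noise_propagated_rms_um": noise_rms}


EXPERIMENTS = {
    "bandwidth-table": _exp_bandwidth_table,
    "rejection-measurement": _exp_rejection_measurement,
    "convergence": _exp_convergence,
    "exposure-delay-scan": _exp_exposure_delay_scan,
    "scenario-prediction": _exp_scenario_prediction,
    "shws-roundtrip": _exp_shws_roundtrip,
}


def run_experiment(name: str, run: RunConfig) -> dict:
    """Run a named experiment; writes results + provenance, returns headline
    numbers."""
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; "
                         f"choose from {sorted(EXPERIMENTS)}")
    cfg = load_config(run.config_path)
    outdir = Path(run.output_dir) / name
    outdir.mkdir(parents=True, exist_ok=True)
    result = EXPERIMENTS[name](cfg, run, outdir)
    record = {"experiment": name, "results": result,
              "provenance": _provenance(cfg, run)}
    (outdir / "result.json").write_text(json.dumps(record, indent=2))
    return result
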