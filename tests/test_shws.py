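import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aoloop import (LensletGeometry, SensorConfig, SlopeSet, WavefrontState,
                    build_zernike_basis, centroid_tcog, detect_blink,
                    phase_to_opd, reconstruct_wavefront,
                    render_calibration_frame, render_frame,
                    sensing_noise_budget)
from aoloop.shws import _mean_gradients, _slope_unit_per_um_coeff


def tilt_state(dx_px: float, dy_px: float, geom: LensletGeometry):
    """Tip/tilt wavefront whose spots displace by (dx_px, dy_px) everywhere.

    On the RMS-normalised basis the two tilt modes are 2*y and 2*x, so a
    coefficient c gives a uniform gradient of 2c um per unit-pupil coord.
    """
    basis = build_zernike_basis(1, exclude_piston_tip_tilt=False)
    slope_x = dx_px * geom.superpixel_um / (geom.focal_length_mm * 1000.0)
    slope_y = dy_px * geom.superpixel_um / (geom.focal_length_mm * 1000.0)
    r_um = geom.pupil_radius_mm * 1000.0
    coeffs = np.array([0.0, slope_y * r_um / 2.0, slope_x * r_um / 2.0])
    return basis, WavefrontState(coefficients=coeffs)


class TestGeometry:
    def test_300_active_lenslets(self, geom):
        assert geom.n_active == 300

    def test_active_lenslets_fully_inside_pupil(self, geom):
        x, y = geom.lenslet_centers_mm()
        mask = geom.active_mask
        half = geom.pitch_mm / 2
        corners = np.hypot(np.abs(x[mask]) + half, np.abs(y[mask]) + half)
        assert np.all(corners <= geom.pupil_radius_mm)

    def test_superpixel_size(self, geom):
        assert geom.superpixel_um == pytest.approx(500.0 / 45)


class TestRenderFrame:
    def test_flat_wavefront_spots_at_reference(self, basis63, geom, sensor_cfg,
                                               calib_frame):
        frame = render_frame(WavefrontState(np.zeros(63)), basis63, geom,
                             sensor_cfg, add_noise=False)
        slopes = centroid_tcog(frame, geom, sensor_cfg, calib_frame)
        assert np.all(slopes.valid)
        assert np.abs(slopes.dx_px).max() < 0.05
        assert np.abs(slopes.dy_px).max() < 0.05

    def test_tilt_displacement_equals_focal_length_times_slope(self, geom,
                                                               sensor_cfg,
                                                               calib_frame):
        # 1 mrad slope -> 13.9 um displacement
        slope = 1e-3
        dx_px = slope * geom.focal_length_mm * 1000.0 / geom.superpixel_um
        basis, state = tilt_state(dx_px, 0.0, geom)
        frame = render_frame(state, basis, geom, sensor_cfg, add_noise=False)
        # geometry oracle: unbiased full-tile centre of gravity of the spot
        n = geom.superpixels_per_subaperture
        i, j = np.argwhere(geom.active_mask)[0]
        tile = frame.pixels[i * n:(i + 1) * n, j * n:(j + 1) * n].astype(float)
        xg = np.arange(n, dtype=float)
        cog = (tile.sum(axis=0) @ xg) / tile.sum() - (n - 1) / 2.0
        assert cog * geom.superpixel_um == pytest.approx(13.9, rel=0.005)
        # the TCoG pipeline recovers it to its own sub-pixel accuracy
        slopes = centroid_tcog(frame, geom, sensor_cfg, calib_frame)
        assert np.abs(slopes.dx_px - dx_px).max() < 0.05

    def test_poisson_photon_budget(self, basis63, geom, calib_frame):
        # sum of spot electrons per lenslet matches the printed mean photon
        # count within 3 standard errors (read noise off isolates Poisson)
        cfg = SensorConfig(read_noise_e=0.0)
        state = WavefrontState(np.zeros(63))
        totals = []
        for seed in range(30):
            frame = render_frame(state, basis63, geom, cfg, seed=seed)
            tiles = frame.pixels.astype(float) / cfg.camera_gain_dn_per_e
            n = geom.superpixels_per_subaperture
            for i, j in zip(*np.nonzero(geom.active_mask)):
                totals.append(tiles[i * n:(i + 1) * n, j * n:(j + 1) * n].sum())
        totals = np.array(totals)
        se = np.sqrt(cfg.photons_per_lenslet) / np.sqrt(totals.size)
        assert totals.mean() == pytest.approx(1962.0, abs=3 * se + 0.5)

    def test_deterministic_given_seed(self, basis63, geom, sensor_cfg,
                                      random_wavefront):
        a = render_frame(random_wavefront, basis63, geom, sensor_cfg, seed=7)
        b = render_frame(random_wavefront, basis63, geom, sensor_cfg, seed=7)
        assert np.array_equal(a.pixels, b.pixels)

    def test_basis_mismatch_rejected(self, basis63, geom, sensor_cfg):
        with pytest.raises(ValueError):
            render_frame(WavefrontState(np.zeros(10)), basis63, geom, sensor_cfg)


class TestCentroidTCoG:
    def test_known_subpixel_offset_recovered(self, geom, sensor_cfg, calib_frame):
        basis, state = tilt_state(0.30, -0.20, geom)
        frame = render_frame(state, basis, geom, sensor_cfg, add_noise=False)
        slopes = centroid_tcog(frame, geom, sensor_cfg, calib_frame)
        assert np.abs(slopes.dx_px - 0.30).max() < 0.05
        assert np.abs(slopes.dy_px + 0.20).max() < 0.05

    def test_dark_subaperture_marked_invalid(self, basis63, geom, sensor_cfg,
                                             calib_frame):
        frame = render_frame(WavefrontState(np.zeros(63)), basis63, geom,
                             sensor_cfg, add_noise=False)
        n = geom.superpixels_per_subaperture
        i, j = np.argwhere(geom.active_mask)[0]
        frame.pixels[i * n:(i + 1) * n, j * n:(j + 1) * n] = 0
        slopes = centroid_tcog(frame, geom, sensor_cfg, calib_frame)
        assert not slopes.valid[0]
        assert slopes.valid[1:].all()
        assert np.abs(slopes.dx_px[1:]).max() < 0.05

    def test_calibration_shape_mismatch_rejected(self, basis63, geom,
                                                 sensor_cfg, calib_frame):
        from aoloop.shws import SensorFrame
        frame = render_frame(WavefrontState(np.zeros(63)), basis63, geom,
                             sensor_cfg, add_noise=False)
        with pytest.raises(ValueError):
            centroid_tcog(frame, geom, sensor_cfg,
                          SensorFrame(pixels=np.zeros((10, 10))))

    def test_photon_noise_scaling(self, geom):
        """Empirical centroid noise follows 1/sqrt(N): log-log slope -0.5."""
        small = LensletGeometry(grid=(4, 4), pupil_diameter_at_array_mm=4.0)
        basis, state = tilt_state(0.0, 0.0, small)
        stds = []
        photon_counts = [200.0, 2000.0, 20000.0]
        for n_ph in photon_counts:
            cfg = SensorConfig(photons_per_lenslet=n_ph, read_noise_e=0.0,
                               camera_gain_dn_per_e=2.0)
            calib = render_calibration_frame(small, cfg)
            dxs = []
            for seed in range(25):
                frame = render_frame(state, basis, small, cfg, seed=seed)
                dxs.append(centroid_tcog(frame, small, cfg, calib).dx_px)
            stds.append(np.concatenate(dxs).std())
        slope = np.polyfit(np.log10(photon_counts), np.log10(stds), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)


class TestBlinkDetection:
    def _slopes(self, peaks):
        n = len(peaks)
        z = np.zeros(n)
        return SlopeSet(rows=z.astype(int), cols=z.astype(int), dx_px=z,
                        dy_px=z, slopes_x=z, slopes_y=z,
                        valid=np.ones(n, dtype=bool),
                        peak_intensities=np.asarray(peaks, dtype=float))

    def test_bright_frame_not_a_blink(self, sensor_cfg):
        assert not detect_blink(self._slopes([800.0] * 300), sensor_cfg)

    def test_majority_dim_is_a_blink(self, sensor_cfg):
        peaks = [600.0] * 151 + [800.0] * 149
        assert detect_blink(self._slopes(peaks), sensor_cfg)

    def test_boundary_half_counts_as_blink(self, sensor_cfg):
        peaks = [600.0] * 150 + [800.0] * 150
        assert detect_blink(self._slopes(peaks), sensor_cfg)

    def test_monotone_dimming_never_unflags(self, sensor_cfg):
        # dimming additional lenslets can only keep or raise the dim fraction
        flagged = False
        for n_dim in range(0, 301, 50):
            peaks = [600.0] * n_dim + [800.0] * (300 - n_dim)
            now = detect_blink(self._slopes(peaks), sensor_cfg)
            assert now or not flagged
            flagged = flagged or now

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(peaks=st.lists(st.floats(0.0, 2000.0), min_size=10, max_size=100),
           extra_dim=st.integers(1, 20))
    def test_blink_monotone_property(self, sensor_cfg, peaks, extra_dim):
        # dimming any subset of lenslets never turns a blink into a non-blink
        peaks = np.asarray(peaks)
        before = detect_blink(self._slopes(peaks), sensor_cfg)
        dimmed = peaks.copy()
        dimmed[:extra_dim] = 0.0
        after = detect_blink(self._slopes(dimmed), sensor_cfg)
        assert after or not before


class TestReconstruction:
    def test_zero_slopes_give_zero_wavefront(self, basis63, geom):
        n = geom.n_active
        z = np.zeros(n)
        slopes = SlopeSet(rows=z.astype(int), cols=z.astype(int), dx_px=z,
                          dy_px=z, slopes_x=z, slopes_y=z,
                          valid=np.ones(n, dtype=bool), peak_intensities=z)
        state = reconstruct_wavefront(slopes, basis63, geom)
        assert state.rms == 0.0

    def test_analytic_slope_round_trip(self, basis63, geom, random_wavefront):
        # slopes computed directly from the forward model reconstruct the
        # coefficients to numerical precision
        gx, gy = _mean_gradients(None, basis63, geom)
        ts = _slope_unit_per_um_coeff(geom)
        c = random_wavefront.coefficients
        n = geom.n_active
        z = np.zeros(n)
        slopes = SlopeSet(rows=z.astype(int), cols=z.astype(int), dx_px=z,
                          dy_px=z, slopes_x=(c @ gx) * ts,
                          slopes_y=(c @ gy) * ts,
                          valid=np.ones(n, dtype=bool), peak_intensities=z)
        state = reconstruct_wavefront(slopes, basis63, geom)
        assert np.linalg.norm(state.coefficients - c) < 1e-2 * np.linalg.norm(c)

    def test_single_mode_rms_is_coefficient(self, basis63, geom):
        gx, gy = _mean_gradients(None, basis63, geom)
        ts = _slope_unit_per_um_coeff(geom)
        c = np.zeros(63)
        c[2] = 0.25  # defocus
        n = geom.n_active
        z = np.zeros(n)
        slopes = SlopeSet(rows=z.astype(int), cols=z.astype(int), dx_px=z,
                          dy_px=z, slopes_x=(c @ gx) * ts,
                          slopes_y=(c @ gy) * ts,
                          valid=np.ones(n, dtype=bool), peak_intensities=z)
        state = reconstruct_wavefront(slopes, basis63, geom)
        assert state.rms == pytest.approx(0.25, rel=0.01)

    def test_too_few_valid_slopes_rejected(self, basis63, geom):
        n = geom.n_active
        z = np.zeros(n)
        valid = np.zeros(n, dtype=bool)
        valid[:50] = True  # 100 measurements < 2 * 63
        slopes = SlopeSet(rows=z.astype(int), cols=z.astype(int), dx_px=z,
                          dy_px=z, slopes_x=z, slopes_y=z, valid=valid,
                          peak_intensities=z)
        with pytest.raises(ValueError):
            reconstruct_wavefront(slopes, basis63, geom)


class TestNoiseBudget:
    def test_printed_values(self, geom, sensor_cfg):
        budget = sensing_noise_budget(sensor_cfg, geom)
        assert budget.sigma_photon == pytest.approx(0.100, abs=0.001)
        assert budget.sigma_readout == pytest.approx(0.010, abs=0.001)
        assert budget.sigma_total == pytest.approx(
            np.hypot(budget.sigma_photon, budget.sigma_readout))

    def test_photon_term_scales_inverse_sqrt(self, geom, sensor_cfg):
        quad = sensing_noise_budget(
            SensorConfig(photons_per_lenslet=4 * 1962.0), geom)
        base = sensing_noise_budget(sensor_cfg, geom)
        assert quad.sigma_photon == pytest.approx(base.sigma_photon / 2)

    def test_zero_read_noise(self, geom):
        budget = sensing_noise_budget(SensorConfig(read_noise_e=0.0), geom)
        assert budget.sigma_readout == 0.0

    def test_zero_photons_rejected(self, geom):
        with pytest.raises(ValueError):
            sensing_noise_budget(SensorConfig(photons_per_lenslet=0.0), geom)


class TestEndToEndRoundTrip:
    def test_noise_free_round_trip_within_2_percent(self, basis63, geom,
                                                    sensor_cfg, calib_frame,
                                                    random_wavefront):
        frame = render_frame(random_wavefront, basis63, geom, sensor_cfg,
                             add_noise=False)
        slopes = centroid_tcog(frame, geom, sensor_cfg, calib_frame)
        recon = reconstruct_wavefront(slopes, basis63, geom)
        err = np.linalg.norm(recon.coefficients - random_wavefront.coefficients)
        assert err / random_wavefront.rms < 0.02

    def test_noisy_round_trip_within_noise_budget(self, basis63, geom,
                                                  sensor_cfg, calib_frame,
                                                  random_wavefront):
        budget = sensing_noise_budget(sensor_cfg, geom)
        bound_um = phase_to_opd(budget.sigma_total, sensor_cfg.wavelength_um)
        errs = []
        for seed in range(30):
            frame = render_frame(random_wavefront, basis63, geom, sensor_cfg,
                                 seed=seed)
            slopes = centroid_tcog(frame, geom, sensor_cfg, calib_frame)
            recon = reconstruct_wavefront(slopes, basis63, geom)
            errs.append(np.linalg.norm(recon.coefficients
                                       - random_wavefront.coefficients))
        assert np.sqrt(np.mean(np.square(errs))) <= bound_um
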