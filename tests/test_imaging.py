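"""Synthetic bead fields, skewed-stack rendering, camera noise, shadowing."""

import numpy as np
import pytest
from scipy import ndimage

from lsfmkit import imaging, psf
from lsfmkit.imaging import Absorber, AcquisitionGeometry, CameraModel


class TestGeometry:
    def test_paper_configuration_shear(self):
        g = AcquisitionGeometry(scan_step_um=0.25, deskew_angle_deg=29.5,
                                pixel_size_um=0.130)
        assert g.shift_px_per_slice == pytest.approx(1.674, abs=1e-3)
        assert g.z_spacing_um == pytest.approx(0.123, abs=1e-3)
        assert g.mount_normal_angle_deg == pytest.approx(60.5)

    def test_angle_bounds(self):
        with pytest.raises(ValueError):
            AcquisitionGeometry(deskew_angle_deg=0.0)
        with pytest.raises(ValueError):
            AcquisitionGeometry(deskew_angle_deg=95.0)


class TestBeadField:
    def test_requested_count_and_separation(self):
        t = imaging.generate_bead_field(50, (10, 20, 20), min_separation_um=1.5, seed=4)
        assert t.n_beads == 50
        d = np.linalg.norm(
            t.positions_um[:, None, :] - t.positions_um[None, :, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 1.5

    def test_deterministic_per_seed(self):
        a = imaging.generate_bead_field(20, (10, 20, 20), seed=7)
        b = imaging.generate_bead_field(20, (10, 20, 20), seed=7)
        assert np.array_equal(a.positions_um, b.positions_um)

    def test_infeasible_packing_raises(self):
        with pytest.raises((RuntimeError, ValueError)):
            imaging.generate_bead_field(
                1000, (3, 3, 3), min_separation_um=1.0, seed=0,
                max_attempts_per_bead=20,
            )


class TestRender:
    def test_per_slice_drift_matches_analytic_shear(self):
        """A single bead's lateral centroid drifts by step*cos(theta)/pixel
        px per slice; the rendered slope must match to <0.01 px."""
        g = AcquisitionGeometry(camera_roi=(33, 160), n_slices=40)
        vx = (g.z_spacing_um, g.pixel_size_um, g.pixel_size_um)
        kern = psf.gaussian_psf((464, 330, 328), vx)
        truth = imaging.GroundTruth(
            positions_um=np.array([[g.z_spacing_um * 20, 33 * 0.13 / 2, 4.0]]),
            intensities_photons=np.array([50000.0]),
            volume_um=(g.z_spacing_um * 40, 33 * 0.13, 8.0),
        )
        raw = imaging.render_skewed_stack(
            truth, kern, g, CameraModel(shot_noise=False), seed=0
        )
        sig = raw.data.astype(float) - 100.0
        ks, cols = [], []
        for k in range(8, 33):  # slices where the bead is bright
            sl = np.clip(sig[k], 0, None)
            if sl.sum() < 1000:
                continue
            ks.append(k)
            cols.append(ndimage.center_of_mass(sl)[1])
        slope = np.polyfit(ks, cols, 1)[0]
        assert slope == pytest.approx(g.shift_px_per_slice, abs=0.01)

    def test_empty_truth_renders_offset_only(self):
        g = AcquisitionGeometry(camera_roi=(16, 64), n_slices=10)
        vx = (g.z_spacing_um, g.pixel_size_um, g.pixel_size_um)
        kern = psf.gaussian_psf((464, 330, 328), vx)
        truth = imaging.GroundTruth(
            positions_um=np.empty((0, 3)), intensities_photons=np.empty(0),
            volume_um=(1.0, 2.0, 2.0),
        )
        raw = imaging.render_skewed_stack(truth, kern, g,
                                          CameraModel(shot_noise=False), seed=0)
        assert np.all(raw.data == 100)

    def test_flux_conservation_noiseless(self, acquisition_geometry, system_psf,
                                         bead_truth):
        camera = CameraModel(gain_counts_per_photon=20.0, shot_noise=False)
        raw = imaging.render_skewed_stack(
            bead_truth, system_psf, acquisition_geometry, camera, seed=0
        )
        signal = raw.data.astype(float) - 100.0
        expected = bead_truth.intensities_photons.sum() * 20.0
        assert signal.sum() == pytest.approx(expected, rel=0.005)

    def test_mismatched_psf_voxel_rejected(self, acquisition_geometry, bead_truth):
        wrong = psf.gaussian_psf((464, 330, 328), (0.2, 0.1, 0.1))
        with pytest.raises(ValueError, match="does not match"):
            imaging.render_skewed_stack(bead_truth, wrong, acquisition_geometry)

    def test_roi_too_small_for_drift(self, system_psf):
        g = AcquisitionGeometry(camera_roi=(16, 40), n_slices=80)
        truth = imaging.GroundTruth(
            positions_um=np.array([[1.0, 1.0, 1.0]]),
            intensities_photons=np.array([1000.0]),
            volume_um=(9.8, 2.0, 5.0),
        )
        with pytest.raises(ValueError, match="too small"):
            imaging.render_skewed_stack(truth, system_psf, g)


class TestCameraNoise:
    def test_noiseless_unit_gain_adds_offset_exactly(self):
        grid = np.arange(12, dtype=float).reshape(3, 2, 2)
        out = imaging.add_camera_noise(grid, CameraModel(shot_noise=False), seed=0)
        assert np.array_equal(out, (grid + 100).astype(np.uint16))

    def test_poisson_mean_consistent(self):
        grid = np.full((40, 40, 40), 100.0)
        out = imaging.add_camera_noise(grid, CameraModel(shot_noise=True), seed=1)
        signal = out.astype(float) - 100.0
        se = 10.0 / np.sqrt(grid.size)
        assert abs(signal.mean() - 100.0) < 3 * se

    def test_deterministic_per_seed(self):
        grid = np.full((10, 10, 10), 50.0)
        cam = CameraModel(read_noise_counts=2.0)
        a = imaging.add_camera_noise(grid, cam, seed=3)
        b = imaging.add_camera_noise(grid, cam, seed=3)
        assert np.array_equal(a, b)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            imaging.add_camera_noise(np.array([-1.0]), CameraModel(), seed=0)

    def test_clipped_to_16bit(self):
        grid = np.full((4, 4, 4), 1e6)
        out = imaging.add_camera_noise(grid, CameraModel(shot_noise=False), seed=0)
        assert out.max() == 65535


class TestShadowing:
    def test_no_absorbers_no_contrast(self):
        r = imaging.simulate_shadowing([], pivot_half_angle_deg=2.0)
        assert r["stripe_contrast_static"] == 0.0
        assert r["stripe_contrast_pivoted"] == 0.0

    def test_static_shadow_has_contrast(self):
        r = imaging.simulate_shadowing([Absorber(0.0, 0.0, 1.0, 0.5)], 0.0)
        assert r["stripe_contrast_static"] > 0
        assert r["stripe_contrast_pivoted"] == r["stripe_contrast_static"]

    @pytest.mark.parametrize("pivot", [0.2, 0.5, 2.0, 5.0])
    def test_pivoting_strictly_reduces_stripe_contrast(self, pivot):
        absorbers = [Absorber(0.0, 0.0, 0.8, 0.5), Absorber(-3.0, 5.0, 1.0, 0.3)]
        r = imaging.simulate_shadowing(absorbers, pivot_half_angle_deg=pivot)
        assert r["stripe_contrast_pivoted"] < r["stripe_contrast_static"]

    def test_absorber_validation(self):
        with pytest.raises(ValueError):
            Absorber(0.0, 0.0, opacity=1.5)
        with pytest.raises(ValueError):
            imaging.simulate_shadowing([Absorber(100.0, 0.0)], 1.0)
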