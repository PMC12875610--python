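"""Gaussian-beam propagation, sheet simulation and calibration checks."""

import numpy as np
import pytest

from lsfmkit import optics
from lsfmkit.optics import (
    FWHM_FACTOR,
    BeamState,
    OpticalElement,
    OpticalTrain,
    calibrate_aperture,
    effective_na_at_sample,
    gaussian_sheet_fwhm,
    profile_fwhm,
    propagate_train,
    propagation_length,
    simulate_sheet_profile,
)


def air_train(elements, diameter=2.0):
    return OpticalTrain(tuple(elements), input_beam_diameter_mm=diameter,
                        wavelength_nm=488.0, immersion_index=1.0)


class TestTrainValidation:
    def test_positions_must_increase(self):
        els = (OpticalElement("thin-lens", 10.0, 30.0, 30.0),
               OpticalElement("thin-lens", 10.0, 80.0, 80.0))
        with pytest.raises(ValueError, match="strictly increasing"):
            air_train(els)

    def test_thin_lens_needs_equal_focals(self):
        with pytest.raises(ValueError, match="equal focal lengths"):
            OpticalElement("thin-lens", 0.0, 30.0, 40.0)

    def test_cylindrical_lens_single_axis(self):
        with pytest.raises(ValueError, match="exactly one"):
            OpticalElement("cylindrical-lens", 0.0, 75.0, 75.0)

    def test_aperture_has_no_power(self):
        with pytest.raises(ValueError, match="no focal power"):
            OpticalElement("aperture", 0.0, focal_length_thin_mm=10.0)

    def test_zero_focal_length_rejected(self):
        with pytest.raises(ValueError, match="zero focal length"):
            OpticalElement("thin-lens", 0.0, 0.0, 0.0)

    def test_nonpositive_beam_diameter(self):
        el = OpticalElement("thin-lens", 0.0, 30.0, 30.0)
        with pytest.raises(ValueError, match="diameter"):
            air_train((el,), diameter=0.0)


class TestPropagation:
    def test_telescope_magnification(self):
        # f1=30/f2=80 telescope: 2 mm in -> 2*(80/30)=5.33 mm collimated out
        els = (OpticalElement("thin-lens", 0.0, 30.0, 30.0),
               OpticalElement("thin-lens", 110.0, 80.0, 80.0))
        tr = air_train(els)
        lam = 488e-6
        q = 1j * np.pi * 1.0**2 / lam
        z = 0.0
        for el in tr.elements:
            q += el.axial_position_mm - z
            z = el.axial_position_mm
            q = 1 / (1 / q - 1 / el.focal_length_thin_mm)
        # 300 mm downstream the output stays collimated at 2.667 mm radius
        q += 300.0
        w = np.sqrt(-lam / (np.pi * (1 / q).imag))
        assert w == pytest.approx(2.0 * 80 / 30 / 2, rel=1e-3)

    def test_single_lens_focuses_at_focal_plane(self):
        # high-Fresnel-number limit: waist lands at f within 0.01%
        el = OpticalElement("thin-lens", 0.0, 75.0, 75.0)
        beam = propagate_train(air_train((el,), diameter=5.34), "thin")
        assert beam.waist_position_mm == pytest.approx(75.0, rel=1e-4)

    def test_nominal_waist_at_objective_focal_plane(self, nominal_train):
        """Independent 2x2 ray-matrix oracle: a marginal parallel ray crosses
        the axis where the Gaussian waist must sit (within 1 µm)."""
        tr = nominal_train
        h, u, z = 1.0, 0.0, 0.0
        for el in tr.elements:
            h += u * (el.axial_position_mm - z)
            z = el.axial_position_mm
            f = el.focal_length("thin")
            if f is None:
                continue
            u -= h / f
            if el.kind == "objective":
                u /= tr.immersion_index  # flat interface: reduced angle
        z_cross = z - h / u
        beam = propagate_train(tr, "thin")
        assert abs(beam.waist_position_mm - z_cross) < 1e-3
        assert abs(beam.waist_position_mm - tr.sample_plane_mm) < 1e-3

    def test_4f_relay_returns_input_waist(self):
        els = (OpticalElement("thin-lens", 50.0, 50.0, 50.0),
               OpticalElement("thin-lens", 150.0, 50.0, 50.0))
        beam = propagate_train(air_train(els), "thin")
        assert beam.waist_radius_um == pytest.approx(1000.0, rel=1e-9)

    def test_nominal_thin_axis_overfills_objective(self, nominal_train):
        beam = propagate_train(nominal_train, "thin")
        assert beam.truncation_flag
        assert beam.pupil_radius_mm == pytest.approx(8.889, rel=1e-3)

    def test_invalid_axis(self, nominal_train):
        with pytest.raises(ValueError, match="axis"):
            propagate_train(nominal_train, "diagonal")


class TestEffectiveNA:
    def test_inversion_of_waist(self):
        beam = BeamState("thin", 0.327, 0.0, 488.0, 1.333)
        assert effective_na_at_sample(beam, 0.6) == pytest.approx(0.475, abs=0.001)

    def test_cap_at_objective_na(self):
        # 8.89 mm fill on a 10 mm objective implies NA 0.889 > 0.6
        w0 = 488e-3 * 10.0 / (np.pi * 8.89)  # µm, from the pupil-fill relation
        beam = BeamState("thin", w0, 0.0, 488.0, 1.333)
        assert effective_na_at_sample(beam, 0.6) == 0.6
        assert beam.truncation_flag

    def test_collimated_limit(self):
        beam = BeamState("thin", 1e9, 0.0, 488.0, 1.333)
        assert effective_na_at_sample(beam, 0.6) < 1e-9

    def test_invalid_waist(self):
        beam = BeamState("thin", 0.3, 0.0, 488.0, 1.333)
        beam.waist_radius_um = 0.0
        with pytest.raises(ValueError):
            effective_na_at_sample(beam, 0.6)


class TestSheetFwhm:
    @pytest.mark.parametrize(
        "na,expected",
        [(0.475, 0.385), (0.6, 0.305)],
    )
    def test_closed_form_values(self, na, expected):
        assert gaussian_sheet_fwhm(na, 488.0) == pytest.approx(expected, abs=5e-4)

    def test_doubling_na_halves_fwhm(self):
        assert gaussian_sheet_fwhm(0.6, 488) == pytest.approx(
            gaussian_sheet_fwhm(0.3, 488) / 2
        )

    def test_strictly_decreasing_in_na(self):
        nas = np.linspace(0.05, 1.3, 40)
        vals = [gaussian_sheet_fwhm(na, 488) for na in nas]
        assert np.all(np.diff(vals) < 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gaussian_sheet_fwhm(0.0, 488)
        with pytest.raises(ValueError):
            gaussian_sheet_fwhm(0.5, -1)


class TestSheetSimulation:
    @pytest.mark.parametrize("na", [0.1, 0.2, 0.3, 0.45, 0.6])
    def test_gaussian_pupil_matches_closed_form(self, na):
        expected = gaussian_sheet_fwhm(na, 488)
        prof = simulate_sheet_profile(
            na, "gaussian",
            z_spacing_um=min(0.02, expected / 10),
            z_extent_um=max(4.0, 8 * expected),
        )
        assert prof.metadata["fwhm_um"] == pytest.approx(expected, rel=0.01)

    def test_slit_pupil_matches_direct_summation_oracle(self):
        """Brute-force Riemann sum of the 1D focal diffraction integral."""
        na, lam, n = 0.6, 0.488, 1.333
        prof = simulate_sheet_profile(na, "slit", z_spacing_um=0.01, z_extent_um=4.0)
        s = np.linspace(-na, na, 20001)
        u = np.arange(-1.0, 1.0, 0.001)
        field = np.exp(2j * np.pi * np.outer(u, s) / lam).sum(axis=1)
        oracle = profile_fwhm(np.abs(field) ** 2, 0.001)
        assert prof.metadata["fwhm_um"] == pytest.approx(oracle, rel=0.01)

    def test_profile_normalized_and_nonnegative(self):
        prof = simulate_sheet_profile(0.4, "gaussian")
        assert prof.intensity.max() == pytest.approx(1.0)
        assert np.all(prof.intensity >= 0)

    def test_grid_too_coarse_rejected(self):
        with pytest.raises(ValueError, match="too coarse"):
            simulate_sheet_profile(0.6, "gaussian", z_spacing_um=0.2)

    def test_train_pupil_is_truncated_gaussian(self, nominal_train):
        prof = simulate_sheet_profile(nominal_train, aperture_width_mm=2.0)
        assert prof.pupil_shape == "truncated-gaussian"


class TestCalibration:
    def test_calibrated_sheet_hits_design_band(self, nominal_train):
        cal = calibrate_aperture(nominal_train)
        assert 0.380 <= cal["fwhm_um"] <= 0.390
        assert 0.45 <= cal["na_eff"] <= 0.50

    def test_unreachable_target_raises(self, nominal_train):
        with pytest.raises(ValueError, match="not bracketed"):
            calibrate_aperture(nominal_train, target_fwhm_um=0.1)


class TestPropagationLength:
    def test_closed_form_confocal_parameter(self):
        beam = BeamState("thin", 0.327, 0.0, 488.0, 1.333)
        length, flag = propagation_length(beam)
        assert length == pytest.approx(1.84, abs=0.01)
        assert not flag

    def test_monotone_in_waist(self):
        lengths = [
            propagation_length(BeamState("thin", w0, 0.0, 488.0, 1.333))[0]
            for w0 in (0.2, 0.3, 0.5, 1.0)
        ]
        assert np.all(np.diff(lengths) > 0)

    def test_profile_estimate_near_confocal_parameter(self):
        prof = simulate_sheet_profile(
            0.475, "gaussian",
            z_spacing_um=0.02, z_extent_um=4.0,
            y_spacing_um=0.02, y_extent_um=6.0,
        )
        w0 = 0.488 / (np.pi * 0.475)
        expected = 2 * np.pi * w0**2 * 1.333 / 0.488
        length, flag = propagation_length(prof)
        assert not flag
        assert length == pytest.approx(expected, rel=0.1)

    def test_boundary_flag_when_waist_fills_grid(self):
        prof = simulate_sheet_profile(
            0.475, "gaussian",
            z_spacing_um=0.02, z_extent_um=4.0,
            y_spacing_um=0.1, y_extent_um=1.0,
        )
        length, flag = propagation_length(prof)
        assert flag
        assert length <= 1.0


class TestProfileFwhm:
    def test_exact_on_analytic_gaussian(self):
        x = np.arange(-3, 3, 0.01)
        sigma = 0.4
        fwhm = profile_fwhm(np.exp(-x**2 / (2 * sigma**2)), 0.01)
        assert fwhm == pytest.approx(2.355 * sigma, rel=1e-3)

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError):
            profile_fwhm(np.ones(100), 0.01)
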