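"""Closed-form detection-path sampling, resolution and timing calculators.

The detection arm pairs a high-NA water-dipping objective with a tube lens
longer than the objective's reference tube length, trading field of view
for magnification so that the camera pixel pitch lands at Nyquist sampling
of the lateral resolution.  Acquisition timing treats the sample-scanning
piezo as a first-order system and the frame period as exposure plus camera
dead time.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, sqrt

__all__ = [
    "DetectionPath",
    "TimingModel",
    "sampling_summary",
    "detection_psf_fwhm",
    "combined_axial_fwhm",
    "piezo_response_time",
    "volumetric_rate",
]


@dataclass(frozen=True)
class DetectionPath:
    """Detection-arm description.

    The 6.5 µm camera pixel pitch is the vendor specification of the
    sCMOS camera assumed by the default configuration; override it for
    other sensors.
    """

    objective_nominal_mag: float = 25.0
    objective_reference_tube_mm: float = 200.0
    objective_na: float = 1.1
    immersion_index: float = 1.333
    tube_lens_focal_mm: float = 400.0
    camera_pixel_pitch_um: float = 6.5
    sensor_width_px: int = 2048
    emission_wavelength_nm: float = 510.0
    galvo_frequency_hz: float = 4000.0

    def __post_init__(self) -> None:
        if self.objective_na >= self.immersion_index:
            raise ValueError("NA must be below the immersion index")
        for name in (
            "objective_nominal_mag",
            "objective_reference_tube_mm",
            "objective_na",
            "tube_lens_focal_mm",
            "camera_pixel_pitch_um",
            "emission_wavelength_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TimingModel:
    """Acquisition timing inputs for a sample-scanned z-stack."""

    exposure_ms: float = 10.0
    dead_time_ms: float = 7.25
    z_range_um: float = 50.0
    z_step_um: float = 0.25
    piezo_resonant_frequency_hz: float | None = None

    def __post_init__(self) -> None:
        if self.exposure_ms <= 0:
            raise ValueError("exposure must be positive")
        if self.dead_time_ms < 0:
            raise ValueError("dead time must be >= 0")


def sampling_summary(path: DetectionPath) -> dict:
    """Magnification, sample-referred pixel size, field of view, Nyquist margin.

    magnification = nominal_mag * tube_lens_focal / reference_tube;
    pixel_size = pitch / magnification; fov = pixel_size * sensor width.
    nyquist_margin = lateral resolution / (2 * pixel size): >= 1 means the
    camera samples at or finer than Nyquist.
    """
    mag = path.objective_nominal_mag * path.tube_lens_focal_mm / path.objective_reference_tube_mm
    if mag <= 0:
        raise ValueError("magnification must be positive")
    pixel_nm = path.camera_pixel_pitch_um * 1e3 / mag
    fov_um = pixel_nm * path.sensor_width_px * 1e-3
    res = detection_psf_fwhm(
        path.objective_na, path.emission_wavelength_nm, path.immersion_index
    )
    return {
        "magnification": mag,
        "pixel_size_nm": pixel_nm,
        "fov_um": fov_um,
        "nyquist_margin": res["lateral_nm"] / (2.0 * pixel_nm),
        "galvo_period_ms": 1e3 / path.galvo_frequency_hz,
    }


def detection_psf_fwhm(
    na: float,
    wavelength_nm: float,
    n: float,
    lateral_constant: float = 0.51,
    axial_constant: float = 0.88,
) -> dict:
    """Conventional widefield resolution estimates (nm).

    lateral = c_lat * lambda / NA, axial = c_ax * lambda / (n - sqrt(n^2 - NA^2)).
    The constants are the standard conventions and are overridable since
    published targets are typically rounded.
    """
    if not 0 < na < n:
        raise ValueError("need 0 < NA < n")
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    lateral = lateral_constant * wavelength_nm / na
    axial = axial_constant * wavelength_nm / (n - sqrt(n * n - na * na))
    return {"lateral_nm": lateral, "axial_nm": axial}


def combined_axial_fwhm(detection_axial_nm: float, sheet_fwhm_nm: float) -> float:
    """System axial FWHM from detection depth of focus and sheet thickness.

    Gaussian quadrature combination: 1/F^2 = 1/F_det^2 + 1/F_sheet^2.
    """
    if detection_axial_nm <= 0 or sheet_fwhm_nm <= 0:
        raise ValueError("FWHMs must be positive")
    return 1.0 / sqrt(detection_axial_nm**-2 + sheet_fwhm_nm**-2)


def piezo_response_time(resonant_frequency_hz: float) -> float:
    """First-order piezo response time t = 0.35 / f, in milliseconds."""
    if resonant_frequency_hz <= 0:
        raise ValueError("resonant frequency must be positive")
    return 0.35 / resonant_frequency_hz * 1e3


def volumetric_rate(timing: TimingModel) -> dict:
    """Frame rate, slice count and stack duration for a z-stack.

    frame_rate = 1000 / (exposure_ms + dead_ms); n_slices = ceil(range/step).
    Dead time is an input (camera readout + piezo settling), not a
    prediction; pass the best-case or average value as appropriate.
    """
    if timing.z_step_um <= 0:
        raise ValueError("z step must be positive")
    frame_rate = 1e3 / (timing.exposure_ms + timing.dead_time_ms)
    n_slices = ceil(timing.z_range_um / timing.z_step_um)
    out = {
        "frame_rate_hz": frame_rate,
        "n_slices": n_slices,
        "stack_duration_s": n_slices / frame_rate,
    }
    if timing.piezo_resonant_frequency_hz:
        out["piezo_response_ms"] = piezo_response_time(timing.piezo_resonant_frequency_hz)
    return out
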