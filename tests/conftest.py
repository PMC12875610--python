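"""Shared fixtures: the nominal train and synthetic bead-characterization chains."""

from __future__ import annotations

import numpy as np
import pytest

from lsfmkit import imaging, optics, pipeline, psf

#: pre-deconvolution bead widths (z, y, x) nm the synthetic stacks emulate
SYSTEM_FWHM_NM = (464.0, 330.0, 328.0)


@pytest.fixture(scope="session")
def nominal_train():
    return optics.nominal_train()


@pytest.fixture(scope="session")
def acquisition_geometry():
    return imaging.AcquisitionGeometry(camera_roi=(160, 320), n_slices=80)


@pytest.fixture(scope="session")
def system_psf(acquisition_geometry):
    g = acquisition_geometry
    voxel = (g.z_spacing_um, g.pixel_size_um, g.pixel_size_um)
    return psf.gaussian_psf(SYSTEM_FWHM_NM, voxel)


def make_bead_truth(geometry, n=55, seed=11, photons=10000.0, min_sep=2.0):
    drift = int(np.ceil((geometry.n_slices - 1) * geometry.shift_px_per_slice))
    volume = (
        geometry.n_slices * geometry.z_spacing_um,
        geometry.camera_roi[0] * geometry.pixel_size_um,
        (geometry.camera_roi[1] - drift) * geometry.pixel_size_um,
    )
    return imaging.generate_bead_field(
        n, volume, min_separation_um=min_sep, seed=seed, intensity_photons=photons
    )


@pytest.fixture(scope="session")
def bead_truth(acquisition_geometry):
    return make_bead_truth(acquisition_geometry)


@pytest.fixture(scope="session")
def noiseless_chain(acquisition_geometry, system_psf, bead_truth):
    """Render -> deskew with no shot/read noise: the geometry round trip."""
    camera = imaging.CameraModel(shot_noise=False)
    raw = imaging.render_skewed_stack(
        bead_truth, system_psf, acquisition_geometry, camera, seed=1
    )
    desk, voxel, meta = pipeline.deskew(raw)
    return {"raw": raw, "deskewed": desk, "voxel_um": voxel, "meta": meta}


@pytest.fixture(scope="session")
def noisy_chain(acquisition_geometry, system_psf, bead_truth):
    """Render -> deskew -> deconvolve with Poisson noise, published parameters."""
    camera = imaging.CameraModel(shot_noise=True)
    raw = imaging.render_skewed_stack(
        bead_truth, system_psf, acquisition_geometry, camera, seed=1
    )
    desk, voxel, meta = pipeline.deskew(raw)
    dec = pipeline.omw_deconvolve(desk, system_psf, voxel_um=voxel).astype(float)
    return {"raw": raw, "deskewed": desk, "deconvolved": dec, "voxel_um": voxel}
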