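"""3D point-spread-function models for the detection path.

Two generators are provided: a separable Gaussian kernel with prescribed
per-axis intensity FWHM (an analytic stand-in used throughout the synthetic
pipeline) and a scalar-diffraction PSF obtained from the radially symmetric
defocused-pupil (Debye) integral, the open model of the high-NA detection
objective.  A light-sheet's axial intensity envelope can be multiplied onto
a detection PSF to form the system PSF of the microscope.

Array axis order is (z, y, x) throughout; triple-valued parameters follow
the same (z, y, x) order.  PSF volumes are normalized to unit sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import j0

from lsfmkit.optics import profile_fwhm

__all__ = [
    "PSFModel",
    "gaussian_psf",
    "scalar_psf",
    "apply_sheet_envelope",
    "volume_fwhm",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PSFModel:
    """Unit-sum 3D PSF on an odd-sized grid with the peak at the center voxel."""

    intensity: np.ndarray  # (z, y, x), sum == 1
    voxel_um: tuple[float, float, float]  # (z, y, x)
    model_kind: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.intensity.ndim != 3:
            raise ValueError("PSF must be 3D")
        if any(s % 2 == 0 for s in self.intensity.shape):
            raise ValueError("PSF grid must be odd-sized on every axis")
        if any(v <= 0 for v in self.voxel_um):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    def measured_fwhm_nm(self) -> tuple[float, float, float]:
        return volume_fwhm(self.intensity, self.voxel_um)


def volume_fwhm(
    volume: np.ndarray, voxel_um: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Per-axis intensity FWHM (nm) of the line profiles through the peak."""
    idx = np.unravel_index(np.argmax(volume), volume.shape)
    lines = (
        volume[:, idx[1], idx[2]],
        volume[idx[0], :, idx[2]],
        volume[idx[0], idx[1], :],
    )
    return tuple(
        profile_fwhm(line, voxel_um[ax]) * 1e3 for ax, line in enumerate(lines)
    )


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def gaussian_psf(
    fwhm_nm: tuple[float, float, float],
    voxel_um: tuple[float, float, float],
    shape: tuple[int, int, int] | None = None,
) -> PSFModel:
    """Separable Gaussian PSF with per-axis intensity FWHM (z, y, x order).

    If ``shape`` is omitted an odd grid covering ~6 FWHM per axis is used.
    """
    fwhm_um = tuple(f * 1e-3 for f in fwhm_nm)
    if any(f <= 0 for f in fwhm_um):
        raise ValueError("FWHM must be positive")
    if shape is None:
        shape = tuple(_odd(int(np.ceil(6 * f / v)) + 1) for f, v in zip(fwhm_um, voxel_um))
    for ax in range(3):
        if shape[ax] % 2 == 0:
            raise ValueError("shape must be odd on every axis")
        if (shape[ax] - 1) * voxel_um[ax] < 4 * fwhm_um[ax]:
            raise ValueError("grid extent must cover >= 4x FWHM per axis")
        if voxel_um[ax] > fwhm_um[ax] / 2:
            raise ValueError("voxel size must be <= FWHM/2 per axis")
    profiles = []
    for ax in range(3):
        c = (np.arange(shape[ax]) - shape[ax] // 2) * voxel_um[ax]
        sigma = fwhm_um[ax] * _FWHM_TO_SIGMA
        profiles.append(np.exp(-(c**2) / (2 * sigma**2)))
    vol = profiles[0][:, None, None] * profiles[1][None, :, None] * profiles[2][None, None, :]
    vol /= vol.sum()
    return PSFModel(
        intensity=vol,
        voxel_um=tuple(voxel_um),
        model_kind="gaussian",
        metadata={"fwhm_nm": tuple(fwhm_nm)},
    )


def scalar_psf(
    na: float,
    wavelength_nm: float,
    n: float = 1.3333,
    voxel_um: tuple[float, float, float] = (0.125, 0.065, 0.065),
    shape: tuple[int, int, int] = (33, 65, 65),
    n_quad: int = 256,
) -> PSFModel:
    """Scalar-diffraction detection PSF from the radial Debye pupil integral.

    E(r, z) = int_0^alpha sqrt(cos t) J0(k n r sin t) exp(i k n z cos t) sin t dt,
    with sin(alpha) = NA/n and k = 2 pi / lambda_vac; intensity |E|^2 is
    radially symmetric in (x, y) and symmetric in z for the unaberrated pupil.
    """
    if not 0 < na < n:
        raise ValueError("need 0 < NA < n")
    if any(s % 2 == 0 for s in shape):
        raise ValueError("shape must be odd on every axis")
    lam_um = wavelength_nm * 1e-3
    # sampling checks against the analytic estimates
    lat_fwhm_um = 0.51 * lam_um / na
    if max(voxel_um[1], voxel_um[2]) > lat_fwhm_um / 3:
        raise ValueError("lateral voxel too coarse for this NA")
    alpha = np.arcsin(na / n)
    theta, wq = np.polynomial.legendre.leggauss(n_quad)
    theta = 0.5 * alpha * (theta + 1.0)
    wq = 0.5 * alpha * wq
    k = 2 * np.pi / lam_um
    st, ct = np.sin(theta), np.cos(theta)
    apod = np.sqrt(ct) * st * wq

    nz, ny, nx = shape
    zs = (np.arange(nz) - nz // 2) * voxel_um[0]
    yy = (np.arange(ny) - ny // 2) * voxel_um[1]
    xx = (np.arange(nx) - nx // 2) * voxel_um[2]
    r_grid = np.sqrt(yy[:, None] ** 2 + xx[None, :] ** 2)
    r_max = r_grid.max()
    nr = 4 * max(ny, nx)
    rs = np.linspace(0.0, r_max, nr)

    bessel = j0(k * n * np.outer(rs, st))  # (nr, n_quad)
    vol = np.empty(shape)
    for iz, z in enumerate(zs):
        defocus = np.exp(1j * k * n * z * ct) * apod
        e_r = bessel @ defocus
        i_r = np.abs(e_r) ** 2
        vol[iz] = np.interp(r_grid.ravel(), rs, i_r).reshape(ny, nx)
    vol /= vol.sum()
    return PSFModel(
        intensity=vol,
        voxel_um=tuple(voxel_um),
        model_kind="scalar-diffraction",
        metadata={"na": na, "wavelength_nm": wavelength_nm, "n": n},
    )


def apply_sheet_envelope(
    psf: PSFModel,
    sheet_axial_profile: np.ndarray,
    profile_spacing_um: float | None = None,
) -> PSFModel:
    """Multiply a detection PSF by the sheet's axial intensity envelope.

    ``sheet_axial_profile`` is 1D intensity versus z, centered on the sheet
    waist.  If its spacing differs from the PSF z voxel it is linearly
    resampled onto the PSF z grid (``profile_spacing_um`` required then).
    """
    prof = np.asarray(sheet_axial_profile, dtype=float)
    nz = psf.shape[0]
    if profile_spacing_um is None:
        if prof.size != nz:
            raise ValueError(
                "envelope length differs from PSF z size; pass profile_spacing_um"
            )
        env = prof
    else:
        z_psf = (np.arange(nz) - nz // 2) * psf.voxel_um[0]
        z_prof = (np.arange(prof.size) - prof.size // 2) * profile_spacing_um
        env = np.interp(z_psf, z_prof, prof, left=0.0, right=0.0)
    if np.any(env < 0):
        raise ValueError("envelope must be non-negative")
    vol = psf.intensity * env[:, None, None]
    total = vol.sum()
    if total <= 0:
        raise ValueError("envelope annihilates the PSF")
    vol = vol / total
    meta = dict(psf.metadata)
    try:
        meta["sheet_fwhm_nm"] = profile_fwhm(
            env, psf.voxel_um[0]
        ) * 1e3
    except ValueError:
        pass
    return PSFModel(
        intensity=vol,
        voxel_um=psf.voxel_um,
        model_kind=psf.model_kind,
        metadata=meta,
    )
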