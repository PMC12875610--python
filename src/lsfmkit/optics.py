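"""Illumination-train Gaussian beam propagation and light-sheet simulation.

The illumination arm of a sample-scanning light-sheet microscope is modelled
per axis as a Gaussian beam propagated through a sequence of ideal elements
(thin lenses, a cylindrical lens, apertures, fold mirrors, the illumination
objective) by ray-transfer (ABCD) matrices acting on the complex beam
parameter q.  The two transverse axes follow the usual light-sheet
convention: the *thin* axis is Z (the detection axis, across the sheet), the
*wide* axis is X (in the plane of the sheet); Y is the propagation
direction.

The sheet's focal-plane profile is computed by 1D coherent angular-spectrum
propagation of the (possibly slit-truncated) pupil field; the wide axis is
treated as separable.  All lengths are stored in consistent units: element
geometry in mm, transverse beam/sheet coordinates in µm, wavelengths in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import yaml

__all__ = [
    "OpticalElement",
    "OpticalTrain",
    "BeamState",
    "SheetProfile",
    "load_train",
    "nominal_train",
    "propagate_train",
    "effective_na_at_sample",
    "gaussian_sheet_fwhm",
    "simulate_sheet_profile",
    "propagation_length",
    "calibrate_aperture",
    "profile_fwhm",
]

ElementKind = Literal[
    "thin-lens", "cylindrical-lens", "aperture", "fold-mirror", "objective"
]

#: intensity-FWHM of a Gaussian = FWHM_FACTOR * (1/e^2 radius)
FWHM_FACTOR = float(np.sqrt(2.0 * np.log(2.0)))


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalElement:
    """One element of the unfolded illumination path.

    Focal lengths are given per transverse axis; a spherical thin lens has
    equal finite focal lengths, a cylindrical lens exactly one, apertures
    and mirrors none.  ``axial_position_mm`` is measured along the unfolded
    optical axis from the first element.
    """

    kind: ElementKind
    axial_position_mm: float
    focal_length_thin_mm: float | None = None
    focal_length_wide_mm: float | None = None
    clear_half_aperture_mm: float | None = None
    numerical_aperture: float | None = None  # objectives only
    label: str = ""

    def __post_init__(self) -> None:
        for f in (self.focal_length_thin_mm, self.focal_length_wide_mm):
            if f is not None and f == 0:
                raise ValueError(f"zero focal length on element {self.label!r}")
        if self.kind == "thin-lens":
            if self.focal_length_thin_mm is None or self.focal_length_wide_mm is None:
                raise ValueError("thin lens needs finite focal length on both axes")
            if self.focal_length_thin_mm != self.focal_length_wide_mm:
                raise ValueError("thin lens must have equal focal lengths per axis")
        elif self.kind == "cylindrical-lens":
            n_finite = sum(
                f is not None
                for f in (self.focal_length_thin_mm, self.focal_length_wide_mm)
            )
            if n_finite != 1:
                raise ValueError("cylindrical lens has exactly one finite-focal axis")
        elif self.kind in ("aperture", "fold-mirror"):
            if self.focal_length_thin_mm is not None or self.focal_length_wide_mm is not None:
                raise ValueError(f"{self.kind} carries no focal power")
        elif self.kind == "objective":
            if self.focal_length_thin_mm is None:
                raise ValueError("objective needs a focal length")

    def focal_length(self, axis: str) -> float | None:
        return self.focal_length_thin_mm if axis == "thin" else self.focal_length_wide_mm


@dataclass(frozen=True)
class OpticalTrain:
    """Ordered illumination train plus the input beam it receives."""

    elements: tuple[OpticalElement, ...]
    input_beam_diameter_mm: float = 2.0
    wavelength_nm: float = 488.0
    immersion_index: float = 1.333

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("train needs at least one element")
        if self.input_beam_diameter_mm <= 0:
            raise ValueError("input beam diameter must be positive")
        if self.immersion_index < 1:
            raise ValueError("immersion index must be >= 1")
        pos = [e.axial_position_mm for e in self.elements]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("element axial positions must be strictly increasing")

    @property
    def objective(self) -> OpticalElement:
        for e in reversed(self.elements):
            if e.kind == "objective":
                return e
        raise ValueError("train has no objective")

    @property
    def sample_plane_mm(self) -> float:
        """Nominal focal plane of the immersed objective.

        The objective is modeled as an ideal thin lens followed by a flat
        interface into the immersion medium, which places the focus of a
        collimated input at n times the air-side focal length.
        """
        obj = self.objective
        return obj.axial_position_mm + self.immersion_index * float(obj.focal_length_thin_mm)

    def aperture_elements(self) -> list[OpticalElement]:
        return [e for e in self.elements if e.kind == "aperture"]

    def with_aperture_width(self, width_mm: float | None) -> "OpticalTrain":
        """Return a copy with every aperture's half-width set to width/2."""
        half = None if width_mm is None else width_mm / 2.0
        new = tuple(
            replace(e, clear_half_aperture_mm=half) if e.kind == "aperture" else e
            for e in self.elements
        )
        return replace(self, elements=new)


@dataclass
class BeamState:
    """Gaussian beam at the sample plane for one transverse axis."""

    axis: Literal["thin", "wide"]
    waist_radius_um: float
    waist_position_mm: float
    wavelength_nm: float
    medium_index: float
    truncation_flag: bool = False
    pupil_radius_mm: float | None = None  # 1/e^2 fill at the objective pupil

    @property
    def rayleigh_range_um(self) -> float:
        w0 = self.waist_radius_um
        return float(np.pi * w0 * w0 * self.medium_index / (self.wavelength_nm * 1e-3))


@dataclass
class SheetProfile:
    """Peak-normalized sheet intensity on a (thin Z x propagation Y) grid."""

    intensity: np.ndarray  # shape (nz, ny), max 1
    z_spacing_um: float
    y_spacing_um: float
    na_eff: float
    pupil_shape: str
    metadata: dict = field(default_factory=dict)

    @property
    def z_coords_um(self) -> np.ndarray:
        nz = self.intensity.shape[0]
        return (np.arange(nz) - nz // 2) * self.z_spacing_um

    @property
    def y_coords_um(self) -> np.ndarray:
        ny = self.intensity.shape[1]
        return (np.arange(ny) - ny // 2) * self.y_spacing_um

    def focal_cross_section(self) -> np.ndarray:
        return self.intensity[:, self.intensity.shape[1] // 2]


# --------------------------------------------------------------------------
# train loading
# --------------------------------------------------------------------------

def load_train(source) -> OpticalTrain:
    """Load an :class:`OpticalTrain` from a YAML path, file object or dict."""
    if isinstance(source, dict):
        cfg = source
    elif hasattr(source, "read"):
        cfg = yaml.safe_load(source.read())
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    elements = tuple(
        OpticalElement(
            kind=e["kind"],
            axial_position_mm=float(e["axial_position_mm"]),
            focal_length_thin_mm=_opt(e.get("focal_length_thin_mm")),
            focal_length_wide_mm=_opt(e.get("focal_length_wide_mm")),
            clear_half_aperture_mm=_opt(e.get("clear_half_aperture_mm")),
            numerical_aperture=_opt(e.get("numerical_aperture")),
            label=e.get("label", ""),
        )
        for e in cfg["elements"]
    )
    return OpticalTrain(
        elements=elements,
        input_beam_diameter_mm=float(cfg.get("input_beam_diameter_mm", 2.0)),
        wavelength_nm=float(cfg.get("wavelength_nm", 488.0)),
        immersion_index=float(cfg.get("immersion_index", 1.333)),
    )


def _opt(v):
    return None if v is None else float(v)


def nominal_train() -> OpticalTrain:
    """The bundled nominal illumination train.

    A 2 mm collimated 488 nm beam reflects off the resonant galvo and a fold
    mirror, is expanded by an f=30/f=80 telescope, clipped by a rectangular
    slit, line-focused on the thin axis by an f=75 cylindrical lens, relayed
    by an f=250 lens whose back focal plane coincides with the pupil of a
    20x (f=10 mm) NA 0.6 water-dipping illumination objective.
    """
    from importlib.resources import files

    with (files("lsfmkit") / "data" / "nominal_train.yaml").open() as fh:
        return load_train(fh)


# --------------------------------------------------------------------------
# ABCD propagation
# --------------------------------------------------------------------------

def _q_from_waist(waist_radius_mm: float, wavelength_mm: float) -> complex:
    zr = np.pi * waist_radius_mm**2 / wavelength_mm
    return 1j * zr


def _beam_radius_mm(q: complex, wavelength_mm: float) -> float:
    inv = 1.0 / q
    return float(np.sqrt(-wavelength_mm / (np.pi * inv.imag)))


def propagate_train(train: OpticalTrain, axis: Literal["thin", "wide"]) -> BeamState:
    """Propagate the input Gaussian beam through the train on one axis.

    The complex beam parameter is advanced element by element; the beam is
    assumed to travel in air up to (and including) the objective, then in the
    immersion medium, so sample-side waist formulas use the immersion index.
    Apertures are not diffracted here: when the 1/e^2 beam radius exceeds a
    clear half-aperture (or implies an NA above the objective's) the
    truncation flag is set and the sheet simulator handles the clipped pupil.
    """
    if axis not in ("thin", "wide"):
        raise ValueError(f"axis must be 'thin' or 'wide', got {axis!r}")
    lam_vac_mm = train.wavelength_nm * 1e-6
    q = _q_from_waist(train.input_beam_diameter_mm / 2.0, lam_vac_mm)
    z = 0.0
    lam = lam_vac_mm  # wavelength in the current medium
    truncated = False
    pupil_radius = None
    for el in train.elements:
        q = q + (el.axial_position_mm - z)
        z = el.axial_position_mm
        w_here = _beam_radius_mm(q, lam)
        if el.clear_half_aperture_mm is not None and w_here > el.clear_half_aperture_mm:
            truncated = True
        f = el.focal_length(axis)
        if el.kind == "objective":
            pupil_radius = w_here
            if el.numerical_aperture is not None:
                geom_na = w_here / float(f)
                if geom_na > el.numerical_aperture:
                    truncated = True
            # ideal thin lens, then a flat interface into the immersion
            # medium: q scales by n and the in-medium wavelength applies
            q = train.immersion_index / (1.0 / q - 1.0 / float(f))
            lam = lam_vac_mm / train.immersion_index
        elif f is not None:
            q = 1.0 / (1.0 / q - 1.0 / float(f))
    # waist after the last element: q(z) = (z - z_w) + i zR
    z_w = z - q.real
    zr = q.imag
    w0_mm = float(np.sqrt(zr * lam / np.pi))
    n_medium = train.immersion_index if lam != lam_vac_mm else 1.0
    return BeamState(
        axis=axis,
        waist_radius_um=w0_mm * 1e3,
        waist_position_mm=z_w,
        wavelength_nm=train.wavelength_nm,
        medium_index=n_medium,
        truncation_flag=truncated,
        pupil_radius_mm=pupil_radius,
    )


def effective_na_at_sample(beam: BeamState, objective_na: float) -> float:
    """Effective focusing NA of the sheet-thin axis at the sample.

    NA_eff = lambda_vac / (pi * w0) for the Gaussian waist; capped at the
    objective NA (with the beam's truncation flag set) when the geometric
    pupil fill implies a larger cone than the objective can pass.
    """
    if beam.waist_radius_um <= 0:
        raise ValueError("waist radius must be positive")
    if not 0 < objective_na < beam.medium_index:
        raise ValueError("objective NA must lie in (0, medium index)")
    na = beam.wavelength_nm * 1e-3 / (np.pi * beam.waist_radius_um)
    if na > objective_na:
        beam.truncation_flag = True
        return objective_na
    return float(na)


def gaussian_sheet_fwhm(na: float, wavelength_nm: float) -> float:
    """Intensity FWHM (µm) of a Gaussian sheet waist at effective NA ``na``.

    FWHM = sqrt(2 ln 2) * lambda_vac / (pi * NA).
    """
    if not 0 < na < 1.6:
        raise ValueError("NA out of range (0, 1.6)")
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return FWHM_FACTOR * wavelength_nm * 1e-3 / (np.pi * na)


# --------------------------------------------------------------------------
# sheet diffraction simulation
# --------------------------------------------------------------------------

def profile_fwhm(values: np.ndarray, spacing: float) -> float:
    """FWHM of a sampled peaked profile via linear half-max crossings."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("profile too short")
    peak = v.max()
    if peak <= 0 or np.isclose(v.min(), peak):
        raise ValueError("profile has no identifiable peak")
    half = peak / 2.0
    i0 = int(np.argmax(v))
    # walk outwards to the half-max crossings
    left = i0
    while left > 0 and v[left] > half:
        left -= 1
    if v[left] > half:
        raise ValueError("half-max not reached inside the grid (left)")
    right = i0
    n = v.size
    while right < n - 1 and v[right] > half:
        right += 1
    if v[right] > half:
        raise ValueError("half-max not reached inside the grid (right)")
    xl = left + (half - v[left]) / (v[left + 1] - v[left])
    xr = right - (half - v[right]) / (v[right - 1] - v[right])
    return float((xr - xl) * spacing)


def _thin_axis_pupil_na(train: OpticalTrain) -> tuple[float, float | None, float]:
    """(Gaussian 1/e^2 NA, slit-cut NA or None, objective NA) on the thin axis.

    The Gaussian fill is traced by ABCD; the slit edge is imaged onto the
    pupil by tracing a field-free paraxial ray from the aperture plane.
    """
    obj = train.objective
    f_obj = float(obj.focal_length_thin_mm)
    # untruncated Gaussian pupil fill; NA of a marginal ray at fill radius
    # h is h/f for the immersed ideal objective (sin theta_medium = h/(n f))
    open_train = train.with_aperture_width(None)
    beam = propagate_train(open_train, "thin")
    if beam.pupil_radius_mm is None:
        raise ValueError("train has no objective pupil")
    na_gauss = beam.pupil_radius_mm / f_obj
    # slit edge -> pupil magnification via paraxial ray trace (h=1, u=0)
    apertures = train.aperture_elements()
    na_cut = None
    for ap in apertures:
        if ap.clear_half_aperture_mm is None:
            continue
        start = ap.axial_position_mm
        h, u, z = 1.0, 0.0, start
        for el in train.elements:
            if el.axial_position_mm <= start:
                continue
            h = h + u * (el.axial_position_mm - z)
            z = el.axial_position_mm
            if el.kind == "objective":
                break
            f = el.focal_length("thin")
            if f is not None:
                u = u - h / float(f)
        mag = abs(h)
        this_cut = ap.clear_half_aperture_mm * mag / f_obj
        na_cut = this_cut if na_cut is None else min(na_cut, this_cut)
    obj_na = obj.numerical_aperture if obj.numerical_aperture is not None else n
    return float(na_gauss), na_cut, float(obj_na)


def simulate_sheet_profile(
    source: OpticalTrain | float,
    pupil_shape: Literal["gaussian", "slit"] = "gaussian",
    aperture_width_mm: float | None = None,
    z_spacing_um: float = 0.02,
    z_extent_um: float = 4.0,
    y_spacing_um: float = 0.1,
    y_extent_um: float = 8.0,
) -> SheetProfile:
    """Simulate the light-sheet intensity in the thin(Z) x propagation(Y) plane.

    ``source`` is either an effective NA (float) paired with ``pupil_shape``,
    or an :class:`OpticalTrain`, in which case the pupil is the ABCD-traced
    Gaussian fill hard-clipped by the slit aperture (optionally overridden by
    ``aperture_width_mm``) and the objective NA.  The focal field is the 1D
    Fourier transform of the pupil; through-focus planes are obtained by
    angular-spectrum phase propagation in the immersion medium.
    """
    if isinstance(source, OpticalTrain):
        train = source
        if aperture_width_mm is not None:
            train = train.with_aperture_width(aperture_width_mm)
        lam_nm = train.wavelength_nm
        n_med = train.immersion_index
        na_gauss, na_cut, na_obj = _thin_axis_pupil_na(train)
        na_max = min(
            x
            for x in (na_gauss * 3, na_cut, na_obj, 0.999 * train.immersion_index)
            if x is not None
        )
        pupil_desc = "truncated-gaussian" if na_cut is not None else "gaussian"
        na_check = na_max
    else:
        na = float(source)
        if not 0 < na < 1.6:
            raise ValueError("NA out of range")
        lam_nm, n_med = 488.0, 1.333
        if pupil_shape == "gaussian":
            # na is the 1/e^2 intensity fill; support extends well beyond it
            na_gauss = na
            na_max = min(3.0 * na, 0.999 * n_med)
            na_check = na
        else:
            na_gauss = None
            na_max = na
            na_check = na
        pupil_desc = pupil_shape

    lam_um = lam_nm * 1e-3
    if na_max >= n_med:
        raise ValueError("pupil NA must be below the medium index")

    # expected FWHM for grid validation (slit pupils are narrower than the
    # Gaussian formula, so this is conservative)
    exp_fwhm = gaussian_sheet_fwhm(min(na_check, 1.59), lam_nm)
    if z_spacing_um > exp_fwhm / 8:
        raise ValueError("z grid spacing too coarse (need <= FWHM/8)")
    if z_extent_um < 4 * exp_fwhm:
        raise ValueError("z extent must cover >= 4x FWHM")

    nz = int(2 ** np.ceil(np.log2(max(256, z_extent_um / z_spacing_um))))
    nu = np.fft.fftfreq(nz, d=z_spacing_um)  # cycles/µm along Z
    dnu = 1.0 / (nz * z_spacing_um)
    nu_cut = na_max / lam_um
    # fractional bin coverage anti-aliases the hard pupil edge so metrics
    # vary continuously with aperture width
    coverage = np.clip((nu_cut - np.abs(nu)) / dnu + 0.5, 0.0, 1.0)
    if pupil_desc == "slit":
        pupil = coverage.astype(complex)
    else:
        if na_gauss is None:
            raise ValueError("gaussian pupil needs a Gaussian fill NA")
        pupil = (np.exp(-((lam_um * nu / na_gauss) ** 2)) * coverage).astype(complex)
    if not np.any(np.abs(pupil) > 0):
        raise ValueError("pupil is empty; aperture wider than pupil or NA zero")

    ny = int(np.round(y_extent_um / y_spacing_um)) | 1
    ys = (np.arange(ny) - ny // 2) * y_spacing_um
    kz2 = (n_med / lam_um) ** 2 - nu**2
    kappa = np.sqrt(np.maximum(kz2, 0.0))
    kappa0 = n_med / lam_um
    intensity = np.empty((nz, ny))
    for j, y in enumerate(ys):
        # subtract the carrier so the defocus phase stays well-sampled
        field = np.fft.ifft(pupil * np.exp(2j * np.pi * y * (kappa - kappa0)))
        intensity[:, j] = np.abs(np.fft.fftshift(field)) ** 2
    intensity /= intensity.max()

    focal = intensity[:, ny // 2]
    fwhm = profile_fwhm(focal, z_spacing_um)
    na_eff = FWHM_FACTOR * lam_um / (np.pi * fwhm)
    return SheetProfile(
        intensity=intensity,
        z_spacing_um=z_spacing_um,
        y_spacing_um=y_spacing_um,
        na_eff=float(na_eff),
        pupil_shape=pupil_desc,
        metadata={
            "wavelength_nm": lam_nm,
            "medium_index": n_med,
            "fwhm_um": fwhm,
            "na_pupil_max": float(na_max),
        },
    )


def propagation_length(obj: SheetProfile | BeamState) -> tuple[float, bool]:
    """Length (µm) over which sheet thickness stays <= sqrt(2) x its minimum.

    For an analytic Gaussian beam this equals the confocal parameter
    2 z_R = 2 pi w0^2 n / lambda_vac.  Returns (length, boundary_flag); the
    flag is set when the sub-sqrt(2) region extends to the grid edge.
    """
    if isinstance(obj, BeamState):
        return 2.0 * obj.rayleigh_range_um, False
    prof = obj
    ny = prof.intensity.shape[1]
    widths = np.full(ny, np.nan)
    for j in range(ny):
        try:
            widths[j] = profile_fwhm(prof.intensity[:, j], prof.z_spacing_um)
        except ValueError:
            widths[j] = np.nan
    if np.all(np.isnan(widths)):
        raise ValueError("profile has no identifiable waist")
    wmin = np.nanmin(widths)
    ok = widths <= np.sqrt(2.0) * wmin
    ok &= ~np.isnan(widths)
    j0 = int(np.nanargmin(widths))
    lo = j0
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = j0
    while hi < ny - 1 and ok[hi + 1]:
        hi += 1
    boundary = lo == 0 or hi == ny - 1
    return float((hi - lo) * prof.y_spacing_um), boundary


# --------------------------------------------------------------------------
# aperture calibration
# --------------------------------------------------------------------------

def calibrate_aperture(
    train: OpticalTrain,
    target_fwhm_um: float = 0.385,
    width_bounds_mm: tuple[float, float] = (0.6, 6.0),
    tol_um: float = 1e-4,
    **grid_kwargs,
) -> dict:
    """Find the slit width whose simulated focal-plane FWHM hits the target.

    The slit width is the one free parameter of the illumination design (it
    is set on the bench, not by the mechanical drawings); monotone bisection
    on width solves FWHM(width) = target.  Returns a dict with the
    calibrated width, the achieved FWHM and the effective NA implied by it.
    """

    # the focal FWHM only needs the y=0 plane; keep the y grid minimal
    grid_kwargs.setdefault("z_extent_um", 8.0)
    grid_kwargs.setdefault("y_extent_um", 1.0)
    grid_kwargs.setdefault("y_spacing_um", 0.25)

    def fwhm_of(width: float) -> float:
        prof = simulate_sheet_profile(train, aperture_width_mm=width, **grid_kwargs)
        return prof.metadata["fwhm_um"]

    lo, hi = width_bounds_mm
    f_lo, f_hi = fwhm_of(lo), fwhm_of(hi)
    if not (f_hi <= target_fwhm_um <= f_lo):
        raise ValueError(
            f"target FWHM {target_fwhm_um} µm not bracketed by widths "
            f"{width_bounds_mm} (FWHM {f_lo:.4f}..{f_hi:.4f} µm)"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f_mid = fwhm_of(mid)
        if abs(f_mid - target_fwhm_um) < tol_um:
            lo = hi = mid
            break
        if f_mid > target_fwhm_um:
            lo = mid
        else:
            hi = mid
    width = 0.5 * (lo + hi)
    prof = simulate_sheet_profile(train, aperture_width_mm=width, **grid_kwargs)
    return {
        "aperture_width_mm": float(width),
        "fwhm_um": float(prof.metadata["fwhm_um"]),
        "na_eff": float(prof.na_eff),
    }
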