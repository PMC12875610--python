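"""Monte-Carlo machining-tolerance analysis of the illumination train.

Fabricated mounts place each optical element within a positional tolerance
band (typically +/-0.005 in, +/-0.002 in for precision machining) and the
dowel pins that register a mount can each be offset independently, tilting
the element by theta = atan(|da - db| / pin spacing).  Every trial draws
independent axial offsets, lateral offsets and pin-pair tilts for each
element, re-evaluates the Gaussian-beam model of the perturbed train, and
records the sheet FWHM and the lateral displacement of the sheet at the
nominal focal plane.

Mirror (and galvo) tilts deviate the beam by twice the mechanical angle;
refractive-element tilts are mapped to an equivalent lateral decentration
through the mount lever arm.  Unit perturbation draws depend only on
(seed, trial index), so runs at different tolerance magnitudes share common
random numbers and worst-case deviations are comparable across tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from lsfmkit.optics import (
    FWHM_FACTOR,
    BeamState,
    OpticalTrain,
    propagate_train,
    _beam_radius_mm,
    _q_from_waist,
    _thin_axis_pupil_na,
)

__all__ = [
    "ToleranceSpec",
    "MonteCarloResult",
    "pin_offset_angle",
    "perturb_train",
    "run_tolerance_mc",
]

INCH_MM = 25.4

#: effective thin-axis NA of the calibrated (slit-truncated) nominal sheet,
#: used to scale the Gaussian-equivalent beam the tolerance model propagates
DEFAULT_EFFECTIVE_NA = 0.48

#: lever arm (mm) converting a mount tilt into element decentration
MOUNT_LEVER_ARM_MM = 25.0


@dataclass(frozen=True)
class ToleranceSpec:
    """Machining-tolerance band and Monte-Carlo settings."""

    positional_tolerance_in: float = 0.005
    pin_spacing_mm: float = 10.0
    n_trials: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.positional_tolerance_in < 0:
            raise ValueError("tolerance must be >= 0")
        if self.pin_spacing_mm <= 0:
            raise ValueError("pin spacing must be positive")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")

    @property
    def positional_tolerance_mm(self) -> float:
        return self.positional_tolerance_in * INCH_MM


@dataclass
class Perturbation:
    """Per-element mechanical offsets for one trial (signed, physical units)."""

    axial_mm: np.ndarray
    lateral_mm: np.ndarray
    tilt_deg: np.ndarray

    @property
    def n_elements(self) -> int:
        return len(self.axial_mm)


@dataclass
class MonteCarloResult:
    """Per-trial sheet metrics plus nominal/best/worst summaries."""

    fwhm_um: np.ndarray
    displacement_um: np.ndarray
    focal_shift_um: np.ndarray
    is_corner: np.ndarray
    nominal_fwhm_um: float
    nominal_displacement_um: float
    nominal_focal_shift_um: float
    spec: ToleranceSpec
    sensitivity: list[dict] = field(default_factory=list)
    failures: list[int] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.fwhm_um)

    @property
    def worst_index(self) -> int:
        return int(np.nanargmax(self.fwhm_um))

    @property
    def best_index(self) -> int:
        return int(np.nanargmin(self.fwhm_um))

    @property
    def worst_fwhm_deviation_um(self) -> float:
        return float(np.nanmax(np.abs(self.fwhm_um - self.nominal_fwhm_um)))

    @property
    def worst_displacement_um(self) -> float:
        return float(np.nanmax(np.abs(self.displacement_um)))

    def summary(self) -> dict:
        wi, bi = self.worst_index, self.best_index
        return {
            "n_trials": self.n_trials,
            "tolerance_in": self.spec.positional_tolerance_in,
            "nominal": {
                "fwhm_um": self.nominal_fwhm_um,
                "displacement_um": self.nominal_displacement_um,
            },
            "best": {
                "index": bi,
                "fwhm_um": float(self.fwhm_um[bi]),
                "displacement_um": float(self.displacement_um[bi]),
            },
            "worst": {
                "index": wi,
                "fwhm_um": float(self.fwhm_um[wi]),
                "displacement_um": float(self.displacement_um[wi]),
                "focal_shift_um": float(self.focal_shift_um[wi]),
            },
            "worst_fwhm_deviation_um": self.worst_fwhm_deviation_um,
            "worst_displacement_um": self.worst_displacement_um,
            "worst_focal_shift_um": float(np.nanmax(np.abs(self.focal_shift_um))),
            "sensitivity": self.sensitivity,
            "n_failures": len(self.failures),
        }


def pin_offset_angle(offset_a_in: float, offset_b_in: float, spacing_mm: float) -> float:
    """Tilt (degrees) of a mount whose two dowel pins are offset by a and b (inches).

    theta = atan(|a - b| * 25.4 / spacing_mm); the worst case of a +/-0.005 in
    band on 10 mm pins is atan(0.254/10) = 1.455 degrees.
    """
    if spacing_mm <= 0:
        raise ValueError("pin spacing must be positive")
    return float(np.degrees(np.arctan(abs(offset_a_in - offset_b_in) * INCH_MM / spacing_mm)))


# --------------------------------------------------------------------------
# perturbation draws
# --------------------------------------------------------------------------

def _unit_draws(seed: int, trial_index: int, n_elements: int) -> np.ndarray:
    """(n_elements, 4) uniform [-1, 1] draws: axial, lateral, pin a, pin b."""
    rng = np.random.default_rng([int(seed), int(trial_index)])
    return rng.uniform(-1.0, 1.0, size=(n_elements, 4))


def draw_perturbation(
    spec: ToleranceSpec, n_elements: int, trial_index: int
) -> Perturbation:
    """Draw one trial's perturbation; deterministic given (seed, trial_index)."""
    u = _unit_draws(spec.seed, trial_index, n_elements)
    tol_in = spec.positional_tolerance_in
    tol_mm = spec.positional_tolerance_mm
    pin_a = u[:, 2] * tol_in
    pin_b = u[:, 3] * tol_in
    tilt = np.array(
        [
            np.sign(a - b) * pin_offset_angle(a, b, spec.pin_spacing_mm)
            for a, b in zip(pin_a, pin_b)
        ]
    )
    return Perturbation(
        axial_mm=u[:, 0] * tol_mm,
        lateral_mm=u[:, 1] * tol_mm,
        tilt_deg=tilt,
    )


def _corner_perturbation(spec: ToleranceSpec, n_elements: int, sign: float) -> Perturbation:
    """Deterministic corner: every DOF at +/-tol (pins anti-symmetric)."""
    tol_in = spec.positional_tolerance_in
    tol_mm = spec.positional_tolerance_mm
    theta = sign * pin_offset_angle(tol_in, -tol_in, spec.pin_spacing_mm)
    return Perturbation(
        axial_mm=np.full(n_elements, sign * tol_mm),
        lateral_mm=np.full(n_elements, sign * tol_mm),
        tilt_deg=np.full(n_elements, theta),
    )


def perturb_train(
    train: OpticalTrain, spec: ToleranceSpec, trial_index: int
) -> tuple[OpticalTrain, Perturbation]:
    """Apply one trial's axial offsets to the train; return it with the draw.

    Axial offsets move ``axial_position_mm``; lateral offsets and tilts do
    not alter the (on-axis) element description and are carried in the
    returned :class:`Perturbation` for the beam-deviation model.
    """
    pert = draw_perturbation(spec, len(train.elements), trial_index)
    return _apply_axial(train, pert), pert


def _apply_axial(train: OpticalTrain, pert: Perturbation) -> OpticalTrain:
    new = tuple(
        replace(e, axial_position_mm=e.axial_position_mm + dz)
        for e, dz in zip(train.elements, pert.axial_mm)
    )
    return replace(train, elements=new)


# --------------------------------------------------------------------------
# metric evaluation
# --------------------------------------------------------------------------

def _effective_train(train: OpticalTrain, na_eff: float) -> OpticalTrain:
    """Scale the input beam so the untruncated Gaussian focuses at na_eff.

    The slit aperture truncates the real beam; for fast per-trial evaluation
    the truncated pupil is replaced by the Gaussian of equal effective NA.
    """
    na_open, _, _ = _thin_axis_pupil_na(train)
    scale = na_eff / na_open
    return replace(train, input_beam_diameter_mm=train.input_beam_diameter_mm * scale)


def evaluate_sheet_metrics(
    train: OpticalTrain,
    pert: Perturbation | None = None,
    sample_plane_mm: float | None = None,
) -> tuple[float, float, float]:
    """(waist FWHM µm, lateral displacement µm, axial focal shift µm).

    Thin-axis Gaussian q and a chief ray (h, u) are propagated together:
    mirror tilts add 2*theta to the ray angle; lens decentrations (drawn
    lateral offset plus lever-arm-projected tilt) deviate the ray by
    delta/f.  The FWHM is the intensity FWHM at the perturbed beam's own
    waist (sheet thickness); the displacement is the chief-ray height at
    the nominal sample plane; the focal shift is the axial offset of the
    perturbed waist from that plane.
    """
    if sample_plane_mm is None:
        sample_plane_mm = train.sample_plane_mm
    lam_vac_mm = train.wavelength_nm * 1e-6
    q = _q_from_waist(train.input_beam_diameter_mm / 2.0, lam_vac_mm)
    lam = lam_vac_mm
    h, u, z = 0.0, 0.0, 0.0
    for i, el in enumerate(train.elements):
        d = el.axial_position_mm - z
        q = q + d
        h = h + u * d
        z = el.axial_position_mm
        tilt = float(pert.tilt_deg[i]) if pert is not None else 0.0
        lateral = float(pert.lateral_mm[i]) if pert is not None else 0.0
        if el.kind == "fold-mirror":
            u += 2.0 * np.radians(tilt)
            continue
        f = el.focal_length("thin")
        if f is None:
            continue
        decenter = lateral + MOUNT_LEVER_ARM_MM * np.radians(tilt)
        u = u - (h - decenter) / float(f)
        if el.kind == "objective":
            q = train.immersion_index / (1.0 / q - 1.0 / float(f))
            lam = lam_vac_mm / train.immersion_index
        else:
            q = 1.0 / (1.0 / q - 1.0 / float(f))
    d = sample_plane_mm - z
    q = q + d
    h = h + u * d
    # q = (z - z_waist) + i zR at the sample plane
    focal_shift_mm = q.real
    w0_mm = np.sqrt(q.imag * lam / np.pi)
    fwhm_um = FWHM_FACTOR * w0_mm * 1e3
    return float(fwhm_um), float(h * 1e3), float(focal_shift_mm * 1e3)


def run_tolerance_mc(
    train: OpticalTrain,
    spec: ToleranceSpec,
    effective_na: float = DEFAULT_EFFECTIVE_NA,
    n_sensitivity_trials: int = 50,
) -> MonteCarloResult:
    """Monte-Carlo tolerance run over the illumination train.

    Trials ``0..n_trials-1`` are random draws; two deterministic corner
    trials (every degree of freedom at +tol and at -tol, pins anti-
    symmetric) are appended so the worst case includes the tolerance-band
    corners.  The per-element sensitivity summary reports the worst metric
    deviation when only that element is perturbed.
    """
    eff = _effective_train(train, effective_na)
    plane = eff.sample_plane_mm
    n_el = len(eff.elements)
    nominal_fwhm, nominal_disp, nominal_shift = evaluate_sheet_metrics(eff, None, plane)

    perts = [draw_perturbation(spec, n_el, i) for i in range(spec.n_trials)]
    corners = [
        _corner_perturbation(spec, n_el, +1.0),
        _corner_perturbation(spec, n_el, -1.0),
    ]
    all_perts = perts + corners
    is_corner = np.array([False] * spec.n_trials + [True, True])

    fwhm = np.full(len(all_perts), np.nan)
    disp = np.full(len(all_perts), np.nan)
    shift = np.full(len(all_perts), np.nan)
    failures: list[int] = []
    for i, pert in enumerate(all_perts):
        try:
            trial_train = _apply_axial(eff, pert)
            fwhm[i], disp[i], shift[i] = evaluate_sheet_metrics(trial_train, pert, plane)
        except (ValueError, ZeroDivisionError, FloatingPointError):
            failures.append(i)

    sensitivity = []
    for e_idx, el in enumerate(eff.elements):
        dev_f = 0.0
        dev_d = 0.0
        for t in range(n_sensitivity_trials):
            full = draw_perturbation(spec, n_el, 10_000 + t)
            solo = Perturbation(
                axial_mm=np.where(np.arange(n_el) == e_idx, full.axial_mm, 0.0),
                lateral_mm=np.where(np.arange(n_el) == e_idx, full.lateral_mm, 0.0),
                tilt_deg=np.where(np.arange(n_el) == e_idx, full.tilt_deg, 0.0),
            )
            try:
                f_t, d_t, _ = evaluate_sheet_metrics(_apply_axial(eff, solo), solo, plane)
            except (ValueError, ZeroDivisionError, FloatingPointError):
                continue
            dev_f = max(dev_f, abs(f_t - nominal_fwhm))
            dev_d = max(dev_d, abs(d_t - nominal_disp))
        sensitivity.append(
            {
                "element": el.label or el.kind,
                "kind": el.kind,
                "fwhm_deviation_um": dev_f,
                "displacement_deviation_um": dev_d,
            }
        )

    return MonteCarloResult(
        fwhm_um=fwhm,
        displacement_um=disp,
        focal_shift_um=shift,
        is_corner=is_corner,
        nominal_fwhm_um=nominal_fwhm,
        nominal_displacement_um=nominal_disp,
        nominal_focal_shift_um=nominal_shift,
        spec=spec,
        sensitivity=sensitivity,
        failures=failures,
    )
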