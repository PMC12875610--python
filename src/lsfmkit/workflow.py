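"""File-based workflow runner chaining the toolkit's stages.

A workflow config (dict or YAML) names an ordered list of stages —
``simulate-sheet``, ``tolerance``, ``detection-calc``, ``make-psf``,
``synth-beads``, ``deskew``, ``decon``, ``bead-qc``,
``compare-populations`` — with their parameters.  Stages exchange data
through files in the output directory; a manifest records every stage's
parameters, outputs and content hashes, so a rerun with the same config and
seeds produces identical manifest hashes.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from lsfmkit import beadqc, detection, optics, pipeline, psf, tolerance
from lsfmkit.imaging import (
    AcquisitionGeometry,
    CameraModel,
    generate_bead_field,
    render_skewed_stack,
)
from lsfmkit.stackio import StackMetadata, read_stack, sidecar_path, write_stack

__all__ = ["run_workflow", "characterize_preset", "WorkflowError"]


class WorkflowError(RuntimeError):
    pass


def _hash_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _hash_output(path: Path) -> str:
    """Content hash; TIFF volumes are hashed by voxel data so container
    timestamps never enter the manifest."""
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        return _hash_bytes(np.ascontiguousarray(tifffile.imread(path)).tobytes())
    return _hash_bytes(path.read_bytes())


def _resolve_psf(params: dict, out_dir: Path) -> psf.PSFModel:
    if "psf_path" in params:
        vol, meta = read_stack(out_dir / params["psf_path"])
        voxel = meta.voxel_um or tuple(params["voxel_um"])
        kernel = vol.astype(float)
        kernel /= kernel.sum()
        return psf.PSFModel(
            intensity=kernel, voxel_um=tuple(voxel), model_kind="measured"
        )
    fwhm = tuple(params["psf_fwhm_nm"])  # (z, y, x)
    voxel = tuple(params["voxel_um"])
    return psf.gaussian_psf(fwhm, voxel)


# --------------------------------------------------------------------------
# stage runners: each takes (params, out_dir, seed) and returns output paths
# --------------------------------------------------------------------------

def _stage_simulate_sheet(params: dict, out_dir: Path, seed: int) -> list[Path]:
    train = (
        optics.nominal_train()
        if params.get("train", "nominal") == "nominal"
        else optics.load_train(params["train"])
    )
    aperture = params.get("aperture_mm", "auto")
    if aperture == "auto":
        cal = optics.calibrate_aperture(train, params.get("target_fwhm_um", 0.385))
        aperture = cal["aperture_width_mm"]
    prof = optics.simulate_sheet_profile(train, aperture_width_mm=float(aperture))
    out = out_dir / params.get("out", "sheet.tif")
    meta = StackMetadata(
        voxel_um=(prof.z_spacing_um, prof.y_spacing_um, 1.0),
        extra={
            "na_eff": prof.na_eff,
            "fwhm_um": prof.metadata["fwhm_um"],
            "aperture_width_mm": float(aperture),
            "pupil_shape": prof.pupil_shape,
        },
    )
    meta.append_stage("simulate-sheet", {"aperture_mm": float(aperture)})
    write_stack(prof.intensity[None, ...], meta, out, dtype="float32")
    return [out, sidecar_path(out)]


def _stage_tolerance(params: dict, out_dir: Path, seed: int) -> list[Path]:
    train = (
        optics.nominal_train()
        if params.get("train", "nominal") == "nominal"
        else optics.load_train(params["train"])
    )
    spec = tolerance.ToleranceSpec(
        positional_tolerance_in=float(params.get("tolerance_in", 0.005)),
        pin_spacing_mm=float(params.get("pin_spacing_mm", 10.0)),
        n_trials=int(params.get("trials", 100)),
        seed=int(params.get("seed", seed)),
    )
    result = tolerance.run_tolerance_mc(train, spec)
    csv_path = out_dir / params.get("out_csv", "tolerance_trials.csv")
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["trial", "is_corner", "fwhm_um", "displacement_um"])
        for i in range(result.n_trials):
            writer.writerow(
                [i, bool(result.is_corner[i]), f"{result.fwhm_um[i]:.9g}",
                 f"{result.displacement_um[i]:.9g}"]
            )
    json_path = out_dir / params.get("out_json", "tolerance_summary.json")
    json_path.write_text(json.dumps(result.summary(), indent=2, sort_keys=True))
    return [csv_path, json_path]


def _stage_detection_calc(params: dict, out_dir: Path, seed: int) -> list[Path]:
    path = detection.DetectionPath(
        **{k: v for k, v in params.items() if k in detection.DetectionPath.__dataclass_fields__}
    )
    timing = detection.TimingModel(
        **{k: v for k, v in params.items() if k in detection.TimingModel.__dataclass_fields__}
    )
    sampling = detection.sampling_summary(path)
    report = {
        "sampling": sampling,
        "resolution_nm": detection.detection_psf_fwhm(
            path.objective_na, path.emission_wavelength_nm, path.immersion_index
        ),
        "timing": detection.volumetric_rate(timing),
    }
    report["galvo_not_rate_limiting"] = (
        sampling["galvo_period_ms"] < timing.exposure_ms
    )
    out = out_dir / params.get("out", "detection.json")
    out.write_text(json.dumps(report, indent=2, sort_keys=True))
    return [out]


def _stage_make_psf(params: dict, out_dir: Path, seed: int) -> list[Path]:
    voxel = tuple(params.get("voxel_um", (0.125, 0.065, 0.065)))
    if "fwhm_nm" in params:
        model = psf.gaussian_psf(tuple(params["fwhm_nm"]), voxel)
    else:
        model = psf.scalar_psf(
            na=float(params.get("na", 1.1)),
            wavelength_nm=float(params.get("emission_nm", 510.0)),
            n=float(params.get("n", 1.3333)),
            voxel_um=voxel,
            shape=tuple(params.get("shape", (33, 65, 65))),
        )
    out = out_dir / params.get("out", "psf.tif")
    meta = StackMetadata(voxel_um=model.voxel_um, extra=dict(model.metadata))
    meta.append_stage("make-psf", {"model_kind": model.model_kind})
    write_stack(model.intensity, meta, out, dtype="float32")
    return [out, sidecar_path(out)]


def _stage_synth_beads(params: dict, out_dir: Path, seed: int) -> list[Path]:
    stage_seed = int(params.get("seed", seed))
    geometry = AcquisitionGeometry(
        scan_step_um=float(params.get("step_um", 0.25)),
        deskew_angle_deg=float(params.get("angle_deg", 29.5)),
        pixel_size_um=float(params.get("pixel_um", 0.130)),
        camera_roi=tuple(params.get("roi", (160, 320))),
        n_slices=int(params.get("n_slices", 80)),
    )
    camera = CameraModel(
        offset_counts=float(params.get("offset", 100.0)),
        gain_counts_per_photon=float(params.get("gain", 1.0)),
        read_noise_counts=float(params.get("read_noise", 0.0)),
        shot_noise=bool(params.get("shot_noise", True)),
    )
    voxel = (geometry.z_spacing_um, geometry.pixel_size_um, geometry.pixel_size_um)
    kernel = psf.gaussian_psf(
        tuple(params.get("psf_fwhm_nm", (464.0, 330.0, 328.0))), voxel
    )
    volume_um = params.get("volume_um")
    if volume_um is None:
        drift = (geometry.n_slices - 1) * geometry.shift_px_per_slice
        volume_um = (
            geometry.n_slices * geometry.z_spacing_um,
            geometry.camera_roi[0] * geometry.pixel_size_um,
            (geometry.camera_roi[1] - int(np.ceil(drift))) * geometry.pixel_size_um,
        )
    truth = generate_bead_field(
        n=int(params.get("n", 50)),
        volume_um=tuple(volume_um),
        min_separation_um=float(params.get("min_separation_um", 2.0)),
        seed=stage_seed,
        intensity_photons=float(params.get("photons", 10000.0)),
    )
    raw = render_skewed_stack(truth, kernel, geometry, camera, seed=stage_seed)
    out = out_dir / params.get("out", "raw.tif")
    meta = StackMetadata(
        voxel_um=None,
        geometry={
            "scan_step_um": geometry.scan_step_um,
            "deskew_angle_deg": geometry.deskew_angle_deg,
            "pixel_size_um": geometry.pixel_size_um,
            "n_slices": geometry.n_slices,
            "lab_cols": raw.lab_cols,
        },
        camera={
            "offset_counts": camera.offset_counts,
            "gain_counts_per_photon": camera.gain_counts_per_photon,
            "read_noise_counts": camera.read_noise_counts,
            "shot_noise": camera.shot_noise,
        },
        seeds={"synth-beads": stage_seed},
    )
    meta.append_stage("synth-beads", {"n": truth.n_beads, "seed": stage_seed})
    write_stack(raw.data, meta, out, dtype="uint16")
    truth_path = out_dir / params.get("truth_out", "ground_truth.csv")
    with open(truth_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["z_um", "y_um", "x_um", "photons"])
        for p, a in zip(truth.positions_um, truth.intensities_photons):
            writer.writerow([f"{p[0]:.6f}", f"{p[1]:.6f}", f"{p[2]:.6f}", f"{a:g}"])
    return [out, sidecar_path(out), truth_path]


def _geometry_from_meta(meta: StackMetadata, params: dict) -> AcquisitionGeometry:
    g = meta.geometry
    return AcquisitionGeometry(
        scan_step_um=float(params.get("step_um", g.get("scan_step_um", 0.25))),
        deskew_angle_deg=float(params.get("angle_deg", g.get("deskew_angle_deg", 29.5))),
        pixel_size_um=float(params.get("pixel_um", g.get("pixel_size_um", 0.130))),
        camera_roi=(1, 1),
        n_slices=int(g.get("n_slices", 1)),
    )


def _stage_deskew(params: dict, out_dir: Path, seed: int) -> list[Path]:
    vol, meta = read_stack(out_dir / params["input"])
    geometry = _geometry_from_meta(meta, params)
    lab_cols = meta.geometry.get("lab_cols")
    fill = meta.camera.get("offset_counts", 0.0)
    desk, voxel, dmeta = pipeline.deskew(
        vol, geometry, params.get("interpolation", "linear"), fill_value=fill
    )
    if lab_cols is not None:
        desk = desk[:, :, : int(lab_cols)]
    out = out_dir / params.get("out", "deskewed.tif")
    meta.voxel_um = voxel
    meta.append_stage("deskew", {k: v for k, v in dmeta.items() if k != "voxel_um"})
    write_stack(desk, meta, out, dtype="uint16")
    return [out, sidecar_path(out)]


def _stage_decon(params: dict, out_dir: Path, seed: int) -> list[Path]:
    vol, meta = read_stack(out_dir / params["input"])
    if meta.voxel_um is None:
        raise WorkflowError("deconvolution input lacks voxel sizes")
    kernel = _resolve_psf({**params, "voxel_um": meta.voxel_um}, out_dir)
    dp = pipeline.DeconParams(
        background=float(params.get("background", meta.camera.get("offset_counts", 100.0))),
        iterations=int(params.get("iterations", 2)),
        wiener_alpha=float(params.get("alpha", 0.005)),
        otf_cumulative_threshold=float(params.get("otf_threshold", 0.6)),
        hann_bounds=tuple(params.get("hann", (0.8, 1.0))),
    )
    result = pipeline.omw_deconvolve(vol, kernel, dp, voxel_um=meta.voxel_um)
    out = out_dir / params.get("out", "decon.tif")
    meta.append_stage(
        "decon",
        {
            "background": dp.background,
            "iterations": dp.iterations,
            "alpha": dp.wiener_alpha,
            "otf_threshold": dp.otf_cumulative_threshold,
            "hann": list(dp.hann_bounds),
        },
    )
    write_stack(result, meta, out, dtype="uint16")
    return [out, sidecar_path(out)]


def _stage_bead_qc(params: dict, out_dir: Path, seed: int) -> list[Path]:
    vol, meta = read_stack(out_dir / params["input"])
    voxel = tuple(params.get("voxel_um", meta.voxel_um or (0.123, 0.130, 0.130)))
    offset = meta.camera.get("offset_counts", 0.0)
    threshold = float(params.get("threshold", offset + 5 * np.sqrt(max(offset, 1.0))))
    expected = tuple(params.get("expected_fwhm_nm", (500.0, 400.0, 400.0)))
    min_sep = float(params.get("min_separation_voxels", 8.0))
    cands = beadqc.detect_beads(vol, threshold, min_sep)
    fits = [
        beadqc.fit_bead_fwhm(vol, c.center_voxel, voxel, expected)
        for c in cands
        if not c.flags
    ]
    stats = beadqc.population_stats(fits)
    prefix = params.get("prefix", "beads")
    csv_path = out_dir / f"{prefix}.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["z_um", "y_um", "x_um", "fwhm_x_nm", "fwhm_y_nm", "fwhm_z_nm", "flags"]
        )
        for f in fits:
            if f.center_um is None:
                continue
            writer.writerow(
                [
                    f"{f.center_um[0]:.4f}",
                    f"{f.center_um[1]:.4f}",
                    f"{f.center_um[2]:.4f}",
                    f"{f.fwhm_nm['x']:.2f}",
                    f"{f.fwhm_nm['y']:.2f}",
                    f"{f.fwhm_nm['z']:.2f}",
                    ";".join(sorted(f.flags)),
                ]
            )
    json_path = out_dir / f"{prefix}_population.json"
    json_path.write_text(
        json.dumps(
            {
                "mean_fwhm_nm": stats.mean_nm,
                "sigma_fwhm_nm": stats.sigma_nm,
                "n_beads": stats.n_beads,
                "rejections": stats.rejections,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return [csv_path, json_path]


def _stage_compare_populations(params: dict, out_dir: Path, seed: int) -> list[Path]:
    pre = json.loads((out_dir / params["pre"]).read_text())
    post = json.loads((out_dir / params["post"]).read_text())
    report = {"pre_mean_fwhm_nm": pre["mean_fwhm_nm"], "post_mean_fwhm_nm": post["mean_fwhm_nm"]}
    report["reduction_pct"] = {
        ax: 100.0 * (1.0 - post["mean_fwhm_nm"][ax] / pre["mean_fwhm_nm"][ax])
        for ax in ("x", "y", "z")
    }
    out = out_dir / params.get("out", "fwhm_report.json")
    out.write_text(json.dumps(report, indent=2, sort_keys=True))
    return [out]


_STAGES = {
    "simulate-sheet": _stage_simulate_sheet,
    "tolerance": _stage_tolerance,
    "detection-calc": _stage_detection_calc,
    "make-psf": _stage_make_psf,
    "synth-beads": _stage_synth_beads,
    "deskew": _stage_deskew,
    "decon": _stage_decon,
    "bead-qc": _stage_bead_qc,
    "compare-populations": _stage_compare_populations,
}


def characterize_preset(seed: int = 7, n_beads: int = 50) -> dict:
    """End-to-end bead characterization: render, deskew, deconvolve, QC."""
    fwhm = (464.0, 330.0, 328.0)
    expected_pre = (550.0, 400.0, 400.0)
    return {
        "seed": seed,
        "stages": [
            {"stage": "synth-beads", "n": n_beads, "psf_fwhm_nm": list(fwhm)},
            {"stage": "deskew", "input": "raw.tif", "out": "deskewed.tif"},
            {
                "stage": "bead-qc",
                "input": "deskewed.tif",
                "prefix": "beads_pre",
                "expected_fwhm_nm": list(expected_pre),
            },
            {
                "stage": "decon",
                "input": "deskewed.tif",
                "psf_fwhm_nm": list(fwhm),
                "out": "decon.tif",
            },
            {
                "stage": "bead-qc",
                "input": "decon.tif",
                "prefix": "beads_post",
                "expected_fwhm_nm": [400.0, 300.0, 300.0],
            },
            {
                "stage": "compare-populations",
                "pre": "beads_pre_population.json",
                "post": "beads_post_population.json",
            },
        ],
    }


def run_workflow(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute a workflow config; return (and write) the manifest.

    A stage failure aborts the run, leaving the partial manifest on disk
    with the failure recorded.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if config.get("preset") == "characterize":
        config = characterize_preset(seed=int(config.get("seed", 7)))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", [])
    for s in stages:
        name = s.get("stage")
        if name not in _STAGES:
            raise WorkflowError(f"unknown stage {name!r}; known: {sorted(_STAGES)}")
    manifest: dict = {"seed": seed, "stages": []}
    manifest_path = out_dir / "manifest.json"
    for s in stages:
        name = s["stage"]
        params = {k: v for k, v in s.items() if k != "stage"}
        record: dict = {"stage": name, "parameters": params}
        try:
            outputs = _STAGES[name](params, out_dir, seed)
        except Exception as exc:
            record["error"] = str(exc)
            manifest["stages"].append(record)
            manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
            raise WorkflowError(f"stage {name!r} failed: {exc}") from exc
        record["outputs"] = {p.name: _hash_output(p) for p in outputs}
        manifest["stages"].append(record)
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
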