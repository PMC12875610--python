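"""Bead detection, Gaussian FWHM fitting and population statistics."""

import numpy as np
import pytest

from lsfmkit import beadqc, imaging, psf
from lsfmkit.beadqc import (
    detect_beads,
    fit_bead_fwhm,
    population_stats,
    sheet_cross_section_fwhm,
)


def gaussian_blob_volume(fwhm_nm=(450.0, 300.0, 300.0), voxel=(0.1, 0.1, 0.1),
                         shape=(41, 41, 41), center=None, amplitude=1000.0,
                         offset=100.0):
    if center is None:
        center = tuple(s // 2 for s in shape)
    sig = np.array(fwhm_nm) * 1e-3 / np.array(voxel) / 2.355
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, sig))
    return amplitude * np.exp(-r2 / 2) + offset


class TestDetect:
    def test_background_only_volume_yields_nothing(self):
        assert detect_beads(np.full((20, 20, 20), 100.0), 150.0) == []

    def test_all_isolated_beads_found(self, bead_truth, noisy_chain):
        desk = noisy_chain["deskewed"]
        voxel = np.array(noisy_chain["voxel_um"])
        cands = detect_beads(desk, 160.0, min_separation_voxels=8)
        found = np.array([c.center_voxel for c in cands], dtype=float) * voxel
        # precision & recall against generator ground truth (1-voxel radius)
        truth = bead_truth.positions_um
        d = np.linalg.norm(found[:, None, :] - truth[None, :, :], axis=-1)
        recall = (d.min(axis=0) < 0.5).mean()
        precision = (d.min(axis=1) < 0.5).mean()
        assert recall >= 0.98
        assert precision >= 0.98

    def test_close_pair_suppressed_and_flagged(self):
        vol = np.full((30, 30, 30), 100.0)
        vol[15, 15, 15] = 500.0
        vol[15, 15, 18] = 450.0
        cands = detect_beads(vol, 200.0, min_separation_voxels=5)
        assert len(cands) == 1
        assert "overlapping" in cands[0].flags

    def test_edge_candidates_flagged(self):
        vol = np.full((30, 30, 30), 100.0)
        vol[2, 15, 15] = 500.0
        cands = detect_beads(vol, 200.0, min_separation_voxels=5)
        assert len(cands) == 1
        assert "edge" in cands[0].flags


class TestFit:
    def test_exact_recovery_on_noiseless_blob(self):
        vol = gaussian_blob_volume(center=(20.3, 20.6, 19.8))
        fit = fit_bead_fwhm(vol, (20, 21, 20), (0.1, 0.1, 0.1), (450, 300, 300))
        assert fit.ok
        for ax, want in zip("zyx", (450.0, 300.0, 300.0)):
            assert fit.fwhm_nm[ax] == pytest.approx(want, rel=0.005)
        assert fit.center_um[0] == pytest.approx(2.03, abs=0.005)

    def test_noisy_recovery_within_5_percent(self):
        rng = np.random.default_rng(8)
        errs = []
        for trial in range(10):
            c = 20 + rng.uniform(-0.5, 0.5, 3)
            clean = gaussian_blob_volume(fwhm_nm=(464, 330, 328),
                                         voxel=(0.123, 0.13, 0.13),
                                         center=tuple(c), amplitude=170.0,
                                         offset=0.0)
            noisy = rng.poisson(clean + 100.0).astype(float)
            fit = fit_bead_fwhm(noisy, tuple(np.round(c).astype(int)),
                                (0.123, 0.13, 0.13), (550, 400, 400))
            assert fit.ok
            for ax, want in zip("zyx", (464.0, 330.0, 328.0)):
                errs.append(abs(fit.fwhm_nm[ax] / want - 1))
        assert np.mean(errs) < 0.05

    def test_edge_bead_flagged_without_fit(self):
        vol = gaussian_blob_volume(center=(2, 20, 20))
        fit = fit_bead_fwhm(vol, (2, 20, 20), (0.1, 0.1, 0.1), (450, 300, 300))
        assert "edge" in fit.flags
        assert not fit.fwhm_nm


class TestPopulation:
    def _fit(self, fwhm):
        f = beadqc.BeadFit(center_um=(1, 1, 1))
        f.fwhm_nm = {"z": fwhm, "y": fwhm, "x": fwhm}
        f.r_squared = {a: 1.0 for a in "zyx"}
        return f

    def test_normal_draws_recover_mean(self):
        rng = np.random.default_rng(12)
        fits = [self._fit(v) for v in rng.normal(330, 20, 500)]
        stats = population_stats(fits)
        assert abs(stats.mean_nm["x"] - 330) < 3 * 20 / np.sqrt(500)
        assert stats.sigma_nm["x"] == pytest.approx(20, rel=0.2)

    def test_single_fit_degenerate(self):
        stats = population_stats([self._fit(330.0)])
        assert stats.degenerate
        assert stats.mean_nm["z"] == 330.0
        assert stats.sigma_nm["z"] == 0.0

    def test_flagged_fits_excluded_and_tallied(self):
        bad = beadqc.BeadFit(center_um=None)
        bad.flags.add("edge")
        stats = population_stats([self._fit(300.0), self._fit(320.0), bad])
        assert stats.n_beads == 2
        assert stats.rejections == {"edge": 1}
        assert stats.mean_nm["x"] == pytest.approx(310.0)

    def test_all_flagged_rejected(self):
        bad = beadqc.BeadFit(center_um=None)
        bad.flags.add("edge")
        with pytest.raises(ValueError):
            population_stats([bad])


class TestSheetCrossSection:
    def _sheet_image(self, fwhm_um, pixel_um=0.02, rows=201, cols=60, noise=0.0,
                     seed=0):
        z = (np.arange(rows) - rows // 2) * pixel_um
        profile = np.exp(-4 * np.log(2) * (z / fwhm_um) ** 2)
        img = np.tile(profile[:, None], (1, cols)) * 1000.0 + 50.0
        if noise:
            img += np.random.default_rng(seed).normal(0, noise, img.shape)
        return img

    def test_recovers_measured_sheet_thickness(self):
        # ground truth set to the experimentally characterized 0.415 µm
        img = self._sheet_image(0.415, noise=10.0)
        fwhm, curve = sheet_cross_section_fwhm(img, 0.02)
        assert fwhm == pytest.approx(0.415, rel=0.02)
        assert curve.shape == (201,)

    def test_exact_on_noiseless_profile(self):
        img = self._sheet_image(0.415)
        fwhm, _ = sheet_cross_section_fwhm(img, 0.02)
        assert fwhm == pytest.approx(0.415, rel=1e-4)

    def test_flat_image_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            sheet_cross_section_fwhm(np.full((50, 50), 7.0), 0.02)
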