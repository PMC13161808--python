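import numpy as np
import pytest

from fcnm.grid import BinaryMask, BOLDSeries, VolumeGrid
from fcnm.preprocess import (
    NuisanceSpec,
    bandpass,
    build_nuisance_design,
    framewise_displacement,
    friston24,
    motion_qc,
    regress_and_filter,
    smooth_gaussian,
)


def fd_oracle(motion, radius=50.0):
    """Independent scalar-loop implementation of Power's FD."""
    out = [0.0]
    for t in range(1, motion.shape[0]):
        s = sum(abs(motion[t, i] - motion[t - 1, i]) for i in range(3))
        s += radius * sum(abs(motion[t, i] - motion[t - 1, i]) for i in range(3, 6))
        out.append(s)
    return np.array(out)


class TestFramewiseDisplacement:
    def test_zero_motion_gives_zero_fd(self):
        assert framewise_displacement(np.zeros((50, 6))).max() == 0.0

    def test_single_translation_step(self):
        motion = np.zeros((10, 6))
        motion[5:, 0] = 0.1
        fd = framewise_displacement(motion)
        assert fd[5] == pytest.approx(0.1)
        assert fd[[0, 4, 6]].max() == 0.0

    def test_rotation_step_uses_50mm_radius(self):
        motion = np.zeros((10, 6))
        motion[3:, 4] = 0.01  # radians
        fd = framewise_displacement(motion)
        assert fd[3] == pytest.approx(0.5)

    def test_matches_independent_oracle(self, rng):
        motion = rng.normal(0, 0.1, size=(80, 6))
        fd = framewise_displacement(motion)
        expected = fd_oracle(motion)
        np.testing.assert_allclose(fd, expected, rtol=1e-12, atol=1e-12)


class TestMotionQC:
    def test_under_threshold_passes(self):
        motion = np.zeros((20, 6))
        motion[10, 0] = 1.9
        motion[12, 3] = np.radians(1.9)
        assert motion_qc(motion).passed

    def test_excess_translation_fails(self):
        motion = np.zeros((20, 6))
        motion[10, 2] = 2.5
        qc = motion_qc(motion)
        assert not qc.passed and qc.max_translation_mm == pytest.approx(2.5)

    def test_excess_rotation_fails(self):
        motion = np.zeros((20, 6))
        motion[10, 5] = np.radians(2.5)
        assert not motion_qc(motion).passed

    def test_empty_trace_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            motion_qc(np.zeros((0, 6)))


def make_bold(grid, rng, T=200, tr=2.0):
    return BOLDSeries(grid, rng.standard_normal(grid.shape + (T,)), tr)


class TestNuisanceDesign:
    def test_full_column_count(self, rng):
        grid = VolumeGrid.isotropic(6, 3.0)
        bold = make_bold(grid, rng)
        motion = rng.normal(0, 0.05, size=(200, 6))
        fd = np.zeros(200)
        fd[[20, 90, 150]] = 0.8  # exactly three spikes
        masks = {
            "global": BinaryMask.full(grid),
            "wm": BinaryMask(grid, np.eye(6, dtype=bool)[:, :, None].repeat(6, 2) > 0),
            "csf": BinaryMask(grid, np.tri(6, dtype=bool)[:, :, None].repeat(6, 2) > 0),
        }
        X, names = build_nuisance_design(bold, motion, NuisanceSpec(), masks=masks, fd=fd)
        assert X.shape == (200, 1 + 1 + 24 + 3 + 3)
        assert sum(n.startswith("spike") for n in names) == 3

    def test_zero_motion_design_still_full_rank(self, rng):
        grid = VolumeGrid.isotropic(5, 3.0)
        bold = make_bold(grid, rng, T=100)
        spec = NuisanceSpec(include_global=False, include_wm=False, include_csf=False)
        with pytest.warns(UserWarning, match="degenerate"):
            X, names = build_nuisance_design(bold, np.zeros((100, 6)), spec)
        assert np.linalg.matrix_rank(X) == X.shape[1]
        assert not any(n.startswith("motion") for n in names)

    def test_infinite_fd_threshold_means_no_spikes(self, rng):
        grid = VolumeGrid.isotropic(5, 3.0)
        bold = make_bold(grid, rng, T=100)
        motion = rng.normal(0, 0.5, size=(100, 6))
        spec = NuisanceSpec(
            fd_spike_threshold_mm=np.inf,
            include_global=False, include_wm=False, include_csf=False,
        )
        _, names = build_nuisance_design(bold, motion, spec)
        assert not any(n.startswith("spike") for n in names)

    def test_friston24_lags_zero_padded(self, rng):
        motion = rng.normal(size=(30, 6))
        F = friston24(motion)
        assert F.shape == (30, 24)
        np.testing.assert_array_equal(F[0, 6:12], 0.0)
        np.testing.assert_allclose(F[1:, 6:12], motion[:-1], rtol=0, atol=0)

    def test_missing_tissue_mask_is_fatal(self, rng):
        grid = VolumeGrid.isotropic(5, 3.0)
        bold = make_bold(grid, rng, T=100)
        with pytest.raises(ValueError, match="wm"):
            build_nuisance_design(
                bold, None, NuisanceSpec(include_global=False, include_csf=False),
                masks={},
            )


class TestRegressAndFilter:
    def test_design_column_is_annihilated(self, rng):
        grid = VolumeGrid.isotropic(4, 3.0)
        T = 120
        col = rng.standard_normal(T)
        design = np.column_stack([np.ones(T), col])
        data = np.tile(col, grid.shape + (1,)) * rng.uniform(0.5, 2.0, grid.shape)[..., None]
        bold = BOLDSeries(grid, data, 2.0)
        spec = NuisanceSpec(include_global=False, include_wm=False, include_csf=False)
        # residual of the regression step alone must vanish
        beta, *_ = np.linalg.lstsq(design, bold.as_matrix().T, rcond=None)
        resid = bold.as_matrix().T - design @ beta
        assert np.abs(resid).max() < 1e-8 * np.abs(data).max()
        # and the full operation output is the filtered zero signal
        out = regress_and_filter(bold, design, spec)
        assert np.abs(out.data).max() < 1e-8

    def test_residuals_orthogonal_to_design(self, rng):
        grid = VolumeGrid.isotropic(4, 3.0)
        T = 150
        bold = make_bold(grid, rng, T=T)
        design = np.column_stack([np.ones(T), np.linspace(-1, 1, T),
                                  rng.standard_normal((T, 3))])
        beta, *_ = np.linalg.lstsq(design, bold.as_matrix().T, rcond=None)
        resid = bold.as_matrix().T - design @ beta
        dots = np.abs(design.T @ resid)
        scale = np.linalg.norm(design, axis=0)[:, None] * np.linalg.norm(resid, axis=0)
        assert (dots / scale).max() < 1e-6

    def test_in_band_sinusoid_preserved(self):
        grid = VolumeGrid.isotropic(3, 3.0)
        T, tr = 200, 2.0
        t = np.arange(T) * tr
        sig = np.sin(2 * np.pi * 0.05 * t)
        bold = BOLDSeries(grid, np.tile(sig, grid.shape + (1,)), tr)
        spec = NuisanceSpec(include_global=False, include_wm=False, include_csf=False)
        out = regress_and_filter(bold, None, spec)
        r = np.corrcoef(out.data[0, 0, 0], sig)[0, 1]
        assert r > 0.99

    def test_out_of_band_sinusoid_rejected(self):
        grid = VolumeGrid.isotropic(3, 3.0)
        T, tr = 200, 2.0
        t = np.arange(T) * tr
        sig = np.sin(2 * np.pi * 0.2 * t)
        bold = BOLDSeries(grid, np.tile(sig, grid.shape + (1,)), tr)
        spec = NuisanceSpec(include_global=False, include_wm=False, include_csf=False)
        out = regress_and_filter(bold, None, spec)
        assert out.data[0, 0, 0].var() < 0.01 * sig.var()

    def test_bandpass_matches_fft_oracle(self, rng):
        T, tr = 180, 2.0
        x = rng.standard_normal((T, 5))
        got = bandpass(x, tr, 0.01, 0.1)
        # independent oracle: project onto kept Fourier basis vectors
        freqs = np.fft.fftfreq(T, d=tr)
        F = np.fft.fft(x, axis=0)
        keep = (np.abs(freqs) >= 0.01 - 1e-12) & (np.abs(freqs) <= 0.1 + 1e-12)
        expected = np.real(np.fft.ifft(F * keep[:, None], axis=0))
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_bandpass_idempotent(self, rng):
        x = rng.standard_normal((160, 7))
        once = bandpass(x, 2.0, 0.01, 0.1)
        twice = bandpass(once, 2.0, 0.01, 0.1)
        assert np.abs(once - twice).max() < 1e-8

    def test_band_above_nyquist_is_fatal(self, rng):
        grid = VolumeGrid.isotropic(3, 3.0)
        bold = make_bold(grid, rng, T=100, tr=10.0)  # Nyquist 0.05 Hz
        spec = NuisanceSpec(include_global=False, include_wm=False, include_csf=False)
        with pytest.raises(ValueError, match="Nyquist"):
            regress_and_filter(bold, None, spec)


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, grid15, rng):
        vol = rng.standard_normal(grid15.shape)
        np.testing.assert_array_equal(smooth_gaussian(vol, 0.0, grid15), vol)

    def test_constant_volume_unchanged(self, grid15):
        vol = np.full(grid15.shape, 3.7)
        out = smooth_gaussian(vol, 6.0, grid15)
        np.testing.assert_allclose(out, vol, atol=1e-12)

    def test_impulse_peak_matches_discrete_kernel_oracle(self, grid15):
        # center value of a smoothed impulse = product of the three 1-D
        # discrete Gaussian center weights, built here independently
        fwhm = 6.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / 3.0  # voxels
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        w = np.exp(-(x**2) / (2 * sigma**2))
        w /= w.sum()
        vol = np.zeros(grid15.shape)
        vol[7, 7, 7] = 1.0
        out = smooth_gaussian(vol, fwhm, grid15)
        assert out[7, 7, 7] == pytest.approx(w[radius] ** 3, rel=1e-10)
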