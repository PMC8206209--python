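"""GLM: HRF kernels, regressor construction, OLS fitting, thresholding."""

import numpy as np
import pytest
from scipy import stats

from reflexmri import glm


class TestHrfKernel:
    def test_kernel_spans_32s(self):
        k = glm.hrf_kernel(glm.STANDARD_HRF, dt=0.01)
        assert len(k) == pytest.approx(3201, abs=1)
        assert k.max() == pytest.approx(1.0)

    def test_undershoot_exists(self):
        k = glm.hrf_kernel(glm.STANDARD_HRF, dt=0.01)
        assert k.min() < 0.0

    def test_brainstem_peaks_before_standard(self):
        dt = 0.01
        kb = glm.hrf_kernel(glm.BRAINSTEM_HRF, dt)
        ks = glm.hrf_kernel(glm.STANDARD_HRF, dt)
        assert np.argmax(kb) < np.argmax(ks)

    def test_bad_dt_rejected(self):
        with pytest.raises(ValueError):
            glm.hrf_kernel(glm.STANDARD_HRF, dt=40.0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            glm.HrfSpec(kernel_length=10.0, undershoot_delay=16.0)


class TestBuildRegressor:
    VT = np.arange(0, 120, 1.225)

    def test_zero_amplitudes_zero_column(self):
        col = glm.build_regressor([10.0, 30.0], [0.0, 0.0], self.VT)
        assert np.all(col == 0.0)

    def test_linearity_in_amplitudes(self):
        col1 = glm.build_regressor([10.0, 30.0], [1.0, 2.0], self.VT)
        col2 = glm.build_regressor([10.0, 30.0], [2.0, 4.0], self.VT)
        assert np.allclose(col2, 2.0 * col1)

    def test_single_event_matches_brute_force_convolution(self):
        """A unit event reproduces the direct discrete convolution."""
        spec = glm.EventRegressorSpec()
        hrf = glm.STANDARD_HRF
        dt = spec.microtime_dt
        col = glm.build_regressor([10.0], [1.0], self.VT, hrf=hrf, spec=spec)
        # independent brute-force convolution on the microtime grid
        n = int(np.ceil((self.VT.max() + dt) / dt)) + 1
        stick = np.zeros(n)
        i0 = int(round((10.0 + spec.onset_offset) / dt))
        stick[i0 : i0 + int(round(spec.boxcar_duration / dt))] = 1.0
        kernel = glm.hrf_kernel(hrf, dt)
        ref = np.zeros(n)
        for i in np.nonzero(stick)[0]:
            hi = min(n, i + len(kernel))
            ref[i:hi] += stick[i] * kernel[: hi - i] * dt
        expected = np.interp(self.VT, np.arange(n) * dt, ref)
        assert np.allclose(col, expected, atol=1e-9)

    def test_event_past_end_contributes_nothing(self):
        col = glm.build_regressor([1e6], [5.0], self.VT)
        assert np.all(col == 0.0)


class TestDesign:
    VT = np.arange(0, 600, 1.225)

    def test_dct_order_closed_form(self):
        """600 s at cutoff 128 s gives floor(2*600/128) = 9 basis functions."""
        n = len(self.VT)
        B = glm.dct_basis(n, 1.225, 128.0)
        assert B.shape[1] == int(np.floor(2 * (n * 1.225) / 128.0)) == 9

    def test_two_sessions_replace_intercept(self):
        n = len(self.VT)
        half = n // 2
        reg = {"H_FCR": np.random.default_rng(0).normal(size=n)}
        d = glm.build_design(reg, self.VT, session_lengths=[half, n - half])
        assert "session_0" in d.names and "session_1" in d.names
        assert "intercept" not in d.names

    def test_no_nuisance_minimal_design(self):
        reg = {"H_FCR": np.random.default_rng(0).normal(size=len(self.VT))}
        d = glm.build_design(reg, self.VT)
        assert d.names == ["H_FCR", "intercept"]

    def test_rank_deficiency_names_columns(self):
        x = np.random.default_rng(0).normal(size=len(self.VT))
        with pytest.raises(ValueError, match="collinear"):
            glm.build_design({"a": x, "b": 2 * x}, self.VT)


class TestSmoothing:
    def test_constant_volume_unchanged(self):
        data = np.full((8, 8, 8, 2), 3.0)
        out = glm.smooth_volume(data, fwhm_mm=4.0, voxel_mm=2.0)
        assert np.allclose(out, 3.0)

    def test_delta_spreads_with_correct_sigma(self):
        data = np.zeros((21, 21, 21, 1))
        data[10, 10, 10, 0] = 1.0
        fwhm = 4.0
        out = glm.smooth_volume(data, fwhm_mm=fwhm, voxel_mm=2.0)
        assert out.sum() == pytest.approx(1.0, rel=1e-2)
        sigma_vox = fwhm / (2 * np.sqrt(2 * np.log(2))) / 2.0
        # the marginal along one axis is Gaussian with the requested sigma
        x = np.arange(21) - 10
        marginal = out[:, :, :, 0].sum(axis=(1, 2))
        sigma_est = np.sqrt((marginal * x**2).sum() / marginal.sum())
        assert sigma_est == pytest.approx(sigma_vox, rel=0.05)


class TestFitAndContrast:
    def _design(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return glm.build_design(
            {"a": rng.normal(size=n), "b": rng.normal(size=n)}, np.arange(n) * 1.0
        )

    def test_noiseless_recovery_exact(self):
        d = self._design()
        beta_true = np.array([[2.0, -1.0, 5.0], [0.5, 3.0, -2.0]])
        Y = beta_true @ d.X.T
        fit = glm.fit_glm(Y, d)
        assert np.allclose(fit.beta, beta_true, atol=1e-10)
        assert np.allclose(fit.mse, 0.0, atol=1e-18)

    def test_orthonormal_design_identity(self):
        n = 100
        q, _ = np.linalg.qr(np.random.default_rng(1).normal(size=(n, 3)))
        d = glm.DesignMatrix(X=q, names=["a", "b", "c"], volume_times=np.arange(n) * 1.0)
        Y = np.random.default_rng(2).normal(size=(5, n))
        fit = glm.fit_glm(Y, d)
        assert np.allclose(fit.beta, Y @ q, atol=1e-10)

    def test_row_mismatch_raises(self):
        d = self._design(n=100)
        with pytest.raises(ValueError):
            glm.fit_glm(np.zeros((3, 99)), d)

    def test_contrast_scale_invariance(self):
        d = self._design()
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(50, d.X.shape[0]))
        fit = glm.fit_glm(Y, d)
        t1 = glm.contrast_t(fit, [1, 0, 0]).t
        t2 = glm.contrast_t(fit, [2, 0, 0]).t
        assert np.allclose(t1, t2)

    def test_contrast_t_matches_analytic_expectation(self):
        """Known beta/sigma: mean voxel t within 10% of beta/SE."""
        rng = np.random.default_rng(4)
        n, nv = 300, 1000
        x = rng.normal(size=n)
        d = glm.build_design({"a": x}, np.arange(n) * 1.0)
        beta, sigma = 0.5, 1.0
        Y = beta * x[None, :] + sigma * rng.normal(size=(nv, n))
        fit = glm.fit_glm(Y, d)
        t = glm.contrast_t(fit, [1, 0]).t
        xc = x - x.mean()
        expected = beta * np.sqrt((xc**2).sum()) / sigma
        assert t.mean() == pytest.approx(expected, rel=0.1)


class TestSecondLevel:
    def test_df_is_n_minus_one(self):
        maps = [np.random.default_rng(i).normal(size=(4, 4, 4)) for i in range(18)]
        res = glm.second_level(maps)
        assert res.df == 17

    def test_identical_maps_flagged_infinite(self):
        m = np.ones((3, 3, 3))
        res = glm.second_level([m, m, m])
        assert np.all(np.isinf(res.t))

    def test_zero_mean_gives_small_t(self):
        m = np.ones((3, 3, 3))
        res = glm.second_level([m, -m])
        assert np.allclose(res.t, 0.0)


class TestThreshold:
    def test_critical_t_oracle(self):
        """p = 0.001, df = 17 uncorrected: t_crit = 3.646."""
        spec = glm.ThresholdSpec(method="uncorrected_p", level=0.001)
        assert glm.critical_t(spec, 17, 1000) == pytest.approx(3.646, abs=1e-3)

    def test_bonferroni_m1_equals_uncorrected(self):
        u = glm.ThresholdSpec(method="uncorrected_p", level=0.01)
        b = glm.ThresholdSpec(method="bonferroni", level=0.01)
        assert glm.critical_t(u, 20, 1) == glm.critical_t(b, 20, 1)

    def test_bonferroni_nondecreasing_in_mask_size(self):
        spec = glm.ThresholdSpec(method="bonferroni", level=0.05)
        ts = [glm.critical_t(spec, 17, m) for m in (10, 100, 1000, 10000)]
        assert all(b >= a for a, b in zip(ts, ts[1:]))

    def test_cluster_extent_removes_small_clusters(self):
        t = np.zeros((10, 10, 10))
        t[1:4, 1:4, 1:4] = 10.0  # 27-voxel cluster
        t[8, 8, 8] = 10.0  # singleton
        smap = glm.StatMap(t=t, df=17)
        spec = glm.ThresholdSpec(level=0.001, cluster_extent=10)
        binary, clusters = glm.threshold_map(smap, spec)
        assert binary.sum() == 27
        assert len(clusters) == 1 and clusters[0]["size"] == 27
        big = glm.ThresholdSpec(level=0.001, cluster_extent=1000)
        binary2, clusters2 = glm.threshold_map(smap, big)
        assert binary2.sum() == 0 and clusters2 == []

    def test_empty_mask_raises(self):
        smap = glm.StatMap(t=np.zeros((3, 3, 3)), df=10)
        with pytest.raises(ValueError):
            glm.threshold_map(smap, glm.ThresholdSpec(), mask=np.zeros((3, 3, 3), bool))
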