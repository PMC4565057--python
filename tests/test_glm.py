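import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import betaconn as bc
from betaconn.design import ColumnInfo, DesignMatrix


def tiny_design(X, tr=2.0):
    """Wrap a plain matrix as a one-run design of trial columns."""
    cols = [
        ColumnInfo(name=f"t{i}", kind="trial", run=1, condition="c",
                   trial_index=i, basis="hrf", onset=float(i))
        for i in range(X.shape[1])
    ]
    return DesignMatrix(matrix=np.asarray(X, float), columns=cols, tr=tr,
                        run_scans={1: X.shape[0]})


def tiny_image(y):
    """(scans,) or (scans, voxels) array as a 1xVx1 image."""
    y = np.atleast_2d(np.asarray(y, float))
    if y.shape[0] == 1 and y.size > 1:
        y = y.T
    n, v = y.shape
    return bc.TimeSeriesImage(y.T.reshape(v, 1, 1, n), np.eye(4), tr=2.0)


def full_mask(img):
    return bc.VolumeMap(np.ones(img.shape, dtype=np.uint8), img.affine, "mask")


class TestFitOls:
    def test_identity_design_returns_data(self):
        img = tiny_image([3.0, 7.0])
        est = bc.fit_ols(img, tiny_design(np.eye(2)), full_mask(img))
        np.testing.assert_allclose(est.betas[:, 0], [3.0, 7.0])

    def test_exact_solution_zero_residual(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        img = tiny_image([1.0, 2.0, 3.0])
        est = bc.fit_ols(img, tiny_design(X), full_mask(img))
        np.testing.assert_allclose(est.betas[:, 0], [1.0, 2.0], atol=1e-12)
        np.testing.assert_allclose(est.residuals[:, 0], 0.0, atol=1e-12)

    def test_residuals_orthogonal_to_design(self, small_fit):
        design, est = small_fit
        inner = design.matrix.T @ np.nan_to_num(est.residuals)
        scale = np.linalg.norm(design.matrix, axis=0)[:, None] * (
            np.linalg.norm(np.nan_to_num(est.residuals), axis=0)[None, :] + 1e-30
        )
        assert np.nanmax(np.abs(inner) / (scale + 1e-30)) < 1e-8

    def test_zero_variance_voxel_flagged(self):
        y = np.column_stack([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        img = tiny_image(y)
        est = bc.fit_ols(img, tiny_design(np.eye(3)), full_mask(img))
        assert est.valid.tolist() == [True, False]
        assert np.isnan(est.betas[:, 1]).all()

    def test_noise_free_simulation_recovers_amplitudes(self):
        spec = bc.SimulationSpec(
            grid_shape=(4, 4, 2), n_regions=2, conditions=("a", "b"),
            trials_per_condition_per_run=4, runs=2, noise_sd=0.0,
            drift_amplitude=0.0, seed=7,
        )
        ds = bc.simulate_dataset(spec)
        d = bc.build_design(ds.events, ds.confounds, [r.n_scans for r in ds.runs], spec.tr)
        est = bc.fit_ols(ds.runs, d, ds.mask)
        for cond in spec.conditions:
            series = bc.extract_beta_series(est, d, cond)
            roi = bc.roi_mean_series(series, ds.atlas)
            np.testing.assert_allclose(roi.values, ds.amplitudes[cond], atol=1e-8)


class TestAr1:
    def test_hand_computed_lag1_ratio(self):
        r = np.array([1.0, 0.5, 0.25, 0.125])
        expected = 0.65625 / 1.328125
        assert bc.estimate_ar1(r[:, None]) == pytest.approx(expected, abs=1e-6)

    def test_white_noise_near_zero(self, rng):
        r = rng.standard_normal((10_000, 1))
        assert abs(bc.estimate_ar1(r)) < 0.05

    def test_ar_process_recovered(self, rng):
        n, rho = 10_000, 0.3
        e = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = e[0]
        for t in range(1, n):
            x[t] = rho * x[t - 1] + e[t]
        assert 0.25 < bc.estimate_ar1(x[:, None]) < 0.35

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            bc.estimate_ar1(np.zeros((10, 1)))

    def test_design_correction_undoes_projection_shrinkage(self, rng):
        # residuals of an OLS fit are P@eps; the raw lag-1 ratio understates
        # rho, the moment-matched estimate recovers it
        n, p, rho = 200, 40, 0.3
        X = rng.standard_normal((n, p))
        P = np.eye(n) - X @ np.linalg.pinv(X)
        e = rng.standard_normal((n, 200))
        x = np.empty_like(e)
        x[0] = e[0]
        for t in range(1, n):
            x[t] = rho * x[t - 1] + e[t]
        resid = P @ x
        raw = bc.estimate_ar1(resid)
        corrected = bc.estimate_ar1(resid, design=X)
        assert abs(corrected - rho) < 0.05
        assert abs(corrected - rho) < abs(raw - rho)


class TestPrewhiten:
    def test_rho_zero_equals_ols(self, small_dataset, small_fit):
        ds = small_dataset
        design, est = small_fit
        white = bc.prewhiten_fit(ds.runs, design, 0.0)
        np.testing.assert_allclose(
            white.betas[:, est.voxel_indices[est.valid]][:, :5],
            est.betas[:, est.valid][:, :5],
            atol=1e-10,
        )

    def test_whitened_residuals_decorrelated(self):
        spec = bc.two_region_spec(0.8, seed=11, ar_rho=0.3)
        ds = bc.simulate_dataset(spec)
        d = bc.build_design(ds.events, ds.confounds, [r.n_scans for r in ds.runs], spec.tr)
        est = bc.fit_glm(ds.runs, d, ds.mask, ar1=True)
        resid_rho = bc.estimate_ar1(
            est.residuals[:, est.valid],
            run_lengths=list(d.run_scans.values()),
            design=d,
        )
        assert -0.05 < resid_rho < 0.05

    def test_rho_out_of_range_rejected(self, small_dataset, small_fit):
        with pytest.raises(ValueError):
            bc.prewhiten_fit(small_dataset.runs, small_fit[0], 1.0)


class TestAmplitudeOfEffect:
    @pytest.mark.parametrize(
        "b, expected",
        [((3.0, 0.0, 0.0), 3.0), ((-3.0, 4.0, 0.0), -5.0), ((0.0, 3.0, 4.0), 0.0)],
    )
    def test_hand_values(self, b, expected):
        assert bc.amplitude_of_effect(*b) == pytest.approx(expected)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.floats(-1e6, 1e6), st.floats(-1e6, 1e6), st.floats(-1e6, 1e6)
    )
    def test_magnitude_dominates_b1(self, b1, b2, b3):
        amp = bc.amplitude_of_effect(b1, b2, b3)
        assert abs(amp) >= abs(b1) - 1e-9
        if b2 == 0 and b3 == 0:
            assert amp == pytest.approx(b1)


class TestOutlierFlags:
    def test_gross_outlier_flagged(self):
        flags = bc.flag_outlier_trials(np.array([1.0, 1.0, 1.0, 1.0, 100.0]))
        assert flags.tolist() == [False, False, False, False, True]

    def test_constant_series_unflagged(self):
        assert not bc.flag_outlier_trials(np.ones(6)).any()

    def test_false_flag_rate_under_null(self, rng):
        x = rng.standard_normal((20, 500))
        assert bc.flag_outlier_trials(x).mean() < 0.05

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            bc.flag_outlier_trials(np.ones(4))
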