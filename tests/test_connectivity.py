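import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import betaconn as bc
from betaconn.connectivity import Z_CLIP


class TestFisherZ:
    def test_values(self):
        assert bc.fisher_z(0.0) == 0.0
        assert bc.fisher_z(0.7) == pytest.approx(0.5 * np.log(1.7 / 0.3), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bc.fisher_z(1.5)

    def test_inverse_round_trip(self):
        assert bc.fisher_z_inverse(0.0) == 0.0
        assert bc.fisher_z_inverse(bc.fisher_z(0.3)) == pytest.approx(0.3, abs=1e-12)
        assert bc.fisher_z_inverse(0.8673) == pytest.approx(0.7, abs=1e-4)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
    def test_odd_and_strictly_increasing(self, r1, r2):
        assert bc.fisher_z(-r1) == pytest.approx(-bc.fisher_z(r1), abs=1e-12)
        if r1 < r2:
            assert bc.fisher_z(r1) < bc.fisher_z(r2)


class TestSem:
    @pytest.mark.parametrize("n, sem", [(4, 1.0), (12, 1 / 3), (24, 1 / np.sqrt(21))])
    def test_formula(self, n, sem):
        assert bc.beta_series_sem(n) == pytest.approx(sem, abs=1e-12)

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            bc.beta_series_sem(3)


class TestCorrelationMatrix:
    def test_hand_computed_pearson(self):
        series = bc.RoiBetaSeries(
            values=np.array([[1.0, 1.0], [2.0, 3.0], [3.0, 2.0], [4.0, 4.0]]),
            labels=["a", "b"],
        )
        mat = bc.correlation_matrix(series)
        assert bc.fisher_z_inverse(mat.values[0, 1]) == pytest.approx(0.8, abs=1e-12)
        assert mat.values[0, 1] == pytest.approx(0.5 * np.log(9), abs=1e-12)

    def test_perfect_anticorrelation_clipped(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        series = bc.RoiBetaSeries(np.column_stack([x, -x]), labels=["a", "b"])
        mat = bc.correlation_matrix(series)
        assert mat.values[0, 1] == pytest.approx(-Z_CLIP)
        assert np.isfinite(mat.values).all()

    def test_spearman_monotone_invariance(self, rng):
        y = rng.standard_normal(20)
        series = bc.RoiBetaSeries(np.column_stack([y, np.exp(y)]), labels=["a", "b"])
        mat = bc.correlation_matrix(series, method="spearman")
        assert mat.values[0, 1] == pytest.approx(Z_CLIP)

    def test_symmetric_zero_diagonal(self, rng):
        series = bc.RoiBetaSeries(rng.standard_normal((24, 6)), labels=list("abcdef"))
        mat = bc.correlation_matrix(series)
        np.testing.assert_array_equal(mat.values, mat.values.T)
        np.testing.assert_array_equal(np.diag(mat.values), 0.0)

    def test_zero_variance_column_goes_missing(self, rng):
        vals = rng.standard_normal((10, 3))
        vals[:, 1] = 2.0
        mat = bc.correlation_matrix(bc.RoiBetaSeries(vals, labels=list("abc")))
        assert np.isnan(mat.values[0, 1]) and np.isnan(mat.values[1, 2])
        assert np.isfinite(mat.values[0, 2])


class TestRoiMeanSeries:
    def test_mean_of_two_voxels(self, rng):
        atlas = bc.phantom_atlas((2, 1, 1), 1)
        betas = bc.BetaSeriesImage(
            values=np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]]),
            condition="c",
            voxel_indices=np.array([0, 1]),
            shape=(2, 1, 1),
            affine=atlas.affine,
            valid=np.array([True, True]),
        )
        roi = bc.roi_mean_series(betas, atlas)
        np.testing.assert_allclose(roi.values[:, 0], [2.0, 2.0, 2.0])

    def test_single_voxel_roi_is_identity(self, small_fit, small_dataset):
        design, est = small_fit
        series = bc.extract_beta_series(est, design, design.conditions[0])
        one = bc.Atlas(
            labels=np.zeros(small_dataset.mask.shape, dtype=np.int32),
            affine=small_dataset.mask.affine,
            names={},
        )
        one.labels[0, 0, 0] = 1
        one.names = {1: "solo"}
        roi = bc.roi_mean_series(series, one)
        np.testing.assert_allclose(roi.values[:, 0], series.values[:, 0])

    def test_empty_roi_dropped(self, small_fit, small_dataset):
        design, est = small_fit
        series = bc.extract_beta_series(est, design, design.conditions[0])
        series.valid = series.valid.copy()
        flat = small_dataset.atlas.labels.reshape(-1)[series.voxel_indices]
        series.valid[flat == 1] = False
        roi = bc.roi_mean_series(series, small_dataset.atlas)
        assert "Region_1" not in roi.labels
        assert roi.n_rois == small_dataset.atlas.region_count - 1


class TestSphereRoi:
    def test_radius_zero_single_voxel(self):
        mask = bc.sphere_roi((0, 0, 0), 0.0, (5, 5, 5), _affine3(center=True))
        assert mask.data.sum() == 1

    @pytest.mark.parametrize("radius, count", [(6.0, 33), (3.0, 7)])
    def test_lattice_counts_on_3mm_grid(self, radius, count):
        mask = bc.sphere_roi((0, 0, 0), radius, (9, 9, 9), _affine3(center=True))
        assert mask.data.sum() == count

    def test_center_outside_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            bc.sphere_roi((100, 0, 0), 6.0, (5, 5, 5), _affine3(center=True))


def _affine3(center=False):
    aff = np.diag([3.0, 3.0, 3.0, 1.0])
    if center:
        aff[:3, 3] = -3.0 * 4  # 9-grid centered at origin
    return aff


class TestSeedMap:
    def _betas(self, values, shape, affine):
        n_vox = int(np.prod(shape))
        return bc.BetaSeriesImage(
            values=values, condition="c",
            voxel_indices=np.arange(n_vox), shape=shape, affine=affine,
            valid=np.ones(n_vox, dtype=bool),
        )

    def test_single_voxel_seed_self_correlation_at_clip(self, rng):
        shape = (3, 3, 1)
        betas = self._betas(rng.standard_normal((10, 9)), shape, np.eye(4))
        seed = bc.VolumeMap(np.zeros(shape, np.uint8), np.eye(4), "mask")
        seed.data[1, 1, 0] = 1
        zmap = bc.seed_connectivity_map(betas, seed)
        assert zmap.data[1, 1, 0] == pytest.approx(Z_CLIP)

    def test_identical_series_everywhere_constant_map(self, rng):
        shape = (2, 2, 2)
        one = rng.standard_normal(8)
        betas = self._betas(np.tile(one[:, None], (1, 8)), shape, np.eye(4))
        seed = bc.VolumeMap(np.ones(shape, np.uint8), np.eye(4), "mask")
        zmap = bc.seed_connectivity_map(betas, seed)
        np.testing.assert_allclose(zmap.data, Z_CLIP)

    def test_defined_voxels_match_target_mask(self, rng):
        shape = (3, 3, 1)
        betas = self._betas(rng.standard_normal((12, 9)), shape, np.eye(4))
        seed = bc.VolumeMap(np.ones(shape, np.uint8), np.eye(4), "mask")
        target = bc.VolumeMap(np.zeros(shape, np.uint8), np.eye(4), "mask")
        target.data[:, 0, 0] = 1
        zmap = bc.seed_connectivity_map(betas, seed, target)
        assert np.isfinite(zmap.data).sum() == target.data.sum()

    def test_empty_seed_rejected(self, rng):
        shape = (2, 2, 1)
        betas = self._betas(rng.standard_normal((8, 4)), shape, np.eye(4))
        seed = bc.VolumeMap(np.zeros(shape, np.uint8), np.eye(4), "mask")
        with pytest.raises(ValueError, match="seed"):
            bc.seed_connectivity_map(betas, seed)


class TestEdgeCount:
    @pytest.mark.parametrize(
        "n, expected", [(1, 0), (2, 1), (90, 4005), (70_000, 2_449_965_000)]
    )
    def test_formula(self, n, expected):
        assert bc.edge_count(n) == expected
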