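"""Lesion image operations and lesion-symptom mapping inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cohmap.lesion_mapping import (LesionDataset, LesionImage, binarize,
                                   fwhm_to_sigma, lesion_volume, smooth,
                                   svr_lsm, vbcm, vbcm_multi)
from cohmap.synthetic_data import GeneratorConfig, make_lesion_cohort


class TestSmooth:
    def test_fwhm_zero_is_identity(self):
        img = LesionImage(np.random.default_rng(0).random((8, 8, 8)))
        out = smooth(img, 0.0)
        np.testing.assert_array_equal(out.values, img.values)

    def test_uniform_image_stays_uniform_in_interior(self):
        img = LesionImage(np.full((16, 16, 16), 0.5))
        out = smooth(img, 8.0)
        np.testing.assert_allclose(out.values[6:10, 6:10, 6:10], 0.5, atol=1e-10)

    def test_impulse_matches_direct_gaussian_kernel(self):
        # single-voxel impulse, 8 mm FWHM on 2 mm voxels -> sigma ~ 1.699 vox
        vals = np.zeros((15, 15, 15))
        vals[7, 7, 7] = 1.0
        out = smooth(LesionImage(vals, voxel_size=2.0), 8.0)
        sigma = fwhm_to_sigma(8.0) / 2.0
        assert sigma == pytest.approx(1.6986, abs=1e-4)
        # brute-force separable kernel, same truncation as the implementation
        r = int(4.0 * sigma + 0.5)
        x = np.arange(-r, r + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        expected = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        got = out.values[7 - r:7 + r + 1, 7 - r:7 + r + 1, 7 - r:7 + r + 1]
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_unknown_voxel_size_rejected(self):
        img = LesionImage(np.zeros((4, 4, 4)))
        img.voxel_size = None
        with pytest.raises(ValueError, match="voxel size"):
            smooth(img, 8.0)


class TestBinarizeAndVolume:
    def test_strict_threshold(self):
        img = LesionImage(np.array([[[0.51, 0.5, 0.49, 0.0]]]))
        out = binarize(img, u=0.5)
        np.testing.assert_array_equal(out.values.ravel(), [1, 0, 0, 0])

    def test_all_zero_warns_empty(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            out = binarize(LesionImage(np.zeros((3, 3, 3))))
        assert out.values.sum() == 0

    def test_lesion_volume_counts_ones(self):
        vals = np.zeros((3, 3, 3))
        vals[0, 0, :2] = 1
        vals[1, 1, :3] = 1
        assert lesion_volume(LesionImage(vals)) == 5
        assert lesion_volume(LesionImage(np.zeros((3, 3, 3)))) == 0

    def test_generated_volumes_within_reference_range(self):
        cfg = GeneratorConfig(seed=5, n_patients=12)
        ds, _ = make_lesion_cohort(cfg, continuous=False)
        vols = ds.lesion_volumes()
        assert (vols >= 175).all() and (vols <= 41379).all()


def _toy_dataset(seed=0, n=10, p=5, covariates=0):
    """n patients x p voxels laid out along one axis, continuous values."""
    rng = np.random.default_rng(seed)
    images = np.zeros((n, p, 1, 1))
    images[:, :, 0, 0] = rng.random((n, p))
    behaviour = rng.normal(size=n)
    covs = pd.DataFrame(
        {f"c{j}": rng.normal(size=n) for j in range(covariates)},
        index=range(n))
    return LesionDataset(images=images, behaviour=behaviour, covariates=covs)


class TestVbcm:
    def test_t_matches_correlation_t_closed_form(self):
        ds = _toy_dataset(seed=1)
        smap, _ = vbcm(ds, n_perm=100, voxel_p=0.05, seed=2)
        V = ds.images[:, :, 0, 0]
        n = ds.n
        for j in range(V.shape[1]):
            r = np.corrcoef(V[:, j], ds.behaviour)[0, 1]
            t_oracle = r * np.sqrt((n - 2) / (1 - r**2))
            assert smap.statistic[j, 0, 0] == pytest.approx(t_oracle, abs=1e-8)

    def test_t_matches_per_voxel_ols_with_covariates(self):
        import statsmodels.api as sm
        ds = _toy_dataset(seed=3, covariates=2)
        smap, _ = vbcm(ds, n_perm=100, voxel_p=0.05, seed=2)
        V = ds.images[:, :, 0, 0]
        for j in range(V.shape[1]):
            X = sm.add_constant(np.column_stack([V[:, j], ds.covariates.values]))
            fit = sm.OLS(ds.behaviour, X).fit()
            assert smap.statistic[j, 0, 0] == pytest.approx(fit.tvalues[1], abs=1e-8)

    def test_constant_behaviour_yields_no_suprathreshold(self):
        ds = _toy_dataset(seed=4)
        ds.behaviour[:] = 0.0
        ds.behaviour += np.linspace(0, 1e-12, ds.n)  # avoid exact zero norm
        smap, cset = vbcm(ds, n_perm=100, voxel_p=0.001, seed=5)
        assert len(cset.clusters) == 0

    def test_permutation_p_bounds(self):
        ds, _ = make_lesion_cohort(
            GeneratorConfig.lesion_recovery(seed=6, n_patients=20))
        _, cset = vbcm(ds, n_perm=200, voxel_p=0.01, seed=7)
        for c in cset.clusters:
            assert 1 / 201 <= c.p_fwe <= 1.0

    def test_zero_variance_voxels_excluded(self):
        ds = _toy_dataset(seed=8)
        ds.images[:, 2, 0, 0] = 0.7       # constant voxel
        ds.mask[:] = True
        smap, _ = vbcm(ds, n_perm=100, voxel_p=0.05, seed=9)
        assert not smap.mask[2, 0, 0]

    def test_planted_region_recovered(self):
        # strong planted effect; strict height threshold (p=1e-4) localizes
        # the cluster to the signal core rather than the smoothing halo
        dices = []
        for seed in (10, 11, 12):
            cfg = GeneratorConfig.lesion_recovery(seed=seed)
            ds, truth = make_lesion_cohort(cfg)
            _, cset = vbcm(ds, n_perm=300, voxel_p=1e-4, seed=seed + 1)
            sig = cset.significant(0.05)
            assert sig, f"no significant cluster at seed {seed}"
            top = max(sig, key=lambda c: c.size)
            m = np.zeros(ds.grid_shape, bool)
            m[tuple(top.voxels.T)] = True
            reg = truth.critical_region_mask
            dices.append(2 * (m & reg).sum() / (m.sum() + reg.sum()))
        assert np.median(dices) > 0.5
        assert min(dices) > 0.3


class TestVbcmMulti:
    def test_duplicate_regressor_rejected(self):
        ds = _toy_dataset(seed=12)
        with pytest.raises(ValueError, match="collinear"):
            vbcm_multi(ds, {"dup": ds.behaviour.copy()}, n_perm=100,
                       voxel_p=0.05)

    def test_noise_regressors_leave_map_essentially_unchanged(self):
        cfg = GeneratorConfig.lesion_recovery(seed=13)
        ds, _ = make_lesion_cohort(cfg)
        rng = np.random.default_rng(14)
        base_map, base_cl = vbcm(ds, n_perm=200, seed=15)
        out = vbcm_multi(ds, {"noise1": rng.normal(size=ds.n),
                              "noise2": rng.normal(size=ds.n)},
                         n_perm=200, seed=15)
        multi_map, multi_cl = out["behaviour"]
        sig_a = base_cl.significant(0.05)
        sig_b = multi_cl.significant(0.05)
        assert sig_a and sig_b
        a = np.zeros(ds.grid_shape, bool)
        b = np.zeros(ds.grid_shape, bool)
        a[tuple(max(sig_a, key=lambda c: c.size).voxels.T)] = True
        b[tuple(max(sig_b, key=lambda c: c.size).voxels.T)] = True
        dice = 2 * (a & b).sum() / (a.sum() + b.sum())
        assert dice > 0.8

    def test_signal_owned_by_other_regressor_removed(self):
        # behaviour's map loses the cluster when the true driver is included
        cfg = GeneratorConfig.lesion_recovery(seed=16)
        ds, truth = make_lesion_cohort(cfg)
        driver = np.array([truth.critical_load[f"P{i+1:02d}"]
                           for i in range(ds.n)])
        out = vbcm_multi(ds, {"driver": driver}, n_perm=200, seed=17)
        _, cl_beh = out["behaviour"]
        assert not cl_beh.significant(0.05)


class TestSvrLsm:
    def _binary_cohort(self, seed=0, n=20, shape=(10, 10, 10)):
        rng = np.random.default_rng(seed)
        images = (rng.random((n, *shape)) < 0.4).astype(float)
        behaviour = rng.normal(size=n)
        covs = pd.DataFrame(index=range(n))
        return LesionDataset(images=images, behaviour=behaviour,
                             covariates=covs), rng

    def test_lesion_threshold_excludes_low_coverage_voxels(self):
        ds, _ = self._binary_cohort(seed=1)
        ds.images[:, 0, 0, 0] = 0.0
        ds.images[:3, 0, 0, 0] = 1.0      # coverage 3 < threshold 4
        smap, _ = svr_lsm(ds, lesion_threshold=4, n_perm=100, voxel_p=0.05,
                          seed=2, hyperparameters=(1.0, 0.1))
        assert not smap.mask[0, 0, 0]
        coverage = ds.images.sum(axis=0)
        np.testing.assert_array_equal(smap.mask, coverage >= 4)

    def test_planted_single_voxel_attains_top_weight(self):
        for seed in range(3):
            ds, _ = self._binary_cohort(seed=seed)
            ds.behaviour = -1.0 * ds.images[:, 5, 5, 5]  # noiseless planted
            smap, _ = svr_lsm(ds, n_perm=100, voxel_p=0.05, seed=seed + 50,
                              hyperparameters=(100.0, 0.001))
            beta = np.abs(np.nan_to_num(smap.statistic))
            peak = np.unravel_index(np.argmax(beta), beta.shape)
            assert peak == (5, 5, 5)

    def test_volume_control_removes_volume_driven_signal(self):
        ds, _ = self._binary_cohort(seed=3, n=30)
        ds.behaviour = ds.lesion_volumes().astype(float)
        _, cset = svr_lsm(ds, n_perm=200, voxel_p=0.01, control_volume=True,
                          seed=4, hyperparameters=(1.0, 0.1))
        assert not cset.significant(0.05)

    def test_empty_feature_set_rejected(self):
        ds, _ = self._binary_cohort(seed=5, n=6)
        ds.images[:] = 0.0
        ds.images[0, 0, 0, 0] = 1.0
        ds.mask = np.ones(ds.grid_shape, bool)
        with pytest.raises(ValueError, match="empty feature set"):
            svr_lsm(ds, lesion_threshold=4, n_perm=100, seed=6,
                    hyperparameters=(1.0, 0.1))

    def test_constant_behaviour_rejected(self):
        ds, _ = self._binary_cohort(seed=7)
        ds.behaviour[:] = 1.0
        with pytest.raises(ValueError, match="degenerate behaviour"):
            svr_lsm(ds, n_perm=100, seed=8, hyperparameters=(1.0, 0.1))
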