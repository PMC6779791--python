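"""Group inference: GLM oracles, smoothness, cluster correction, scalars."""

import numpy as np
import pytest
from scipy import stats
from scipy.ndimage import gaussian_filter

from dynalff import (DesignMatrix, build_design, fit_voxelwise_glm,
                     estimate_fwhm, grf_cluster_correction,
                     permutation_cluster_correction, partial_correlation,
                     chi_square_2x2, group_scalar_test)


def _group_design(n_pat, n_con, covs=None):
    n = n_pat + n_con
    cols = [np.ones(n), np.repeat([1.0, 0.0], [n_pat, n_con])]
    labels = ["intercept", "group"]
    if covs is not None:
        cols.append(covs)
        labels += [f"c{i}" for i in range(np.atleast_2d(covs).T.shape[0]
                                          if covs.ndim == 1 else covs.shape[1])]
    if covs is not None and covs.ndim == 1:
        cols[-1] = covs[:, None]
        labels = labels[:3]
    return DesignMatrix(np.column_stack(cols), labels)


class TestVoxelwiseGlm:
    def test_group_contrast_equals_two_sample_t(self, rng):
        # oracle: pooled-variance two-sample t at every voxel
        for _ in range(100):
            n1, n2 = rng.integers(4, 12, size=2)
            maps = rng.normal(size=(n1 + n2, 2, 2, 1))
            design = _group_design(n1, n2)
            res = fit_voxelwise_glm(maps, design, "group")
            t_ref = stats.ttest_ind(maps[:n1], maps[n1:], axis=0).statistic
            np.testing.assert_allclose(res.t_map, t_ref, rtol=1e-10)
            assert res.df == n1 + n2 - 2

    def test_orthogonal_covariate_leaves_group_effect_unchanged(self, rng):
        n1 = n2 = 10
        maps = rng.normal(size=(20, 3, 3, 3))
        base = _group_design(n1, n2)
        cov = rng.normal(size=20)
        # orthogonalize against intercept and group columns
        Q = base.X @ np.linalg.lstsq(base.X, cov, rcond=None)[0]
        full = _group_design(n1, n2, cov - Q)
        b0 = fit_voxelwise_glm(maps, base, "group").beta[1]
        b1 = fit_voxelwise_glm(maps, full, "group").beta[1]
        np.testing.assert_allclose(b0, b1, atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(8), np.repeat([1, 0], 4),
                             np.repeat([2, 0], 4)])
        with pytest.raises(ValueError, match="rank"):
            DesignMatrix(X, ["intercept", "group", "group2"])

    def test_build_design_columns(self):
        import pandas as pd
        df = pd.DataFrame({"group": ["patient"] * 3 + ["control"] * 3,
                           "age": [60, 61, 59, 58, 62, 60.0],
                           "sex": ["M", "F", "M", "F", "M", "F"],
                           "mean_fd": [0.1, 0.2, 0.1, 0.15, 0.1, 0.2]})
        d = build_design(df)
        assert d.labels == ["intercept", "group", "age", "sex", "mean_fd"]
        np.testing.assert_array_equal(d.X[:, 1], [1, 1, 1, 0, 0, 0])
        assert abs(d.X[:, 2].mean()) < 1e-12  # centered


class TestEstimateFwhm:
    def test_white_noise_near_voxel_size(self, rng):
        R = rng.normal(size=(20, 16, 16, 16))
        fwhm = estimate_fwhm(R, 3.0)
        assert np.all(np.abs(fwhm - 3.0) < 0.2 * 3.0 + 1e-9)

    def test_smoothed_noise_recovers_kernel(self, rng):
        sigma_vox = 6.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        R = np.stack([gaussian_filter(rng.normal(size=(24, 24, 24)), sigma_vox)
                      for _ in range(20)])
        fwhm = estimate_fwhm(R, 3.0)
        assert np.all(np.abs(fwhm - 6.0) < 0.2 * 6.0)

    def test_units_scale_with_voxel_size(self, rng):
        R = rng.normal(size=(10, 12, 12, 12))
        np.testing.assert_allclose(2.0 * estimate_fwhm(R, 3.0),
                                   estimate_fwhm(R, 6.0))

    def test_too_few_maps_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_fwhm(rng.normal(size=(2, 8, 8, 8)), 3.0)


class TestGrfClusterCorrection:
    def test_zero_map_yields_empty_table(self):
        mask = np.ones((10, 10, 10), bool)
        table = grf_cluster_correction(np.zeros((10, 10, 10)), 50, mask,
                                       6.0, 3.0)
        assert len(table) == 0

    def test_planted_blob_recovered(self, rng):
        # strong focal blob + weak background: exactly one surviving cluster
        mask = np.ones((14, 14, 14), bool)
        t_map = rng.normal(scale=0.5, size=(14, 14, 14))
        blob = np.zeros_like(t_map, dtype=bool)
        blob[5:9, 5:9, 5:9] = True
        t_map[blob] = 8.0
        table = grf_cluster_correction(t_map, 50, mask, 6.0, 3.0)
        assert len(table) == 1
        cl = table.clusters[0]
        assert cl.size == blob.sum() and cl.p_cluster < 0.05
        got = np.zeros_like(blob)
        got[tuple(cl.voxel_indices.T)] = True
        assert (got & blob).sum() == blob.sum()

    def test_p_monotone_in_extent(self, rng):
        mask = np.ones((16, 16, 16), bool)
        ps = []
        for side in (2, 3, 4):
            t_map = np.zeros((16, 16, 16))
            t_map[:side, :side, :side] = 6.0
            table = grf_cluster_correction(t_map, 40, mask, 6.0, 3.0,
                                           cluster_p=0.999999)
            ps.append(table.clusters[0].p_cluster)
        assert ps[0] > ps[1] > ps[2]

    def test_negative_clusters_reported_with_sign(self):
        mask = np.ones((12, 12, 12), bool)
        t_map = np.zeros((12, 12, 12))
        t_map[2:6, 2:6, 2:6] = -7.0
        table = grf_cluster_correction(t_map, 40, mask, 6.0, 3.0)
        assert len(table) == 1 and table.clusters[0].sign == -1

    def test_invalid_thresholds_rejected(self):
        mask = np.ones((8, 8, 8), bool)
        with pytest.raises(ValueError):
            grf_cluster_correction(np.zeros((8, 8, 8)), 40, mask, 6.0, 3.0,
                                   voxel_p=1.5)

    def test_permutation_corrector_agrees_on_strong_effect(self, rng):
        # internal oracle: label-permutation max-extent null finds the same
        # dominant cluster as the parametric route
        n1 = n2 = 10
        maps = rng.normal(size=(20, 10, 10, 10))
        blob = np.zeros((10, 10, 10), bool)
        blob[3:7, 3:7, 3:7] = True
        maps[:n1, blob] += 3.0
        mask = np.ones((10, 10, 10), bool)
        design = _group_design(n1, n2)
        table = permutation_cluster_correction(maps, design, mask,
                                               n_perm=100, seed=0)
        assert len(table) >= 1
        got = np.zeros_like(blob)
        got[tuple(table.clusters[0].voxel_indices.T)] = True
        dice = 2 * (got & blob).sum() / (got.sum() + blob.sum())
        assert dice > 0.8


class TestPartialCorrelation:
    def test_identity_without_covariates(self, rng):
        x = rng.normal(size=20)
        r, p = partial_correlation(x, x)
        assert r == pytest.approx(1.0)
        # and plain Pearson for distinct vectors
        y = rng.normal(size=20)
        r2, p2 = partial_correlation(x, y)
        ref = stats.pearsonr(x, y)
        assert r2 == pytest.approx(ref.statistic, abs=1e-12)
        assert p2 == pytest.approx(ref.pvalue, rel=1e-9)

    def test_matches_two_stage_regression_oracle(self, rng):
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        Z = rng.normal(size=(10, 2))
        r, _ = partial_correlation(x, y, Z)
        # brute-force oracle: residualize both against [1|Z], correlate
        A = np.column_stack([np.ones(10), Z])
        rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
        ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        ref = np.corrcoef(rx, ry)[0, 1]
        assert r == pytest.approx(ref, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        df = pd.DataFrame({"x": rng.normal(size=25),
                           "y": rng.normal(size=25),
                           "z1": rng.normal(size=25),
                           "z2": rng.normal(size=25)})
        out = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        r, p = partial_correlation(df.x, df.y, df[["z1", "z2"]].to_numpy())
        p_col = "p_val" if "p_val" in out.columns else "p-val"
        assert r == pytest.approx(float(out["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(out[p_col].iloc[0]), rel=1e-6)

    def test_degenerate_residuals_rejected(self, rng):
        z = rng.normal(size=15)
        with pytest.raises(ValueError):
            partial_correlation(2 * z, -3 * z, z)


class TestChiSquare:
    def test_printed_sex_table(self):
        chi2, p = chi_square_2x2([[15, 13], [14, 14]])
        assert round(p, 3) == 0.789

    def test_no_association(self):
        chi2, p = chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == 1.0

    def test_perfect_association_closed_form(self):
        # N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 40
        chi2, p = chi_square_2x2([[20, 0], [0, 20]])
        assert chi2 == pytest.approx(40.0)
        assert p == pytest.approx(stats.chi2.sf(40.0, 1), rel=1e-9)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestGroupScalarTest:
    def test_equals_pooled_t_without_covariates(self, rng):
        for _ in range(20):
            a = rng.normal(size=9)
            b = rng.normal(size=7)
            t, p = group_scalar_test(np.concatenate([a, b]),
                                     np.repeat([1, 0], [9, 7]))
            ref = stats.ttest_ind(a, b)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_identical_groups_give_null_t(self):
        vals = np.concatenate([np.array([1.0, 2, 3]), np.array([1.0, 2, 3])])
        t, p = group_scalar_test(vals, np.repeat([1, 0], 3))
        assert abs(t) < 1e-12 and p > 0.99

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_scalar_test(np.ones(5), np.ones(5))
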