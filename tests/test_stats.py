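"""Voxelwise GLM, smoothness, GRF/permutation cluster inference, small-table stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.ndimage import gaussian_filter

from rehopredict import (
    BrainMask,
    DesignMatrix,
    chi_square_2x2,
    cohens_d_from_t,
    correlate_with_symptoms,
    estimate_smoothness_fwhm,
    grf_cluster_table,
    paired_t_map,
    permutation_cluster_oracle,
    voxelwise_glm_contrast,
)
from rehopredict.stats import TStatMap, SmoothnessEstimate, _grf_cluster_p


def _mask(shape):
    return BrainMask(np.ones(shape))


def _smooth_maps(n, shape, rng, sigma=1.0):
    return [gaussian_filter(rng.standard_normal(shape), sigma) for _ in range(n)]


class TestVoxelwiseGlm:
    def test_matches_closed_form_pooled_t(self):
        """Intercept+group design reproduces the textbook two-sample t."""
        maps = [np.full((3, 3, 3), v, float) for v in [1, 2, 3, 4, 5, 6]]
        design = DesignMatrix.two_sample(np.array([1, 1, 1, 2, 2, 2]))
        tmap = voxelwise_glm_contrast(maps, design, _mask((3, 3, 3)))
        # diff 3, pooled sd 1, se sqrt(2/3)
        assert tmap.data[0, 0, 0] == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), abs=1e-10)
        assert tmap.df == 4

    def test_matches_scipy_on_random_maps(self):
        rng = np.random.default_rng(0)
        group = np.repeat([1, 2], 8)
        maps = [rng.standard_normal((4, 4, 4)) for _ in group]
        design = DesignMatrix.two_sample(group)
        tmap = voxelwise_glm_contrast(maps, design, _mask((4, 4, 4)))
        a = np.stack(maps[:8])
        b = np.stack(maps[8:])
        ref = sps.ttest_ind(b, a, axis=0).statistic
        np.testing.assert_allclose(tmap.data, ref, atol=1e-10)

    def test_orthogonal_covariate_only_costs_df(self):
        rng = np.random.default_rng(1)
        group = np.repeat([1, 2], 10)
        maps = [rng.standard_normal((3, 3, 3)) for _ in group]
        d0 = DesignMatrix.two_sample(group)
        # covariate orthogonal to the design AND to the data, so the fit is
        # unchanged and t moves only through the df-adjusted variance
        cov = np.tile([1.0, -1.0], 10).astype(float)
        cov -= d0.X @ np.linalg.lstsq(d0.X, cov, rcond=None)[0]
        Y = np.stack([m.ravel() for m in maps])
        Y -= np.outer(cov, cov @ Y) / (cov @ cov)
        maps = [y.reshape(3, 3, 3) for y in Y]
        d1 = DesignMatrix.two_sample(group, cov[:, None])
        t0 = voxelwise_glm_contrast(maps, d0, _mask((3, 3, 3)))
        t1 = voxelwise_glm_contrast(maps, d1, _mask((3, 3, 3)))
        assert t1.df == t0.df - 1
        # same contrast estimate and residual sums: t changes only via df
        np.testing.assert_allclose(
            t1.data * np.sqrt(t0.df) / np.sqrt(t1.df), t0.data, rtol=1e-6
        )

    def test_identical_groups_give_zero_t(self):
        base = np.random.default_rng(2).standard_normal((3, 3, 3))
        maps = [base.copy() for _ in range(6)]
        design = DesignMatrix.two_sample(np.array([1, 1, 1, 2, 2, 2]))
        with pytest.warns(RuntimeWarning):
            tmap = voxelwise_glm_contrast(maps, design, _mask((3, 3, 3)))
        np.testing.assert_array_equal(tmap.data, 0.0)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError):
            DesignMatrix(X, np.array([0.0, 1.0]))


class TestPairedT:
    def test_worked_differences(self):
        pre = [np.zeros((2, 2, 2))] * 3
        post = [np.full((2, 2, 2), v, float) for v in [1, 2, 3]]
        tmap = paired_t_map(pre, post, _mask((2, 2, 2)))
        assert tmap.data[0, 0, 0] == pytest.approx(2.0 * np.sqrt(3.0), abs=1e-6)
        assert tmap.df == 2

    def test_identical_pre_post_zero_with_warning(self):
        maps = [np.random.default_rng(i).standard_normal((2, 2, 2)) for i in range(4)]
        with pytest.warns(RuntimeWarning):
            tmap = paired_t_map(maps, maps, _mask((2, 2, 2)))
        np.testing.assert_array_equal(tmap.data, 0.0)

    def test_sign_flip_negates_t(self):
        rng = np.random.default_rng(3)
        pre = [rng.standard_normal((2, 2, 2)) for _ in range(5)]
        post = [rng.standard_normal((2, 2, 2)) for _ in range(5)]
        t1 = paired_t_map(pre, post, _mask((2, 2, 2)))
        t2 = paired_t_map(post, pre, _mask((2, 2, 2)))
        np.testing.assert_allclose(t1.data, -t2.data, atol=1e-10)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_map([np.zeros((2, 2, 2))] * 3, [np.zeros((2, 2, 2))] * 4,
                         _mask((2, 2, 2)))


class TestSmoothnessEstimate:
    def test_recovers_applied_kernel_fwhm(self):
        """Truth = the smoothing kernel: 6 mm FWHM on 3 mm voxels."""
        sigma_vox = 6.0 / (3.0 * np.sqrt(8 * np.log(2)))
        ests = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            res = np.stack(_smooth_maps(12, (20, 20, 20), rng, sigma_vox))
            est = estimate_smoothness_fwhm(res, _mask((20, 20, 20)), (3, 3, 3))
            ests.append(np.mean(est.fwhm_mm))
        assert np.mean(ests) == pytest.approx(6.0, rel=0.15)

    def test_unsmoothed_noise_estimates_one_voxel(self):
        rng = np.random.default_rng(0)
        res = rng.standard_normal((10, 16, 16, 16))
        est = estimate_smoothness_fwhm(res, _mask((16, 16, 16)), (3, 3, 3))
        assert np.mean(est.fwhm_mm) == pytest.approx(3.0, rel=0.2)

    def test_voxel_size_scales_fwhm_in_mm(self):
        rng = np.random.default_rng(1)
        res = np.stack(_smooth_maps(8, (14, 14, 14), rng, 1.2))
        e1 = estimate_smoothness_fwhm(res, _mask((14, 14, 14)), (3, 3, 3))
        e2 = estimate_smoothness_fwhm(res, _mask((14, 14, 14)), (6, 6, 6))
        np.testing.assert_allclose(np.array(e2.fwhm_mm), 2 * np.array(e1.fwhm_mm))

    def test_too_few_maps_rejected(self):
        with pytest.raises(ValueError):
            estimate_smoothness_fwhm(np.zeros((2, 8, 8, 8)), _mask((8, 8, 8)))


class TestGrfClusterTable:
    def _tmap_with_blob(self, shape=(16, 16, 16), peak=8.0, df=38):
        data = np.zeros(shape)
        data[5:9, 5:9, 5:9] = peak
        return TStatMap(data=data, df=df)

    def _smoothness(self):
        return SmoothnessEstimate(fwhm_mm=(6, 6, 6), fwhm_vox=(2, 2, 2),
                                  resel_count=16 ** 3 / 8)

    def test_no_suprathreshold_voxels_gives_empty_table(self):
        tmap = TStatMap(data=np.zeros((8, 8, 8)), df=30)
        table = grf_cluster_table(tmap, self._smoothness(), _mask((8, 8, 8)))
        assert len(table) == 0

    def test_strong_blob_detected_with_correct_extent_and_sign(self):
        table = grf_cluster_table(
            self._tmap_with_blob(), self._smoothness(), _mask((16, 16, 16)),
            n1=20, n2=20,
        )
        assert len(table) == 1
        row = table.iloc[0]
        assert row["sign"] == "+" and row["n_voxels"] == 64
        assert row["peak_t"] == pytest.approx(8.0)
        assert row["p_corrected"] < 0.025
        assert row["cohens_d"] == pytest.approx(8.0 * np.sqrt(0.1), abs=1e-6)

    def test_negative_blob_reported_with_minus_sign(self):
        tmap = self._tmap_with_blob(peak=-8.0)
        table = grf_cluster_table(tmap, self._smoothness(), _mask((16, 16, 16)))
        assert len(table) == 1 and table.iloc[0]["sign"] == "-"

    def test_corrected_p_nonincreasing_in_extent(self):
        ps = [_grf_cluster_p(k, 3.1, 500.0, 6859) for k in [5, 20, 80, 200]]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_deterministic_given_identical_inputs(self):
        t1 = grf_cluster_table(self._tmap_with_blob(), self._smoothness(),
                               _mask((16, 16, 16)))
        t2 = grf_cluster_table(self._tmap_with_blob(), self._smoothness(),
                               _mask((16, 16, 16)))
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            grf_cluster_table(self._tmap_with_blob(), self._smoothness(),
                              _mask((16, 16, 16)), voxel_p=2.0)


class TestPermutationOracle:
    def test_single_group_rejected(self):
        maps = [np.zeros((4, 4, 4))] * 6
        with pytest.raises(ValueError):
            design = DesignMatrix.two_sample(np.array([1, 1, 1, 1, 1, 1]))

    def test_planted_effect_found_and_p_at_floor(self):
        """Observed cluster larger than all null maxima -> p = 1/(n_perm+1)."""
        rng = np.random.default_rng(0)
        shape = (10, 10, 10)
        group = np.repeat([1, 2], 10)
        maps = []
        for g in group:
            m = gaussian_filter(rng.standard_normal(shape), 0.8)
            if g == 2:
                m[2:7, 2:7, 2:7] += 3.0
            maps.append(m)
        design = DesignMatrix.two_sample(group)
        table = permutation_cluster_oracle(
            maps, design, _mask(shape), voxel_p=0.001, n_perm=99, seed=1
        )
        assert len(table) >= 1
        assert table.iloc[0]["p_corrected"] == pytest.approx(1.0 / 100.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        group = np.repeat([1, 2], 6)
        maps = [gaussian_filter(rng.standard_normal((8, 8, 8)), 0.8) + (g == 2) * 2.0
                for g in group]
        design = DesignMatrix.two_sample(group)
        kw = dict(voxel_p=0.01, n_perm=120, seed=9)
        t1 = permutation_cluster_oracle(maps, design, _mask((8, 8, 8)), **kw)
        t2 = permutation_cluster_oracle(maps, design, _mask((8, 8, 8)), **kw)
        pd.testing.assert_frame_equal(t1, t2)


class TestEffectSizesAndTables:
    @pytest.mark.parametrize(
        "t,expected",
        [(-3.39, -0.65), (4.94, 0.95), (4.43, 0.85), (-3.42, -0.66), (0.0, 0.0)],
    )
    def test_two_sample_d_from_t_54_per_group(self, t, expected):
        assert cohens_d_from_t(t, "two_sample", 54, 54) == pytest.approx(
            expected, abs=0.005
        )

    def test_paired_d_formulas(self):
        assert cohens_d_from_t(4.57, "paired", 36) == pytest.approx(4.57 / 6.0)
        alt = cohens_d_from_t(4.57, "paired", 36,
                              paired_formula="t_times_2_over_sqrt_df")
        assert alt == pytest.approx(2 * 4.57 / np.sqrt(35))

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_from_t(1.0, "two_sample", 0, 5)

    def test_chi_square_matches_published_sex_table(self):
        chi2, df, v = chi_square_2x2([[25, 29], [21, 33]])
        assert chi2 == pytest.approx(0.61, abs=0.005)
        assert df == 1
        assert v == pytest.approx(np.sqrt(chi2 / 108), abs=1e-12)

    def test_proportional_table_gives_zero(self):
        chi2, _, v = chi_square_2x2([[10, 20], [30, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_table_hand_value(self):
        # N(ad-bc)^2 / product of marginals = 20*(100)^2/10^4 = 20
        chi2, _, _ = chi_square_2x2([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)

    def test_matches_scipy_chi2_contingency(self):
        from scipy.stats import chi2_contingency

        tab = [[25, 29], [21, 33]]
        ref = chi2_contingency(np.array(tab), correction=False).statistic
        assert chi_square_2x2(tab)[0] == pytest.approx(ref, abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestSymptomCorrelations:
    def test_exact_linear_relation_flagged(self):
        x = np.arange(10.0)
        feats = pd.DataFrame({"c0": x})
        scores = pd.DataFrame({"hama": 2 * x})
        out = correlate_with_symptoms(feats, scores, method="pearson", n_tests=50)
        assert out.iloc[0]["r"] == pytest.approx(1.0)
        assert bool(out.iloc[0]["significant_bonferroni"])

    def test_monotone_nonlinear_spearman_is_one(self):
        x = np.linspace(-2, 2, 12)
        out = correlate_with_symptoms(
            pd.DataFrame({"c0": x}), pd.DataFrame({"s": x ** 3}), method="spearman"
        )
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_auto_picks_spearman_for_skewed_data(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(54)
        y = np.exp(rng.standard_normal(54) * 2)  # heavily skewed
        out = correlate_with_symptoms(
            pd.DataFrame({"c0": x}), pd.DataFrame({"s": y}), method="auto"
        )
        assert out.iloc[0]["method"] == "spearman"

    def test_auto_picks_pearson_for_gaussian_data(self):
        rng = np.random.default_rng(0)
        out = correlate_with_symptoms(
            pd.DataFrame({"c0": rng.standard_normal(54)}),
            pd.DataFrame({"s": rng.standard_normal(54)}),
            method="auto",
        )
        assert out.iloc[0]["method"] == "pearson"

    def test_bonferroni_false_positive_rate_at_nominal_level(self):
        """Independent data: flag rate ~ alpha/n_tests summed over 9 tests."""
        rng = np.random.default_rng(2)
        n_sim, hits = 400, 0
        for _ in range(n_sim):
            feats = pd.DataFrame({"c0": rng.standard_normal(54)})
            scores = pd.DataFrame({f"s{j}": rng.standard_normal(54) for j in range(9)})
            out = correlate_with_symptoms(feats, scores, method="pearson", n_tests=9)
            hits += int(out["significant_bonferroni"].any())
        assert hits / n_sim == pytest.approx(0.05, abs=0.04)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            correlate_with_symptoms(
                pd.DataFrame({"c0": [1.0, 2.0]}), pd.DataFrame({"s": [1.0, 2.0]})
            )
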