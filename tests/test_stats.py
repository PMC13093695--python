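import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from niikit._tfce import neighbor_table, tfce_flat, tfce_ndimage
from niikit.simulate import CohortSpec, cohort_table, make_cohort, stack_metric_maps
from niikit.stats import (DesignError, DesignMatrix, build_design,
                          chi_square_2x2, glm_tstat, permutation_fwe, tfce,
                          wilcoxon_rank_sum)


def two_group_design(n_per_group, covs=None):
    n = 2 * n_per_group
    cols = [np.ones(n), np.repeat([0.0, 1.0], n_per_group)]
    names = ["intercept", "group"]
    if covs is not None:
        cols.extend(covs)
        names.extend(f"c{i}" for i in range(len(covs)))
    X = np.column_stack(cols)
    c = np.zeros(X.shape[1])
    c[1] = 1.0
    return DesignMatrix(X=X, contrast=c, names=names)


class TestGlmTstat:
    def test_equal_group_means_give_zero_t(self):
        data = np.tile([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], (4, 1))
        t = glm_tstat(data, two_group_design(3))
        np.testing.assert_allclose(t, 0.0, atol=1e-10)

    def test_matches_pooled_two_sample_t(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        y = rng.normal(0.8, size=10)
        t_ref, _ = sps.ttest_ind(y, x)  # pooled variance
        t = glm_tstat(np.concatenate([x, y])[None, :], two_group_design(10))
        assert t[0] == pytest.approx(t_ref, abs=1e-10)

    def test_orthogonal_covariate_leaves_t_unchanged(self):
        rng = np.random.default_rng(1)
        n = 20
        data = rng.normal(size=(5, n))
        base = two_group_design(10)
        cov = rng.normal(size=n)
        # orthogonalize against design and data
        proj = np.column_stack([base.X, data.T])
        cov -= proj @ np.linalg.lstsq(proj, cov, rcond=None)[0]
        with_cov = two_group_design(10, covs=[cov])
        t_base = glm_tstat(data, base)
        t_cov = glm_tstat(data, with_cov)
        # contrast estimate and residual sum of squares are untouched; only
        # the error df changes (n-2 -> n-3), rescaling t by sqrt(df ratio)
        np.testing.assert_allclose(t_cov, t_base * np.sqrt((n - 3) / (n - 2)),
                                   atol=1e-10)

    def test_rank_deficiency_names_columns(self):
        n = 10
        col = np.arange(n, dtype=float)
        with pytest.raises(DesignError, match="collinear"):
            DesignMatrix(X=np.column_stack([np.ones(n), col, 2 * col]),
                         contrast=[0, 1, 0], names=["intercept", "a", "a_twice"])

    def test_more_regressors_than_subjects_rejected(self):
        with pytest.raises(DesignError):
            glm_tstat(np.zeros((3, 4)),
                      DesignMatrix(X=np.eye(4), contrast=[1, 0, 0, 0]))


class TestTfce:
    def test_single_voxel_analytic_value(self):
        m = np.zeros((7, 7, 7))
        m[3, 3, 3] = 3.0
        out = tfce(m, E=0.5, H=2.0, dh=0.01)
        # dh -> 0 limit: integral of 1^0.5 * h^2 from 0 to 3 = 9.0
        assert out[3, 3, 3] == pytest.approx(9.0, rel=0.02)

    def test_all_zero_map(self):
        assert not tfce(np.zeros((5, 5, 5))).any()

    def test_plateau_extent_scaling(self):
        # doubling a plateau's extent scales TFCE by 2^E = sqrt(2)
        h, dh = 2.0, 0.02
        m1 = np.zeros((4, 12, 4))
        m1[1, 4:8, 1] = h
        m2 = np.zeros((4, 12, 4))
        m2[1, 2:10, 1] = h
        t1 = tfce(m1, E=0.5, H=2.0, dh=dh)[1, 5, 1]
        t2 = tfce(m2, E=0.5, H=2.0, dh=dh)[1, 5, 1]
        assert t2 / t1 == pytest.approx(np.sqrt(2), rel=1e-9)

    def test_signed_maps_enhance_each_sign_separately(self):
        m = np.zeros((5, 5, 5))
        m[1, 1, 1] = 2.0
        m[3, 3, 3] = -2.0
        out = tfce(m, dh=0.02)
        assert out[1, 1, 1] > 0 and out[3, 3, 3] < 0
        assert out[1, 1, 1] == pytest.approx(-out[3, 3, 3], rel=1e-9)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_union_find_matches_ndimage_reference(self, connectivity):
        rng = np.random.default_rng(3)
        mask = np.ones((10, 10, 10), bool)
        nbr, nnbr = neighbor_table(mask, connectivity)
        for _ in range(5):
            m = np.maximum(rng.normal(size=(10, 10, 10)), 0.0)
            fast = np.zeros(m.shape)
            fast[mask] = tfce_flat(m[mask], nbr, nnbr, 0.5, 2.0, None)
            ref = tfce_ndimage(m, 0.5, 2.0, None, connectivity)
            np.testing.assert_allclose(fast, ref, atol=1e-10)

    def test_monotone_in_input(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = np.maximum(rng.normal(size=(8, 8, 8)), 0.0)
            b = a + rng.uniform(0.0, 0.5, size=a.shape)
            ta = tfce(a, dh=0.05)
            tb = tfce(b, dh=0.05)
            assert np.all(tb >= ta - 1e-12)


class TestPermutationFwe:
    def make_null(self, seed, n_per_group=10, shape=(6, 6, 6)):
        rng = np.random.default_rng(seed)
        mask = np.ones(shape, bool)
        data = rng.normal(size=(mask.sum(), 2 * n_per_group))
        return data, two_group_design(n_per_group), mask

    def test_minimum_achievable_p(self):
        data, design, mask = self.make_null(0)
        res = permutation_fwe(data, design, mask, n_perm=100, seed=1)
        assert np.nanmin(res.fwe_p_map) >= 1.0 / 101.0
        assert np.nanmax(res.fwe_p_map) <= 1.0

    def test_n_perm_floor_enforced(self):
        data, design, mask = self.make_null(0)
        with pytest.raises(ValueError):
            permutation_fwe(data, design, mask, n_perm=50, seed=0)

    def test_strong_effect_detected_and_localized(self):
        rng = np.random.default_rng(5)
        shape = (8, 8, 8)
        mask = np.ones(shape, bool)
        blob = np.zeros(shape, bool)
        blob[2:6, 2:6, 2:6] = True
        n = 15
        data = rng.normal(size=(mask.sum(), 2 * n))
        data[blob[mask], n:] += 1.5
        design = two_group_design(n)
        res = permutation_fwe(data, design, mask, n_perm=200, seed=6)
        sig = res.significant(0.05)
        assert np.nansum(sig[blob]) > 0
        assert np.nansum(sig[~blob]) <= np.nansum(sig[blob])

    def test_exact_enumeration_warning_for_tiny_n(self, caplog):
        import logging
        rng = np.random.default_rng(7)
        mask = np.ones((3, 3, 3), bool)
        data = rng.normal(size=(27, 4))
        design = two_group_design(2)
        with caplog.at_level(logging.WARNING, logger="niikit.stats"):
            res = permutation_fwe(data, design, mask, n_perm=100, seed=0)
        assert res.n_perm == 24  # 4! distinct orderings
        assert any("exact enumeration" in r.message for r in caplog.records)

    def test_regression_sign_matches_generative_slope(self):
        """Positive planted metric-score slope yields positive t-values in
        affected voxels (mirrors the positive RF-MCS association)."""
        spec = CohortSpec(n_per_group=30, shape=(8, 8, 8), seed=8)
        recs = make_cohort(spec)
        table = cohort_table(recs)
        design = build_design(table, "MCS", ["sex", "age"])
        data = stack_metric_maps(recs, "nii_RF", spec.skeleton)
        t = glm_tstat(data, design)
        assert t.mean() > 0


class TestBuildDesign:
    def test_group_coding_and_contrast(self):
        table = pd.DataFrame({"group": ["control", "patient"] * 5,
                              "age": np.arange(10.0)})
        d = build_design(table, "group", ["age"])
        assert d.names == ["intercept", "group", "age"]
        np.testing.assert_array_equal(d.X[:, 1], [0, 1] * 5)
        np.testing.assert_array_equal(d.contrast, [0, 1, 0])

    def test_missing_values_rejected(self):
        table = pd.DataFrame({"group": ["a", "b"], "age": [1.0, np.nan]})
        with pytest.raises(DesignError, match="missing"):
            build_design(table, "group", ["age"])


class TestChiSquare:
    def test_study_sex_table(self):
        stat, p = chi_square_2x2([[54, 13], [52, 15]])
        assert p == pytest.approx(0.671, abs=5e-4)

    def test_proportional_table_is_null(self):
        stat, p = chi_square_2x2([[10, 10], [20, 20]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_perfect_association(self):
        stat, p = chi_square_2x2([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)
        assert p < 1e-9

    def test_zero_marginal_rejected(self):
        with pytest.raises(ZeroDivisionError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestWilcoxonRankSum:
    def test_identical_samples(self):
        assert wilcoxon_rank_sum([1.0, 1.0, 1.0], [1.0, 1.0])[1] == 1.0

    def test_exact_small_sample(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 orderings as extreme

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=12), rng.normal(0.5, size=15)
        p1 = wilcoxon_rank_sum(x, y)[1]
        p2 = wilcoxon_rank_sum(np.exp(x), np.exp(y))[1]
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])
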