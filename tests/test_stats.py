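"""Voxelwise GLM, one-sample maps, FDR and the demographic tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rehokit.stats import (
    DesignMatrix,
    SummaryStats,
    build_design_matrix,
    chi_square_2x2,
    demographics_table,
    fdr_correct,
    glm_group_ttest,
    mann_whitney_u,
    one_sample_ttest_map,
    pearson_corr,
    summary_two_sample_t,
)


def _design(group, covs=None, names=()):
    cols = [np.ones(len(group)), np.asarray(group, float)]
    col_names = ["intercept", "group"]
    for c, name in zip(covs or [], names):
        cols.append(np.asarray(c, float))
        col_names.append(name)
    return DesignMatrix(X=np.column_stack(cols), column_names=col_names)


def _maps_from_matrix(Y, shape=(2, 2, 2)):
    """n_subjects x n_voxels matrix -> list of 3D arrays + full mask."""
    mask = np.ones(shape, bool)
    maps = [row.reshape(shape) for row in Y]
    return maps, mask


class TestGlmGroupTtest:
    def test_identical_groups_give_zero_t(self, rng):
        vox = rng.random(8)
        Y = np.tile(vox, (6, 1))
        maps, mask = _maps_from_matrix(Y)
        tmap = glm_group_ttest(maps, _design([0, 0, 0, 1, 1, 1]), mask)
        assert np.allclose(tmap.t[mask], 0.0)
        assert tmap.df == 4

    def test_toy_pooled_t(self):
        # means 2 vs 4, pooled sd 1, se = sqrt(2/3) -> t = 2.449
        Y = np.array([[1.0], [2.0], [3.0], [3.0], [4.0], [5.0]])
        maps, mask = _maps_from_matrix(Y, shape=(1, 1, 1))
        tmap = glm_group_ttest(maps, _design([0, 0, 0, 1, 1, 1]), mask)
        oracle = sps.ttest_ind([3, 4, 5], [1, 2, 3]).statistic
        assert tmap.t[0, 0, 0] == pytest.approx(2.449, abs=5e-4)
        assert tmap.t[0, 0, 0] == pytest.approx(oracle, abs=1e-10)

    def test_orthogonal_covariate_equals_direct_two_sample_t(self, rng):
        group = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        cov = np.array([-1.0, 1, -1, 1, -1, 1, -1, 1])  # orthogonal to group
        Y = rng.standard_normal((8, 8))
        maps, mask = _maps_from_matrix(Y)
        tmap = glm_group_ttest(maps, _design(group, [cov], ["cov"]), mask)
        # orthogonality means the group coefficient is exactly the mean
        # difference of the direct two-sample comparison
        direct_diff = Y[group == 1].mean(axis=0) - Y[group == 0].mean(axis=0)
        X = np.column_stack([np.ones(8), group, cov])
        beta = np.linalg.lstsq(X, Y, rcond=None)[0]
        assert np.allclose(beta[1], direct_diff, atol=1e-10)
        # oracle: normal-equations refit of the full model, per voxel
        rss = ((Y - X @ beta) ** 2).sum(axis=0)
        se = np.sqrt(rss / 5 * np.linalg.inv(X.T @ X)[1, 1])
        assert np.allclose(tmap.t[mask], beta[1] / se, atol=1e-8)
        # and with no covariate the GLM t IS the pooled two-sample t
        tmap0 = glm_group_ttest(maps, _design(group), mask)
        pooled = sps.ttest_ind(Y[group == 1], Y[group == 0], axis=0).statistic
        assert np.allclose(tmap0.t[mask], pooled, atol=1e-8)

    def test_sign_convention_patient_above_control_is_positive(self):
        Y = np.array([[0.0], [0.0], [1.0], [1.0], [1.0], [0.9]])
        maps, mask = _maps_from_matrix(Y, shape=(1, 1, 1))
        tmap = glm_group_ttest(maps, _design([0, 0, 1, 1, 1, 1]), mask)
        assert tmap.t[0, 0, 0] > 0

    def test_rank_deficient_design_names_columns(self):
        group = [0, 0, 1, 1]
        dup = [0.0, 0.0, 1.0, 1.0]
        with pytest.raises(ValueError, match="collinear"):
            glm_group_ttest(
                _maps_from_matrix(np.zeros((4, 8)))[0],
                _design(group, [dup], ["dup_of_group"]),
                np.ones((2, 2, 2), bool),
            )

    def test_build_design_matrix_from_metadata(self):
        meta = pd.DataFrame(
            {
                "group": ["patient", "patient", "control", "control"],
                "age_y": [30.0, 40, 35, 45],
                "education_y": [10.0, 12, 14, 16],
            }
        )
        d = build_design_matrix(meta)
        assert d.column_names == ["intercept", "group", "age_y", "education_y"]
        assert np.array_equal(d.X[:, 1], [1, 1, 0, 0])
        assert d.X[:, 2].sum() == pytest.approx(0)  # centered


class TestOneSampleTtestMap:
    def test_hand_example(self):
        Y = np.array([[1.1], [1.2], [1.3], [1.4]])
        maps, mask = _maps_from_matrix(Y, shape=(1, 1, 1))
        tmap = one_sample_ttest_map(maps, null_value=1.0, mask=mask)
        assert tmap.t[0, 0, 0] == pytest.approx(3.873, abs=5e-4)
        assert tmap.df == 3

    def test_values_at_null_give_zero(self):
        Y = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]]) + np.array(
            [[-0.1, 0.1]] * 3
        ) * np.array([[1.0], [0.0], [-1.0]])
        maps, mask = _maps_from_matrix(Y, shape=(1, 1, 2))
        tmap = one_sample_ttest_map(maps, null_value=Y.mean(axis=0)[0], mask=mask)
        assert tmap.t[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_single_subject_is_an_error(self):
        maps, mask = _maps_from_matrix(np.ones((1, 8)))
        with pytest.raises(ValueError, match="at least 2"):
            one_sample_ttest_map(maps, mask=mask)

    def test_zero_variance_voxel_flagged_with_sentinel(self):
        maps, mask = _maps_from_matrix(np.full((3, 8), 2.0))
        tmap = one_sample_ttest_map(maps, null_value=1.0, mask=mask)
        assert np.isinf(tmap.t[mask]).all()
        assert tmap.degenerate[mask].all()


class TestFdrCorrect:
    @pytest.mark.parametrize(
        "p, q, expected_n",
        [
            ([0.01, 0.02, 0.03, 0.04], 0.05, 4),
            ([1.0, 1.0, 1.0], 0.05, 0),
            ([0.001, 0.2, 0.9], 0.05, 1),
        ],
    )
    def test_step_up_rule(self, p, q, expected_n):
        assert fdr_correct(np.array(p), q).sum() == expected_n

    def test_empty_input(self):
        assert fdr_correct(np.array([])).size == 0

    def test_matches_hand_step_up_on_random_input(self, rng):
        p = rng.uniform(0, 1, 50)
        q = 0.1
        # oracle: reject p_(i) for all i <= max{i : p_(i) <= i q / m}
        order = np.argsort(p)
        thresh = (np.arange(1, 51)) * q / 50
        below = np.nonzero(p[order] <= thresh)[0]
        expected = np.zeros(50, bool)
        if below.size:
            expected[order[: below.max() + 1]] = True
        assert np.array_equal(fdr_correct(p, q), expected)


class TestSummaryTwoSampleT:
    @pytest.mark.parametrize(
        "a, b, expected_t",
        [
            ((37.1, 8.6, 20), (38.3, 6.5, 20), -0.499),
            ((29.2, 0.8, 20), (29.5, 0.8, 20), -1.189),
            ((12.0, 2.9, 20), (12.9, 3.2, 20), -0.938),
            ((13.5, 9.2, 2), (16.7, 12.6, 3), -0.325),
        ],
    )
    def test_cohort_table_values(self, a, b, expected_t):
        res = summary_two_sample_t(SummaryStats(*a), SummaryStats(*b))
        assert res.t == pytest.approx(expected_t, abs=0.02)

    def test_equal_means_give_zero(self):
        res = summary_two_sample_t(SummaryStats(5, 1, 10), SummaryStats(5, 2, 12))
        assert res.t == 0.0

    def test_equal_n_matches_pooled_variance_t_exactly(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.5, 2, 15)
        a = SummaryStats(x.mean(), x.std(ddof=1), 15)
        b = SummaryStats(y.mean(), y.std(ddof=1), 15)
        res = summary_two_sample_t(a, b)
        oracle = sps.ttest_ind(x, y, equal_var=True)
        assert res.t == pytest.approx(oracle.statistic, abs=1e-12)
        assert res.df_pooled == 28

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            SummaryStats(1.0, 1.0, 1)


class TestCategoricalAndCorrelation:
    def test_balanced_sex_table_gives_zero_chi_square(self):
        stat, dof = chi_square_2x2(np.array([[15, 5], [15, 5]]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert dof == 1

    def test_chi_square_hand_example(self):
        stat, _ = chi_square_2x2(np.array([[10, 10], [15, 5]]))
        assert stat == pytest.approx(8 / 3, abs=1e-9)

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(np.array([[0, 0], [15, 5]]))

    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson_corr(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_pearson_hand_example(self):
        r, _ = pearson_corr(np.array([1.0, 2, 3]), np.array([1.0, 3, 2]))
        assert r == pytest.approx(0.5, abs=1e-12)

    def test_zero_covariance_by_construction(self):
        x = np.array([-1.0, 0, 1, 0])
        y = np.array([0.0, 1, 0, -1])
        assert pearson_corr(x, y)[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr(np.ones(5), np.arange(5.0))

    def test_mann_whitney_matches_scipy(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(1, 1, 10)
        stat, p = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided")
        assert stat == ref.statistic and p == ref.pvalue


def test_demographics_table_on_generated_cohort():
    from rehokit.synthetic import SimConfig, generate_cohort

    cohort = generate_cohort(SimConfig(grid_shape=(8, 8, 8), n_volumes=20, n_per_group=20,
                                       roi_specs=[], seed=3))
    table = demographics_table(cohort.metadata)
    sex_row = table[table["variable"] == "sex (M/F)"].iloc[0]
    assert sex_row["statistic"] == pytest.approx(0.0, abs=1e-12)
    assert set(table["variable"]) >= {"age_y", "education_y", "mmse", "sex (M/F)"}
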