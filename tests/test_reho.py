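"""Kendall's W, the ReHo map, normalization and smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rehokit.io import Scan4D
from rehokit.reho import (
    NeighborhoodSpec,
    fwhm_to_sigma,
    gaussian_smooth,
    kendall_w,
    normalize_reho,
    rank_time_series,
    reho_map,
    stencil_offsets,
)

from oracles import mean_pairwise_spearman, naive_reho


class TestRankTimeSeries:
    def test_simple_ordering(self):
        assert np.array_equal(rank_time_series(np.array([3.2, 1.1, 2.0])), [3, 1, 2])

    def test_ties_get_average_ranks(self):
        assert np.array_equal(rank_time_series(np.array([5.0, 5.0, 1.0])), [2.5, 2.5, 1])

    def test_distinct_values_give_a_permutation(self, rng):
        x = rng.permutation(150) + rng.uniform(0, 0.4, 150)
        ranks = rank_time_series(x)
        assert np.array_equal(np.sort(ranks), np.arange(1, 151))
        # sort-based oracle: the rank of x[i] is its position in sorted order
        assert np.array_equal(ranks, np.searchsorted(np.sort(x), x) + 1)


class TestKendallW:
    def test_identical_series_have_full_concordance(self):
        col = np.arange(1, 8)
        assert kendall_w(np.tile(col[:, None], (1, 5))) == 1.0

    def test_reversed_pair_has_zero_concordance(self):
        assert kendall_w(np.array([[1, 3], [2, 2], [3, 1]])) == 0.0

    def test_hand_worked_example(self):
        # columns (1,2,3,4), (1,2,4,3), (2,1,3,4): R=(4,5,10,11), S=37
        ranks = np.array([[1, 1, 2], [2, 2, 1], [3, 4, 3], [4, 3, 4]])
        assert kendall_w(ranks) == pytest.approx(12 * 37 / (9 * 60), abs=1e-12)
        assert kendall_w(ranks) == pytest.approx(0.8222, abs=5e-5)

    def test_single_series_rejected(self):
        with pytest.raises(ValueError, match="k=1"):
            kendall_w(np.arange(1, 5)[:, None])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((8, 4))
        ranks = np.stack([rank_time_series(c) for c in data.T], axis=1)
        transformed = np.stack(
            [rank_time_series(np.exp(0.5 * c) + c**3 + 3 * c) for c in data.T], axis=1
        )
        assert kendall_w(transformed) == pytest.approx(kendall_w(ranks), abs=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 9), st.integers(5, 12))
    def test_matches_mean_pairwise_spearman_identity(self, seed, k, n):
        # W = ((k-1)*rho_bar + 1)/k in the tie-free case
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((n, k))
        ranks = np.stack([rank_time_series(c) for c in data.T], axis=1)
        rho_bar = mean_pairwise_spearman(data)
        assert kendall_w(ranks) == pytest.approx(((k - 1) * rho_bar + 1) / k, abs=1e-10)


class TestRehoMap:
    def test_shared_time_course_gives_unit_w(self, rng):
        tc = rng.standard_normal(30)
        data = np.broadcast_to(tc, (6, 6, 6, 30)).copy()
        scan = Scan4D(data, np.eye(4), 3.0)
        mask = np.ones((6, 6, 6), bool)
        m = reho_map(scan, mask)
        assert np.allclose(m.values[mask], 1.0)

    def test_interior_neighborhood_has_27_series(self, small_scan):
        mask = np.ones((6, 6, 6), bool)
        m = reho_map(small_scan, mask)
        assert m.k_map[3, 3, 3] == 27

    @pytest.mark.parametrize("stencil", [6, 18, 26])
    def test_matches_triple_loop_oracle(self, rng, stencil):
        data = rng.standard_normal((5, 5, 5, 30))
        mask = rng.random((5, 5, 5)) > 0.25
        scan = Scan4D(data, np.eye(4), 3.0)
        got = reho_map(scan, mask, NeighborhoodSpec(stencil=stencil))
        expected = naive_reho(data, mask, stencil_offsets(stencil))
        expected[~got.mask] = 0.0
        assert np.abs(got.values - expected).max() < 1e-10

    def test_exclude_policy_keeps_only_full_neighborhoods(self, small_scan):
        mask = np.ones((6, 6, 6), bool)
        m = reho_map(small_scan, mask, NeighborhoodSpec(edge_policy="exclude"))
        assert m.mask.sum() == 4**3
        assert (m.k_map[m.mask] == 27).all()
        assert (m.values[~m.mask] == 0).all()

    def test_grid_mismatch_is_an_error(self, small_scan):
        with pytest.raises(ValueError, match="grid"):
            reho_map(small_scan, np.ones((5, 5, 5), bool))


class TestNormalizeReho:
    def test_constant_map_becomes_ones(self):
        from rehokit.reho import ReHoMap

        mask = np.ones((4, 4, 4), bool)
        m = ReHoMap(values=np.full((4, 4, 4), 0.4), mask=mask, affine=np.eye(4))
        out = normalize_reho(m)
        assert np.allclose(out.values[mask], 1.0)
        assert out.normalized

    def test_two_voxel_hand_arithmetic(self):
        from rehokit.reho import ReHoMap

        mask = np.zeros((1, 1, 2), bool)
        mask[0, 0, :] = True
        values = np.zeros((1, 1, 2))
        values[0, 0] = [0.2, 0.6]
        out = normalize_reho(ReHoMap(values=values, mask=mask, affine=np.eye(4)))
        assert np.allclose(out.values[0, 0], [0.5, 1.5])

    def test_mask_mean_is_one(self, rng):
        from rehokit.reho import ReHoMap

        mask = rng.random((6, 6, 6)) > 0.3
        values = np.where(mask, rng.uniform(0.1, 0.9, (6, 6, 6)), 0.0)
        out = normalize_reho(ReHoMap(values=values, mask=mask, affine=np.eye(4)))
        assert out.values[mask].mean() == pytest.approx(1.0, abs=1e-6)

    def test_zero_mean_map_is_an_error(self):
        from rehokit.reho import ReHoMap

        mask = np.ones((2, 2, 2), bool)
        with pytest.raises(ValueError, match="normalize"):
            normalize_reho(ReHoMap(values=np.zeros((2, 2, 2)), mask=mask, affine=np.eye(4)))


class TestGaussianSmooth:
    def test_fwhm_8mm_sigma(self):
        assert fwhm_to_sigma(8.0) == pytest.approx(3.3973, abs=1e-4)

    def test_fwhm_zero_is_identity(self, rng):
        from rehokit.reho import ReHoMap

        mask = np.ones((5, 5, 5), bool)
        m = ReHoMap(values=rng.random((5, 5, 5)), mask=mask, affine=np.diag([3.0, 3, 3, 1]))
        out = gaussian_smooth(m, 0.0)
        assert np.array_equal(out.values, m.values)
        assert out.smoothed_fwhm_mm == 0.0

    def test_impulse_kernel_mass_and_profile(self):
        from rehokit.reho import ReHoMap

        shape = (41, 41, 41)
        mask = np.ones(shape, bool)
        values = np.zeros(shape)
        values[20, 20, 20] = 1.0
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        out = gaussian_smooth(ReHoMap(values=values, mask=mask, affine=affine), fwhm_mm=8.0)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-6)
        # analytic profile at +-1 and +-2 sigma along an axis (sigma in voxels)
        sigma_vox = fwhm_to_sigma(8.0) / 2.0
        peak = out.values[20, 20, 20]
        for n_sigma in (1, 2):
            d = int(round(n_sigma * sigma_vox))
            analytic = np.exp(-(d**2) / (2 * sigma_vox**2))
            assert out.values[20 + d, 20, 20] / peak == pytest.approx(analytic, rel=0.02)

    def test_negative_fwhm_rejected(self):
        from rehokit.reho import ReHoMap

        m = ReHoMap(values=np.zeros((3, 3, 3)), mask=np.ones((3, 3, 3), bool), affine=np.eye(4))
        with pytest.raises(ValueError, match="fwhm"):
            gaussian_smooth(m, -1.0)


def test_reho_increases_with_implanted_amplitude():
    """Seeded ROI coherence: in-ROI ReHo is monotone in amplitude (paired)."""
    from rehokit.pipeline import subject_mreho
    from rehokit.synthetic import RoiSpec, SimConfig, generate_subject_scan

    amplitudes = (0.0, 0.8, 2.0)
    diffs = {a: [] for a in amplitudes}
    for seed in (11, 12, 13):
        for amp in amplitudes:
            cfg = SimConfig(
                grid_shape=(16, 16, 16),
                n_volumes=60,
                roi_specs=[RoiSpec(center_voxel=(8, 8, 8), radius_mm=6.0, label="r")],
                group_effect={"patient": amp},
                seed=seed,
            )
            scan = generate_subject_scan(cfg, "patient", seed)
            mask = cfg.brain_mask()
            m = subject_mreho(scan, mask, smooth_fwhm_mm=0.0)
            roi = cfg.roi_specs[0].voxel_mask(cfg.grid_shape, cfg.voxel_size_mm)
            diffs[amp].append(m.values[roi & mask].mean() - m.values[mask & ~roi].mean())
    for lo, hi in zip(amplitudes[:-1], amplitudes[1:]):
        assert all(h > l for l, h in zip(diffs[lo], diffs[hi]))
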