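"""Mass-univariate t, TFCE, permutation FWE, FDR, clusters, power, medians."""

import numpy as np
import pandas as pd
import pytest

from netclass.filtering import (
    GroupDesign,
    TFCEParams,
    bonferroni,
    detectable_effect_filter,
    extract_cluster_features,
    fdr_bh,
    mass_univariate_t,
    permutation_fwe,
    permutation_median_test,
    roi_matrix_tfce,
    tfce_enhance,
)

from _oracles import (
    min_detectable_d_oracle,
    pooled_t_oracle,
    stepup_fdr_oracle,
    tfce_fine_oracle,
)


def design_ab(na, nb):
    return GroupDesign(np.array(["a"] * na + ["b"] * nb), "a", "b")


class TestMassUnivariateT:
    def test_hand_computed_pooled_t(self):
        values = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        t = mass_univariate_t(values, design_ab(3, 3))
        assert t[0] == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-12)
        assert t[0] == pytest.approx(pooled_t_oracle([1, 2, 3], [4, 5, 6]), abs=1e-12)

    def test_identical_constant_groups_give_zero_with_warning(self):
        values = np.ones((6, 3))
        with pytest.warns(UserWarning, match="zero-variance"):
            t = mass_univariate_t(values, design_ab(3, 3))
        assert np.all(t == 0)

    def test_label_swap_negates_t(self, rng):
        values = rng.standard_normal((10, 4))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        t_ab = mass_univariate_t(values, GroupDesign(labels, "a", "b"))
        t_ba = mass_univariate_t(values, GroupDesign(labels, "b", "a"))
        assert np.allclose(t_ab, -t_ba)

    def test_single_subject_group_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 2"):
            mass_univariate_t(rng.standard_normal((3, 2)), design_ab(1, 2))


class TestTFCE:
    def test_zero_map_enhances_to_zero(self):
        assert np.all(tfce_enhance(np.zeros((5, 5, 5))) == 0)

    def test_isolated_voxel_closed_form(self):
        """Single suprathreshold voxel: integral of 1^E * x^2 dx = h^3 / 3."""
        stat = np.zeros((7, 7, 7))
        h = 2.5
        stat[3, 3, 3] = h
        params = TFCEParams(n_steps=10_000)
        enh = tfce_enhance(stat, params)
        assert enh[3, 3, 3] == pytest.approx(h**3 / 3.0, rel=1e-3)

    def test_uniform_component_closed_form(self):
        """n connected voxels at height h: each gets sqrt(n) * h^3 / 3."""
        stat = np.zeros((6, 6, 6))
        h = 1.7
        stat[2, 2:5, 2] = h  # 3-voxel line, 26-connected
        enh = tfce_enhance(stat, TFCEParams(n_steps=10_000))
        assert enh[2, 3, 2] == pytest.approx(np.sqrt(3) * h**3 / 3.0, rel=1e-3)

    def test_backends_agree_exactly(self, rng):
        for shape, conn in [((8, 8, 8), 26), ((8, 8, 8), 6), ((12, 12), 4)]:
            stat = rng.standard_normal(shape)
            params = TFCEParams(connectivity=conn)
            fast = tfce_enhance(stat, params, backend="fast")
            ref = tfce_enhance(stat, params, backend="ndimage")
            assert np.allclose(fast, ref, atol=1e-10)

    def test_matches_independent_fine_integration(self, rng):
        stat = rng.standard_normal((6, 6, 6))
        enh = tfce_enhance(stat, TFCEParams(n_steps=500))
        oracle = tfce_fine_oracle(stat, 0.5, 2.0, 500)
        assert np.allclose(enh, oracle, atol=1e-9)

    def test_scaling_monotonicity(self, rng):
        stat = np.abs(rng.standard_normal((6, 6, 6)))
        base = tfce_enhance(stat)
        scaled = tfce_enhance(2.0 * stat)
        assert np.all(scaled >= base - 1e-12)

    def test_negative_lobe_sign_restored(self, rng):
        stat = rng.standard_normal((6, 6, 6))
        enh = tfce_enhance(stat)
        assert np.all(np.sign(enh[stat < 0]) <= 0)
        assert np.all(np.sign(enh[stat > 0]) >= 0)


class TestPermutationFWE:
    def test_constant_data_yields_no_rejections(self):
        values = np.ones((12, 4, 4, 4))
        params = TFCEParams(n_permutations=50)
        res = permutation_fwe(values, design_ab(6, 6), params, seed=0)
        assert not res.mask.any()
        assert np.all(res.pvalues == 1.0)

    def test_planted_cluster_recovered(self, rng):
        values = rng.standard_normal((30, 10, 10, 10))
        cluster = (slice(15, 30), slice(3, 7), slice(3, 7), slice(3, 7))
        values[cluster] += 3.0
        labels = np.array(["a"] * 15 + ["b"] * 15)
        res = permutation_fwe(
            values, GroupDesign(labels, "b", "a"), TFCEParams(n_permutations=100), seed=1
        )
        planted = np.zeros((10, 10, 10), dtype=bool)
        planted[3:7, 3:7, 3:7] = True
        recovered = (res.mask & planted).sum() / planted.sum()
        assert recovered >= 0.9
        assert res.mask[~planted].sum() <= 5

    def test_small_groups_enumerate_all_assignments(self, rng):
        values = rng.standard_normal((6, 3, 3, 3))
        with pytest.warns(UserWarning, match="enumerating"):
            res = permutation_fwe(values, design_ab(3, 3), TFCEParams(n_permutations=500), seed=0)
        assert res.n_permutations == 20

    def test_seed_reproducibility(self, rng):
        values = rng.standard_normal((20, 6, 6, 6))
        d = design_ab(10, 10)
        a = permutation_fwe(values, d, TFCEParams(n_permutations=60), seed=3)
        b = permutation_fwe(values, d, TFCEParams(n_permutations=60), seed=3)
        assert np.array_equal(a.pvalues, b.pvalues)


class TestRoiMatrixTFCE:
    def test_two_roi_matrix_reduces_to_single_pair_test(self, rng):
        mats = rng.standard_normal((24, 2, 2))
        mats = (mats + np.swapaxes(mats, 1, 2)) / 2
        for m in mats:
            np.fill_diagonal(m, 0)
        mats[:12, 0, 1] += 2.5
        mats[:12, 1, 0] += 2.5
        res = roi_matrix_tfce(mats, design_ab(12, 12), TFCEParams(n_permutations=200), seed=0)
        assert res.mask[0, 1] and res.mask[1, 0]
        assert not res.mask.diagonal().any()

    def test_altered_block_dominates_mask(self, rng):
        r = 8
        mats = rng.standard_normal((40, r, r))
        mats = (mats + np.swapaxes(mats, 1, 2)) / 2
        block = np.ix_(range(20, 40), range(0, 3), range(0, 3))
        mats[block] += 2.0
        for m in mats:
            np.fill_diagonal(m, 0)
        res = roi_matrix_tfce(mats, design_ab(20, 20), TFCEParams(n_permutations=150), seed=2)
        inside = res.mask[:3, :3][~np.eye(3, dtype=bool)]
        outside = res.mask[3:, 3:]
        assert inside.mean() > 0.8
        assert outside.mean() < 0.1


class TestFdrBH:
    def test_hand_examples(self):
        assert fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), 0.05).all()
        assert not fdr_bh(np.ones(5), 0.05).any()
        assert fdr_bh(np.array([0.04]), 0.05)[0]

    def test_matches_stepup_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            m = rng.integers(1, 40)
            p = rng.random(m) ** rng.uniform(0.3, 3)
            q = rng.uniform(0.01, 0.2)
            assert np.array_equal(fdr_bh(p, q), stepup_fdr_oracle(p, q))

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            fdr_bh(np.array([0.5, 1.2]), 0.05)


class TestClusterFeatures:
    def grid_mask(self, blocks, dims=(12, 12, 12)):
        mask = np.zeros(dims, dtype=bool)
        for b in blocks:
            mask[b] = True
        return mask

    def test_single_component_averages_member_voxels(self, rng):
        mask = self.grid_mask([(slice(0, 4), slice(0, 4), slice(0, 4))])  # 64 voxels
        maps = rng.standard_normal((5, 12, 12, 12))
        feats = extract_cluster_features(maps, mask, min_size=50)
        assert feats.shape == (5, 1)
        expected = maps[:, mask].mean(axis=1)
        assert np.allclose(feats.iloc[:, 0], expected)

    def test_min_size_is_strict_threshold(self, rng):
        # one 49-voxel and one 64-voxel component; only the second survives
        mask = self.grid_mask(
            [(slice(0, 4), slice(0, 4), slice(0, 4)), (slice(8, 12), slice(8, 12), slice(9, 12))]
        )
        assert mask.sum() == 64 + 48
        mask[8, 8, 8] = True  # 49th voxel, 26-connected to the second block
        maps = rng.standard_normal((4, 12, 12, 12))
        feats = extract_cluster_features(maps, mask, min_size=50)
        assert feats.shape[1] == 1

    def test_two_components_stable_naming_order(self, rng):
        mask = self.grid_mask(
            [(slice(0, 4), slice(0, 4), slice(0, 4)), (slice(7, 12), slice(7, 12), slice(7, 12))]
        )
        maps = rng.standard_normal((3, 12, 12, 12))
        f1 = extract_cluster_features(maps, mask, min_size=10)
        f2 = extract_cluster_features(maps, mask, min_size=10)
        assert list(f1.columns) == list(f2.columns)
        assert f1.shape[1] == 2

    def test_empty_mask_warns(self, rng):
        with pytest.warns(UserWarning, match="empty"):
            feats = extract_cluster_features(
                rng.standard_normal((3, 4, 4, 4)), np.zeros((4, 4, 4), bool)
            )
        assert feats.empty


class TestDetectableEffect:
    def test_matches_noncentral_t_power_sweep(self):
        for n1, n2 in [(20, 20), (50, 30)]:
            d_star = detectable_effect_filter(n1, n2, 0.80, 0.05)
            assert d_star == pytest.approx(min_detectable_d_oracle(n1, n2, 0.80, 0.05), abs=1e-3)

    def test_monotone_decreasing_in_n(self):
        ds = [detectable_effect_filter(n, n, 0.80, 0.05) for n in (10, 20, 40, 80)]
        assert all(a > b for a, b in zip(ds, ds[1:]))

    def test_degenerate_power_rejected(self):
        with pytest.raises(ValueError, match="power"):
            detectable_effect_filter(10, 10, 0.0, 0.05)


class TestMedianPermutation:
    def test_identical_samples_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        p, _ = permutation_median_test(x, x.copy(), n_permutations=200, seed=0)
        assert p == 1.0

    def test_matches_exact_enumeration(self):
        import itertools

        x = np.array([1, 2, 3, 4, 5], float)
        y = np.array([10, 11, 12, 13, 14], float)
        p, stats_ = permutation_median_test(x, y, n_permutations=5000, seed=0)
        pooled = np.concatenate([x, y])
        observed = abs(np.median(x) - np.median(y))
        hits = 0
        for combo in itertools.combinations(range(10), 5):
            sel = np.zeros(10, bool)
            sel[list(combo)] = True
            if abs(np.median(pooled[sel]) - np.median(pooled[~sel])) >= observed:
                hits += 1
        assert p == pytest.approx(hits / 252)
        assert stats_["median_x"] == 3 and stats_["mad_y"] == 1

    def test_bonferroni_definition(self):
        adjusted = bonferroni(np.array([0.01, 0.4, 0.9]))
        assert np.allclose(adjusted, [0.03, 1.0, 1.0])
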