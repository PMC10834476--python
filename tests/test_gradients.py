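import numpy as np
import pytest
from scipy import stats

import epidyn as ed
from epidyn.gradients import (
    compute_fc_gradient,
    compute_gradients,
    group_difference_map,
    networkwise_compare,
    procrustes_align,
    rank_contributing_features,
)


class TestComputeGradients:
    def test_rank_one_matrix_explains_all_variance(self):
        rng = np.random.default_rng(0)
        pattern = rng.standard_normal(20)
        vals = np.outer(rng.uniform(0.5, 2.0, 30), pattern)
        gs = compute_gradients(vals, k=1)
        assert gs.explained_variance[0] == pytest.approx(1.0)

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(1)
        gs = compute_gradients(rng.standard_normal((40, 20)), k=5)
        assert np.all(np.diff(gs.explained_variance) <= 1e-12)
        assert gs.explained_variance.sum() <= 1.0 + 1e-9

    def test_recovers_planted_orthogonal_patterns(self):
        """Two orthogonal spatial patterns with 4:1 variance across 40 features."""
        rng = np.random.default_rng(2)
        n_regions = 30
        q, _ = np.linalg.qr(rng.standard_normal((n_regions, 2)))
        p1, p2 = q[:, 0], q[:, 1]
        load1 = rng.standard_normal(40) * 2.0
        load2 = rng.standard_normal(40) * 1.0
        vals = np.outer(load1, p1) + np.outer(load2, p2)
        vals += 0.01 * rng.standard_normal(vals.shape)
        gs = compute_gradients(vals, k=2)
        assert abs(np.corrcoef(gs.components[:, 0], p1)[0, 1]) > 0.95
        assert abs(np.corrcoef(gs.components[:, 1], p2)[0, 1]) > 0.95

    def test_sign_convention_follows_reference_axis(self):
        rng = np.random.default_rng(3)
        axis = np.arange(20.0)
        vals = rng.standard_normal((15, 20))
        gs = compute_gradients(vals, k=3, reference_axis=axis)
        for j in range(3):
            c = gs.components[:, j] - gs.components[:, j].mean()
            assert c @ (axis - axis.mean()) >= 0

    def test_k_too_large_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="k"):
            compute_gradients(rng.standard_normal((10, 8)), k=8)


class TestProcrustes:
    def _gset(self, comps):
        k = comps.shape[1]
        return ed.GradientSet(comps, np.linspace(0.5, 0.1, k),
                              np.zeros((5, k)))

    def test_identical_sets_have_zero_disparity(self):
        rng = np.random.default_rng(5)
        gs = self._gset(rng.standard_normal((30, 3)))
        aligned, disparity = procrustes_align(gs, gs)
        assert disparity == pytest.approx(0.0, abs=1e-20)

    def test_rotated_copy_recovered_exactly(self):
        rng = np.random.default_rng(6)
        ref = self._gset(rng.standard_normal((30, 3)))
        R, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rotated = self._gset(ref.components @ R)
        aligned, disparity = procrustes_align(rotated, ref)
        assert disparity < 1e-10

    def test_disparity_tracks_injected_noise_energy(self):
        rng = np.random.default_rng(7)
        ref = self._gset(rng.standard_normal((60, 3)))
        noise = 0.05 * rng.standard_normal((60, 3))
        noisy = self._gset(ref.components + noise)
        _, disparity = procrustes_align(noisy, ref)
        noise_energy = ((noise - noise.mean(axis=0)) ** 2).sum()
        assert disparity == pytest.approx(noise_energy, rel=0.2)

    def test_alignment_preserves_column_norms(self):
        rng = np.random.default_rng(8)
        ind = self._gset(rng.standard_normal((30, 3)))
        ref = self._gset(rng.standard_normal((30, 3)))
        aligned, _ = procrustes_align(ind, ref)
        centered = ind.components - ind.components.mean(axis=0)
        assert np.linalg.norm(aligned.components) == pytest.approx(
            np.linalg.norm(centered))
        np.testing.assert_array_equal(aligned.explained_variance,
                                      ind.explained_variance)

    def test_k_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError, match="share"):
            procrustes_align(self._gset(rng.standard_normal((30, 2))),
                             self._gset(rng.standard_normal((30, 3))))


class TestGroupDifferenceMap:
    def _hemis(self, n):
        return np.array(["left"] * (n // 2) + ["right"] * (n - n // 2))

    def test_planted_effect_detected_with_power(self):
        """+2 sd offset in 5 regions, 30 vs 30 subjects."""
        rng = np.random.default_rng(10)
        n_sub, n_reg = 60, 16
        maps = rng.standard_normal((n_sub, n_reg))
        groups = np.array(["HC"] * 30 + ["PAT"] * 30)
        target = [0, 1, 2, 8, 9]
        maps[np.ix_(np.arange(30, 60), target)] += 2.0
        cov = rng.standard_normal((n_sub, 2))
        res = group_difference_map(maps, groups, cov, self._hemis(n_reg),
                                   n_perm=1000, seed=0)
        assert res["significant"][target].sum() >= 4

    def test_covariate_explaining_the_gap_suppresses_detections(self):
        """A group gap fully carried by age rejects everywhere unadjusted but
        drops to the calibration rate once age is regressed out."""
        rng = np.random.default_rng(11)
        n_sub, n_reg = 40, 12
        age = np.concatenate([rng.normal(20, 2, 20), rng.normal(40, 2, 20)])
        maps = rng.standard_normal((n_sub, n_reg)) + 0.2 * age[:, None]
        groups = np.array(["HC"] * 20 + ["PAT"] * 20)
        unadjusted = group_difference_map(maps, groups, None, self._hemis(n_reg),
                                          n_perm=500, seed=1)
        adjusted = group_difference_map(maps, groups, age[:, None],
                                        self._hemis(n_reg), n_perm=500, seed=1)
        assert unadjusted["significant"].sum() >= n_reg // 2
        assert adjusted["significant"].sum() <= 2

    def test_zero_variance_region_flagged_not_significant(self):
        rng = np.random.default_rng(12)
        maps = rng.standard_normal((20, 6))
        maps[:, 3] = 1.0
        groups = np.array(["A"] * 10 + ["B"] * 10)
        res = group_difference_map(maps, groups, None, self._hemis(6),
                                   n_perm=200, seed=2)
        assert res["zero_variance"][3]
        assert res["t"][3] == 0.0
        assert not res["significant"][3]

    def test_small_permutation_count_warns(self):
        rng = np.random.default_rng(13)
        maps = rng.standard_normal((10, 4))
        groups = np.array(["A"] * 5 + ["B"] * 5)
        with pytest.warns(UserWarning, match="n_perm"):
            group_difference_map(maps, groups, None, self._hemis(4),
                                 n_perm=50, seed=3)


class TestNetworkwise:
    def test_uniform_map_gives_equal_network_means(self, parc12):
        maps = np.ones((8, 12))
        groups = np.array(["A"] * 4 + ["B"] * 4)
        table = networkwise_compare(maps, parc12, groups)
        np.testing.assert_allclose(table["mean_difference"], 0.0)

    def test_bonferroni_threshold_arithmetic(self):
        assert 0.05 / 7 == pytest.approx(0.0071428, abs=1e-6)

    def test_only_the_affected_network_is_flagged_at_high_power(self):
        parc = ed.generate_parcellation(28, seed=4)
        rng = np.random.default_rng(14)
        n_sub = 40
        maps = 0.1 * rng.standard_normal((n_sub, 28))
        groups = np.array(["HC"] * 20 + ["PAT"] * 20)
        idx = parc.network_regions("somatomotor")
        maps[np.ix_(np.arange(20, n_sub), idx)] += 3.0
        table = networkwise_compare(maps, parc, groups)
        flagged = set(table.loc[table["significant"], "network"])
        assert flagged == {"somatomotor"}


class TestFeatureAttribution:
    def test_map_itself_ranks_first_with_unit_correlation(self):
        rng = np.random.default_rng(15)
        t_map = rng.standard_normal(20)
        rows = np.vstack([t_map, rng.standard_normal((3, 20))])
        table = rank_contributing_features(rows, ["self", "a", "b", "c"], t_map)
        assert table.iloc[0]["feature"] == "self"
        assert table.iloc[0]["r"] == pytest.approx(1.0)

    def test_negated_feature_has_same_rank_magnitude(self):
        rng = np.random.default_rng(16)
        t_map = rng.standard_normal(20)
        rows = np.vstack([t_map, -t_map])
        table = rank_contributing_features(rows, ["pos", "neg"], t_map)
        assert set(table["feature"][:2]) == {"pos", "neg"}
        assert table.set_index("feature").loc["neg", "r"] == pytest.approx(-1.0)

    def test_ranking_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(17)
        t_map = rng.standard_normal(25)
        rows = rng.standard_normal((30, 25))
        names = [f"f{i:02d}" for i in range(30)]
        table = rank_contributing_features(rows, names, t_map)
        oracle = sorted(
            ((abs(np.corrcoef(r, t_map)[0, 1]), n) for r, n in zip(rows, names)),
            key=lambda x: (-x[0], x[1]),
        )
        assert list(table["feature"]) == [n for _, n in oracle]

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            rank_contributing_features(np.ones((2, 5)), ["a", "b"], np.ones(5))


class TestFCGradient:
    def _block_fc(self, n=20, within=0.8):
        fc = np.full((n, n), 0.0)
        half = n // 2
        fc[:half, :half] = within
        fc[half:, half:] = within
        np.fill_diagonal(fc, 1.0)
        return fc

    def test_block_structure_yields_bimodal_gradient(self):
        fc = self._block_fc()
        g = compute_fc_gradient(fc)
        half = len(g) // 2
        assert g[:half].std() < 0.05
        assert g[half:].std() < 0.05
        assert abs(g[:half].mean() - g[half:].mean()) > 1.0

    def test_permutation_equivariance(self):
        # Toeplitz-like FC with a clear spectral gap, so the first component
        # is unique and must commute with region reordering
        idx = np.arange(15)
        fc = np.exp(-np.abs(idx[:, None] - idx[None, :]) / 5.0)
        rng = np.random.default_rng(18)
        g = compute_fc_gradient(fc)
        perm = rng.permutation(15)
        g_perm = compute_fc_gradient(fc[np.ix_(perm, perm)])
        # same sign convention cannot be guaranteed after permutation of the
        # default index axis, so compare up to sign
        agree = np.corrcoef(g_perm, g[perm])[0, 1]
        assert abs(agree) == pytest.approx(1.0, abs=1e-8)

    def test_output_is_zscored(self):
        rng = np.random.default_rng(19)
        fc = np.corrcoef(rng.standard_normal((12, 300)))
        g = compute_fc_gradient(fc)
        assert g.mean() == pytest.approx(0.0, abs=1e-10)
        assert g.std() == pytest.approx(1.0)

    def test_non_unit_diagonal_rejected(self):
        fc = np.eye(5) * 0.9
        with pytest.raises(ValueError, match="diagonal"):
            compute_fc_gradient(fc)
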