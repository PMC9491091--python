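import numpy as np
import pytest
from scipy import ndimage

from neuropet import TFCEConfig, permutation_fwe, tfce_transform, tstat_map

from conftest import make_noise_maps


def brute_force_tfce(stat, mask, E, H, dh, connectivity=26):
    """Independent threshold-sum TFCE: explicit per-voxel loop over heights."""
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    s = np.where(mask, np.clip(stat, 0, None), 0.0)
    m = s.max()
    out = np.zeros_like(s)
    k = 1
    while k * dh <= m + 1e-9:
        h = k * dh
        above = s >= h - 1e-9 * m
        lab, _ = ndimage.label(above, structure=structure)
        for v in np.argwhere(above):
            comp = lab == lab[tuple(v)]
            out[tuple(v)] += comp.sum() ** E * h ** H * dh
        k += 1
    return out


class TestTStatMap:
    def test_identical_groups_give_zero_t(self):
        const = np.full((4, 4, 4), 1.3)
        mask = np.ones((4, 4, 4), bool)
        t = tstat_map([const] * 3, [const] * 3, mask)
        assert np.allclose(t[mask], 0.0)

    def test_pooled_variance_closed_form(self):
        """A={1,2,3}, B={4,5,6} at one voxel -> t = -3.6742."""
        shape = (3, 3, 3)
        mask = np.zeros(shape, bool)
        mask[1, 1, 1] = True
        maps_a = [np.full(shape, v) for v in (1.0, 2.0, 3.0)]
        maps_b = [np.full(shape, v) for v in (4.0, 5.0, 6.0)]
        t = tstat_map(maps_a, maps_b, mask)
        assert t[1, 1, 1] == pytest.approx(-3.6742, abs=1e-4)

    def test_single_subject_group_rejected(self):
        m = np.ones((3, 3, 3))
        with pytest.raises(ValueError, match=">= 2 subjects"):
            tstat_map([m], [m, m], np.ones((3, 3, 3), bool))

    def test_nan_voxels_excluded(self):
        mask = np.ones((3, 3, 3), bool)
        a = np.ones((3, 3, 3))
        a_nan = a.copy()
        a_nan[0, 0, 0] = np.nan
        t = tstat_map([a_nan, a, a], [a * 2, a * 2, a * 2.1], mask)
        assert np.isnan(t[0, 0, 0])
        assert np.isfinite(t[1, 1, 1])


class TestTFCE:
    def test_zero_map_gives_zero(self):
        mask = np.ones((4, 4, 4), bool)
        out = tfce_transform(np.zeros((4, 4, 4)), mask)
        assert np.all(out == 0)

    def test_single_voxel_closed_form(self):
        """Isolated voxel at stat 1.0: sum of 1^E * h^2 * dh over 10 steps."""
        stat = np.zeros((5, 5, 5))
        stat[2, 2, 2] = 1.0
        cfg = TFCEConfig(dh=0.1)
        out = tfce_transform(stat, np.ones((5, 5, 5), bool), cfg)
        expected = 0.1 * sum((0.1 * k) ** 2 for k in range(1, 11))  # 0.385
        assert out[2, 2, 2] == pytest.approx(expected, abs=1e-12)
        assert out.sum() == pytest.approx(out[2, 2, 2])

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_brute_force_on_random_maps(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(5):
            stat = rng.normal(0, 1, (6, 6, 6))
            mask = rng.random((6, 6, 6)) > 0.2
            cfg = TFCEConfig(dh=0.25, connectivity=connectivity)
            fast = tfce_transform(stat, mask, cfg)
            slow = brute_force_tfce(stat, mask, cfg.E, cfg.H, cfg.dh, connectivity)
            np.testing.assert_allclose(fast, slow, atol=1e-8)

    def test_larger_blob_enhanced_more(self):
        stat = np.zeros((8, 8, 8))
        stat[1, 1, 1] = 2.0            # singleton
        stat[5, 5, 5] = stat[5, 5, 6] = 2.0  # 2-voxel blob at equal height
        out = tfce_transform(stat, np.ones((8, 8, 8), bool), TFCEConfig(dh=0.1))
        assert out[5, 5, 5] > out[1, 1, 1]

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        stat = np.zeros((10, 10, 10))
        stat[2:5, 2:5, 2:5] = rng.random((3, 3, 3)) * 2
        mask = np.zeros((10, 10, 10), bool)
        mask[1:6, 1:6, 1:6] = True
        cfg = TFCEConfig(dh=0.2)
        out1 = tfce_transform(stat, mask, cfg)
        out2 = tfce_transform(np.roll(stat, 3, axis=0), np.roll(mask, 3, axis=0), cfg)
        np.testing.assert_allclose(np.roll(out1, 3, axis=0), out2, atol=1e-12)

    def test_invariant_to_values_outside_mask(self):
        rng = np.random.default_rng(4)
        stat = rng.random((6, 6, 6))
        mask = np.zeros((6, 6, 6), bool)
        mask[2:4, 2:4, 2:4] = True
        cfg = TFCEConfig(dh=0.1)
        out1 = tfce_transform(stat, mask, cfg)
        noisy = stat.copy()
        noisy[~mask] = 99.0
        out2 = tfce_transform(noisy, mask, cfg)
        np.testing.assert_allclose(out1, out2)

    def test_nonfinite_inside_mask_rejected(self):
        stat = np.full((4, 4, 4), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            tfce_transform(stat, np.ones((4, 4, 4), bool))


class TestPermutationFWE:
    def test_exhaustive_matches_sampled_cover_on_3v3(self):
        mask = np.ones((4, 4, 4), bool)
        rng = np.random.default_rng(7)
        maps = [rng.normal(1.0, 0.05, (4, 4, 4)) for _ in range(6)]
        maps[0][1:3, 1:3, 1:3] += 0.3  # some structure in one A subject
        labels = ["A"] * 3 + ["B"] * 3
        exh = permutation_fwe(maps, labels, mask,
                              TFCEConfig(n_perm=20, exhaustive=True, dh=0.1))
        # sampled mode with n_perm >= 20 distinct relabelings covers the
        # exhaustive set and must produce the identical p map
        smp = permutation_fwe(maps, labels, mask,
                              TFCEConfig(n_perm=20, seed=1, dh=0.1))
        assert exh.exhaustive_used and smp.exhaustive_used
        np.testing.assert_array_equal(exh.p_fwe_map, smp.p_fwe_map)
        assert exh.null_max.size == 20

    def test_exhaustive_nperm_overflow_rejected(self):
        mask = np.ones((3, 3, 3), bool)
        maps = make_noise_maps(mask, 6, seed=0)
        with pytest.raises(ValueError, match="distinct relabelings"):
            permutation_fwe(maps, ["A"] * 3 + ["B"] * 3, mask,
                            TFCEConfig(n_perm=50, exhaustive=True))

    def test_single_permutation_p_bounds(self):
        mask = np.ones((3, 3, 3), bool)
        maps = make_noise_maps(mask, 12, seed=5)
        res = permutation_fwe(maps, ["A"] * 6 + ["B"] * 6, mask,
                              TFCEConfig(n_perm=1, seed=0))
        vals = res.p_fwe_map[np.isfinite(res.p_fwe_map)]
        assert set(np.unique(vals)) <= {0.5, 1.0}
        assert res.n_significant == 0

    def test_p_bounds_and_monotonicity_in_tfce(self):
        mask = np.ones((4, 4, 4), bool)
        maps = make_noise_maps(mask, 10, seed=2)
        maps[0][:2] += 0.2
        res = permutation_fwe(maps, ["A"] * 5 + ["B"] * 5, mask,
                              TFCEConfig(n_perm=100, seed=3))
        p = res.p_fwe_map[res.mask]
        tf = res.tfce_map[res.mask]
        assert np.all(p >= 1.0 / (res.null_max.size + 1) - 1e-12)
        assert np.all(p <= 1.0)
        order = np.argsort(tf)
        assert np.all(np.diff(p[order]) <= 1e-12)  # p non-increasing in TFCE

    def test_seed_determinism(self):
        mask = np.ones((4, 4, 4), bool)
        maps = make_noise_maps(mask, 12, seed=9)
        cfg = TFCEConfig(n_perm=50, seed=11)
        r1 = permutation_fwe(maps, ["A"] * 6 + ["B"] * 6, mask, cfg)
        r2 = permutation_fwe(maps, ["A"] * 6 + ["B"] * 6, mask, cfg)
        np.testing.assert_array_equal(r1.null_max, r2.null_max)
        np.testing.assert_array_equal(r1.p_fwe_map, r2.p_fwe_map)

    def test_strong_effect_detected_in_correct_direction(self):
        mask = np.ones((5, 5, 5), bool)
        maps = make_noise_maps(mask, 12, seed=13, sd=0.02)
        for m in maps[:6]:
            m[1:4, 1:4, 1:4] += 0.5  # group A higher in a blob
        labels = ["A"] * 6 + ["B"] * 6
        up = permutation_fwe(maps, labels, mask,
                             TFCEConfig(n_perm=200, seed=1, direction="A>B"))
        down = permutation_fwe(maps, labels, mask,
                               TFCEConfig(n_perm=200, seed=1, direction="B>A"))
        assert up.n_significant > 0
        assert np.all(up.sig_mask[1:4, 1:4, 1:4])
        assert down.n_significant == 0

    def test_degenerate_groups_rejected(self):
        mask = np.ones((3, 3, 3), bool)
        maps = make_noise_maps(mask, 3, seed=0)
        with pytest.raises(ValueError, match="degenerate"):
            permutation_fwe(maps, ["A", "A", "B"], mask, TFCEConfig(n_perm=10))
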