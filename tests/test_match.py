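import numpy as np
import pytest
from scipy import ndimage

from connfp.match import (
    AssignmentMap,
    StatMap,
    classify_voxels,
    conjunction_difference,
    group_onesample_tfce,
    tfce_enhance,
    unassigned_evidence,
    voxelwise_similarity_map,
    weighted_timeseries,
    wholebrain_connectivity_map,
)


def tfce_oracle(vol, E=0.5, H=2.0, dh=0.01, connectivity=6):
    """Brute-force per-threshold connected-component labelling."""
    vol = np.asarray(vol, float)
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])

    def one_sided(v):
        out = np.zeros_like(v)
        vmax = v.max()
        if vmax <= 0:
            return out
        nsteps = int(np.floor(vmax / dh + 1e-12))
        for s in range(1, nsteps + 1):
            h = s * dh
            mask = v >= h
            lab, nlab = ndimage.label(mask, structure=structure)
            if nlab == 0:
                continue
            sizes = ndimage.sum_labels(np.ones_like(v), lab, index=np.arange(1, nlab + 1))
            ext = np.zeros_like(v)
            ext[mask] = sizes[lab[mask] - 1]
            out += np.where(mask, ext**E * h**H * dh, 0.0)
        return out

    return one_sided(np.maximum(vol, 0)) - one_sided(np.maximum(-vol, 0))


class TestSimilarityMap:
    def test_proportional_fingerprint_maxed(self, rng):
        t = rng.normal(size=8)
        fps = np.vstack([2.0 * t + 1.0, t])
        z = voxelwise_similarity_map(fps, t)
        assert z[0] == pytest.approx(np.arctanh(1 - 1e-7))
        assert z[1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_negated_fingerprint_negative(self, rng):
        t = rng.normal(size=8)
        z = voxelwise_similarity_map((-t)[None, :], t)
        assert z[0] < 0

    def test_null_z_standard_deviation(self, rng):
        # null r of two 12-vectors: z sd ~ 1/sqrt(12 - 3)
        t = rng.normal(size=12)
        fps = rng.normal(size=(20_000, 12))
        z = voxelwise_similarity_map(fps, t)
        assert abs(z.mean()) < 0.02
        assert z.std() == pytest.approx(1 / 3, abs=0.03)

    def test_constant_fingerprint_warns_and_zeroes(self, rng):
        fps = np.vstack([np.full(6, 0.3), rng.normal(size=6)])
        with pytest.warns(UserWarning, match="constant"):
            z = voxelwise_similarity_map(fps, rng.normal(size=6))
        assert z[0] == 0.0

    def test_too_few_targets_raises(self, rng):
        with pytest.raises(ValueError):
            voxelwise_similarity_map(rng.normal(size=(4, 2)), rng.normal(size=2))


class TestTfce:
    def test_all_zero(self):
        np.testing.assert_array_equal(tfce_enhance(np.zeros((4, 4, 4))), 0.0)

    def test_isolated_voxel_closed_form(self):
        v = np.zeros((5, 5, 5))
        v[2, 2, 2] = 3.0
        e = tfce_enhance(v, E=0.5, H=2.0, dh=0.01)
        assert e[2, 2, 2] == pytest.approx(3.0**3 / 3.0, rel=0.01)
        assert np.all(e[v == 0] == 0)

    def test_two_voxel_plateau_closed_form(self):
        h = 2.0
        v = np.zeros((5, 5, 5))
        v[2, 2, 2] = h
        v[2, 2, 3] = h
        e = tfce_enhance(v, E=0.5, H=2.0, dh=0.001)
        expected = np.sqrt(2) * h**3 / 3
        assert e[2, 2, 2] == pytest.approx(expected, rel=0.01)
        assert e[2, 2, 3] == pytest.approx(expected, rel=0.01)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_agrees_with_bruteforce_oracle(self, rng, connectivity):
        for _ in range(10):
            v = rng.normal(size=(5, 5, 5))
            got = tfce_enhance(v, dh=0.05, connectivity=connectivity)
            want = tfce_oracle(v, dh=0.05, connectivity=connectivity)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_monotone_under_scaling(self, rng):
        v = np.abs(rng.normal(size=(6, 6, 6)))
        e1 = tfce_enhance(v, dh=0.02)
        e2 = tfce_enhance(2.0 * v, dh=0.02)
        assert np.all(e2 >= e1 - 1e-12)

    def test_negative_values_enhanced_separately(self, rng):
        v = rng.normal(size=(5, 5, 5))
        e = tfce_enhance(v, dh=0.05)
        e_neg = tfce_enhance(-v, dh=0.05)
        np.testing.assert_allclose(e, -e_neg, atol=1e-10)

    def test_non_3d_raises(self):
        with pytest.raises(ValueError):
            tfce_enhance(np.zeros((4, 4)))

    def test_bad_connectivity_raises(self):
        with pytest.raises(ValueError):
            tfce_enhance(np.zeros((4, 4, 4)), connectivity=10)


class TestGroupInference:
    def test_planted_effect_detected(self, rng):
        maps = rng.normal(size=(10, 8, 8, 4))
        maps[:, 2:5, 2:5, 1:3] += 2.0
        sm = group_onesample_tfce(maps, n_perm=500, rng_seed=0)
        assert isinstance(sm, StatMap)
        block = sm.p_corrected[2:5, 2:5, 1:3]
        assert np.all(block < 0.05)
        # exact enumeration path for n=10 subjects
        assert sm.n_permutations == 2**10

    def test_degenerate_constant_region_significant(self, rng):
        maps = np.tile(rng.normal(size=(1, 6, 6, 3)), (8, 1, 1, 1))
        maps[:, 1:4, 1:4, :] = 1.5  # identical across subjects, zero variance
        sm = group_onesample_tfce(maps, n_perm=300, rng_seed=1)
        assert np.isfinite(sm.t).all()
        assert np.all(sm.p_corrected[1:4, 1:4, :] < 0.05)

    def test_p_floor_monte_carlo(self, rng):
        maps = rng.normal(size=(20, 5, 5, 3)) + 3.0
        sm = group_onesample_tfce(maps, n_perm=99, rng_seed=2)
        assert sm.p_corrected.min() >= 1 / 100
        assert sm.n_permutations == 99

    def test_subject_relabelling_invariance(self, rng):
        maps = rng.normal(size=(8, 5, 5, 3))
        sm1 = group_onesample_tfce(maps, rng_seed=3)
        sm2 = group_onesample_tfce(maps[::-1], rng_seed=3)
        # exact enumeration is order-invariant up to float-tie resolution
        np.testing.assert_allclose(sm1.p_corrected, sm2.p_corrected, atol=2 / 256)

    def test_too_few_subjects_raises(self, rng):
        with pytest.raises(ValueError):
            group_onesample_tfce(rng.normal(size=(1, 4, 4, 2)))


class TestClassify:
    def _stat(self, p):
        arr = np.array(p).reshape(1, 1, -1)
        return StatMap(t=np.ones_like(arr), p_corrected=arr, n_subjects=5, n_permutations=10)

    def test_single_match(self):
        am = classify_voxels({"a": self._stat([0.01]), "b": self._stat([0.2]), "c": self._stat([0.9])})
        assert am.matched["a"][0, 0, 0]
        assert not am.matched["b"][0, 0, 0]
        assert not am.unassigned[0, 0, 0]
        assert am.label_sets()[0, 0, 0] == frozenset({"a"})

    def test_unassigned(self):
        am = classify_voxels({"a": self._stat([0.3]), "b": self._stat([0.6])})
        assert am.unassigned[0, 0, 0]
        assert am.label_sets()[0, 0, 0] == frozenset()

    def test_multi_membership_preserved(self):
        am = classify_voxels({"a": self._stat([0.01]), "b": self._stat([0.02]), "c": self._stat([0.9])})
        assert am.label_sets()[0, 0, 0] == frozenset({"a", "b"})

    def test_grid_mismatch_raises(self):
        sm1 = self._stat([0.1])
        sm2 = StatMap(t=np.ones((2, 2, 2)), p_corrected=np.full((2, 2, 2), 0.5),
                      n_subjects=5, n_permutations=10)
        with pytest.raises(ValueError):
            classify_voxels({"a": sm1, "b": sm2})


class TestConjunction:
    def test_identical_maps_empty_conjunction(self, rng):
        u = rng.normal(size=(10, 5, 5, 3))
        conj, masks = conjunction_difference(u, {"a": u.copy(), "b": u + rng.normal(size=u.shape)},
                                             n_perm=200, rng_seed=0)
        assert not masks["a"].any()
        assert not conj.any()

    def test_planted_region_recovered(self, rng):
        u = rng.normal(size=(20, 8, 8, 4))
        u[:, 2:6, 2:6, :] += 1.0
        assigned = {k: rng.normal(size=(20, 8, 8, 4)) for k in "abc"}
        conj, masks = conjunction_difference(u, assigned, n_perm=300, rng_seed=1)
        assert conj[2:6, 2:6, :].mean() > 0.5  # region recovered
        assert conj.any()
        outside = conj.copy()
        outside[2:6, 2:6, :] = False
        assert outside.mean() < 0.02
        for m in masks.values():
            assert np.all(conj <= m)  # conjunction subset of every pairwise mask

    def test_unpaired_raises(self, rng):
        with pytest.raises(ValueError, match="paired"):
            conjunction_difference(rng.normal(size=(5, 4, 4, 2)),
                                   {"a": rng.normal(size=(6, 4, 4, 2))}, n_perm=10)

    def test_unassigned_evidence(self, rng):
        stacks = {"a": rng.normal(size=(4, 10)), "b": rng.normal(size=(4, 10))}
        ev = unassigned_evidence(stacks)
        np.testing.assert_allclose(ev, 1.0 - np.maximum(stacks["a"], stacks["b"]))


class TestWeightedTimeseries:
    def test_single_positive_voxel(self, rng):
        ts = rng.normal(size=(50, 3))
        t = np.array([-1.0, 0.0, 2.5])
        np.testing.assert_allclose(weighted_timeseries(t, ts), ts[:, 2])

    def test_hand_weights(self, rng):
        ts = rng.normal(size=(50, 2))
        out = weighted_timeseries(np.array([1.0, 3.0]), ts)
        np.testing.assert_allclose(out, 0.25 * ts[:, 0] + 0.75 * ts[:, 1])

    def test_no_positive_raises(self, rng):
        with pytest.raises(ValueError, match="positive"):
            weighted_timeseries(np.array([-1.0, 0.0]), rng.normal(size=(50, 2)))


class TestWholebrain:
    def test_planted_block_survives(self, rng):
        grid = (6, 6, 4)
        n_vox = int(np.prod(grid))
        n_subj, n_time = 12, 150
        idx = np.zeros(grid, bool)
        idx[1:4, 1:4, 1:3] = True
        flat_idx = idx.ravel()
        weighted, brains = [], []
        for _ in range(n_subj):
            seed = rng.normal(size=n_time)
            brain = rng.normal(size=(n_time, n_vox))
            brain[:, flat_idx] += seed[:, None]
            weighted.append(seed)
            brains.append(brain)
        res = wholebrain_connectivity_map(weighted, brains, grid, n_perm=200,
                                          voxel_p=0.001, cluster_alpha=0.05, rng_seed=0)
        assert res["significant_mask"][idx].mean() > 0.9
        assert res["significant_mask"][~idx].mean() < 0.05

    def test_bad_voxel_p_raises(self, rng):
        with pytest.raises(ValueError, match="voxel_p"):
            wholebrain_connectivity_map([rng.normal(size=10)] * 2,
                                        [rng.normal(size=(10, 8))] * 2,
                                        (2, 2, 2), voxel_p=1.0)

    def test_pure_noise_rarely_significant(self, rng):
        grid = (5, 5, 4)
        n_vox = int(np.prod(grid))
        hits = 0
        for rep in range(10):
            weighted = [rng.normal(size=80) for _ in range(8)]
            brains = [rng.normal(size=(80, n_vox)) for _ in range(8)]
            res = wholebrain_connectivity_map(weighted, brains, grid, n_perm=99, rng_seed=rep)
            hits += res["significant_mask"].any()
        assert hits <= 2
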