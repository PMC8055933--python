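"""Patch extraction: lesion filtering, ring geometry, normalization, and the
greedy union-overlap sampler."""

import numpy as np
import pytest

from attnrank.patches import (
    DegenerateContrastError,
    Patch,
    PatchSpec,
    build_patch_dataset,
    cube_overlap_fraction,
    extract_patch_values,
    filter_small_lesions,
    make_perilesional_mask,
    normalize_subject,
    sample_patches,
)


class TestFilterSmallLesions:
    def test_small_lesion_removed_and_relabeled(self):
        vol = np.zeros((10, 10, 10), np.int32)
        vol[0, 0, :2] = 1          # 2 voxels -> dropped
        vol[5, 5, :10] = 2         # 10 voxels -> survives as label 1
        out = filter_small_lesions(vol, 3)
        np.testing.assert_array_equal(np.unique(out), [0, 1])
        assert (out == 1).sum() == 10
        assert out[5, 5, 0] == 1 and out[0, 0, 0] == 0

    def test_empty_volume_identity(self):
        out = filter_small_lesions(np.zeros((4, 4, 4), np.int32), 3)
        assert out.max() == 0

    def test_no_op_when_all_large(self):
        vol = np.zeros((10, 10, 10), np.int32)
        vol[:2, 0, 0:3] = 1
        vol[5:7, 5, 5:8] = 2
        out = filter_small_lesions(vol, 3)
        np.testing.assert_array_equal(np.unique(out), np.unique(vol))
        np.testing.assert_array_equal(out == 1, vol == 1)


class TestPerilesionalRing:
    def test_single_voxel_ring1_is_face_neighbors(self):
        vol = np.zeros((7, 7, 7), np.int32)
        vol[3, 3, 3] = 1
        ring = make_perilesional_mask(vol, np.ones_like(vol, bool), ring_width=1)
        # brute-force 6-neighborhood oracle
        expected = {(2, 3, 3), (4, 3, 3), (3, 2, 3), (3, 4, 3), (3, 3, 2), (3, 3, 4)}
        assert set(map(tuple, np.argwhere(ring))) == expected

    def test_no_lesions_empty_ring(self):
        ring = make_perilesional_mask(np.zeros((5, 5, 5), np.int32),
                                      np.ones((5, 5, 5), bool), 3)
        assert not ring.any()

    def test_ring_clipped_by_tissue_mask(self):
        vol = np.zeros((7, 7, 7), np.int32)
        vol[3, 3, 3] = 1
        mask = np.ones_like(vol, bool)
        mask[:, :, :3] = False  # excludes part of the would-be ring
        ring = make_perilesional_mask(vol, mask, 1)
        full = make_perilesional_mask(vol, np.ones_like(vol, bool), 1)
        np.testing.assert_array_equal(ring, full & mask)  # set-intersection oracle

    def test_ring_width_is_cityblock_distance(self):
        vol = np.zeros((11, 11, 11), np.int32)
        vol[5, 5, 5] = 1
        ring = make_perilesional_mask(vol, np.ones_like(vol, bool), 3)
        dist = np.abs(np.indices(vol.shape) - 5).sum(axis=0)
        np.testing.assert_array_equal(ring, (dist >= 1) & (dist <= 3))


class TestNormalize:
    def test_masked_zscore(self, rng):
        vol = rng.standard_normal((10, 10, 10)) * 5 + 2
        mask = np.zeros_like(vol, bool)
        mask[2:8, 2:8, 2:8] = True
        out = normalize_subject(vol, mask)
        assert abs(out[mask].mean()) < 1e-10
        assert abs(out[mask].std() - 1) < 1e-10
        assert np.all(out[~mask] == 0)

    def test_affine_invariance(self, rng):
        vol = rng.standard_normal((8, 8, 8))
        mask = np.ones_like(vol, bool)
        np.testing.assert_allclose(normalize_subject(3.0 * vol + 7.0, mask),
                                   normalize_subject(vol, mask), atol=1e-9)

    @pytest.mark.parametrize("bad", ["tiny_mask", "constant"])
    def test_degenerate_inputs_raise(self, bad):
        vol = np.ones((5, 5, 5)) if bad == "constant" else np.random.rand(5, 5, 5)
        mask = np.ones_like(vol, bool)
        if bad == "tiny_mask":
            mask[:] = False
            mask[0, 0, 0] = True
        with pytest.raises(DegenerateContrastError):
            normalize_subject(vol, mask)


class TestOverlapRule:
    def test_offset4_overlap_is_point2_and_offset3_is_point4(self):
        occupied = np.zeros((20, 20, 20), bool)
        occupied[2:7, 2:7, 2:7] = True  # cube centered at (4,4,4), size 5
        # 5x5x1 slab shared at offset 4 -> 25/125
        assert cube_overlap_fraction(occupied, (8, 4, 4), 5) == pytest.approx(0.2)
        # 5x5x2 at offset 3 -> 50/125
        assert cube_overlap_fraction(occupied, (7, 4, 4), 5) == pytest.approx(0.4)

    def test_greedy_acceptance_at_boundary(self, rng):
        """A lesion shaped so candidates are exactly offset-4 cubes: both are
        accepted at max_overlap 0.2 (shared fraction exactly 0.2)."""
        labels = np.zeros((20, 20, 20), np.int32)
        labels[4, 4, 4] = 1
        labels[8, 4, 4] = 1   # second center 4 voxels away along one axis
        spec = PatchSpec(patch_size=5, max_overlap=0.2, min_lesion_voxels=1,
                         density=1.0)
        patches = sample_patches(labels, np.zeros_like(labels, bool), spec, rng)
        assert len(patches) == 2

    def test_rejection_below_threshold(self, rng):
        """Offset-3 candidates overlap 0.4 > 0.2 and cannot both be kept."""
        labels = np.zeros((20, 20, 20), np.int32)
        labels[4, 4, 4] = 1
        labels[7, 4, 4] = 1
        spec = PatchSpec(patch_size=5, max_overlap=0.2, min_lesion_voxels=1,
                         density=1.0)
        patches = sample_patches(labels, np.zeros_like(labels, bool), spec, rng)
        assert len(patches) == 1


class TestSampler:
    def _subject(self, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.zeros((24, 24, 24), np.int32)
        labels[8:12, 8:12, 8:12] = 1
        labels[16:19, 16:19, 5:8] = 2
        peri = make_perilesional_mask(labels, np.ones_like(labels, bool), 3)
        return labels, peri, rng

    def test_min_one_patch_per_lesion(self, rng):
        labels = np.zeros((20, 20, 20), np.int32)
        labels[10, 10, 10] = 1
        spec = PatchSpec(min_lesion_voxels=1, density=1e-9)
        patches = sample_patches(labels, np.zeros_like(labels, bool), spec, rng)
        assert len(patches) == 1 and patches[0].label == 1

    def test_centers_in_correct_regions_and_inside_volume(self):
        labels, peri, rng = self._subject()
        spec = PatchSpec(density=0.1)
        patches = sample_patches(labels, peri, spec, rng)
        assert patches
        for p in patches:
            c = np.asarray(p.center)
            assert np.all(c - 2 >= 0) and np.all(c + 3 <= 24)
            if p.label == 1:
                assert labels[tuple(c)] > 0
            else:
                assert peri[tuple(c)]

    def test_union_constraint_holds_under_replay(self):
        """Replaying the accepted patches in greedy order, every cube shares
        at most max_overlap of its voxels with the union of its predecessors."""
        labels, peri, rng = self._subject(3)
        spec = PatchSpec(density=0.2, max_overlap=0.2)
        patches = sample_patches(labels, peri, spec, rng)
        occupied = np.zeros(labels.shape, bool)
        for p in patches:
            assert cube_overlap_fraction(occupied, p.center, 5) <= 0.2 + 1e-12
            sl = tuple(slice(c - 2, c + 3) for c in p.center)
            occupied[sl] = True

    def test_same_seed_same_manifest(self):
        labels, peri, _ = self._subject(1)
        spec = PatchSpec(density=0.1)
        a = sample_patches(labels, peri, spec, np.random.default_rng(9))
        b = sample_patches(labels, peri, spec, np.random.default_rng(9))
        assert [(p.center, p.label) for p in a] == [(p.center, p.label) for p in b]


def test_extract_patch_values_shape_and_content(rng):
    vols = [rng.standard_normal((10, 10, 10)) for _ in range(3)]
    block = extract_patch_values(vols, (5, 5, 5), 5)
    assert block.shape == (3, 5, 5, 5)
    np.testing.assert_allclose(block[1], vols[1][3:8, 3:8, 3:8], rtol=1e-6)


def test_build_patch_dataset_end_to_end(small_cohort):
    config, cohort = small_cohort
    X, y, sids, patches = build_patch_dataset(cohort, PatchSpec(density=0.05, seed=4))
    assert X.shape[1:] == (config.n_contrasts, 5, 5, 5)
    assert len(X) == len(y) == len(sids) == len(patches)
    assert set(np.unique(y)) == {0, 1}
    assert set(sids) <= {r.subject_id for r in cohort}
    # subject-wise normalization: values live on the z-scale
    assert np.abs(X).max() < 10
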