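"""WM masking, series extraction, fingerprints, k-means and consensus."""

import numpy as np
import pytest

from twdfc.core import TwDfcImage, WindowSpec
from twdfc.images import Image3D
from twdfc.parcellate import (
    Partition,
    coassignment,
    consensus,
    extract_series,
    fingerprint,
    group_coassignment,
    kmeans_partition,
    make_wm_mask,
)


def img(data, vs=2.0):
    return Image3D(np.asarray(data), np.diag([vs, vs, vs, 1.0]))


class TestMakeWmMask:
    def test_full_probability_and_empty_roi_gives_full_mask(self):
        wm = img(np.ones((8, 8, 8)))
        roi = img(np.zeros((8, 8, 8)))
        out = make_wm_mask([wm], [roi], dilation_mm=4.0)
        assert out.data.all()

    def test_subthreshold_probability_is_error(self):
        wm = img(np.full((8, 8, 8), 0.4))
        roi = img(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError):
            make_wm_mask([wm], [roi], dilation_mm=4.0)

    def test_roi_and_4mm_surround_removed(self, small_scene):
        out = make_wm_mask(
            [small_scene.wm_mask],
            [small_scene.roi_left, small_scene.roi_right],
            dilation_mm=4.0,
        )
        from scipy import ndimage

        roi = (small_scene.roi_left.data > 0) | (small_scene.roi_right.data > 0)
        dist = ndimage.distance_transform_edt(~roi, sampling=out.voxel_sizes)
        assert not np.any(out.data[dist <= 4.0])
        assert out.data.any()

    def test_mean_across_subjects_is_thresholded(self):
        low = img(np.full((6, 6, 6), 0.2))
        high = img(np.full((6, 6, 6), 0.9))
        roi = img(np.zeros((6, 6, 6)))
        out = make_wm_mask([low, high], [roi], dilation_mm=0.0)  # mean 0.55
        assert out.data.all()


def make_twdfc(data4d, traversed=None, vs=2.0):
    data4d = np.asarray(data4d, dtype=float)
    if traversed is None:
        traversed = np.ones(data4d.shape[:3], dtype=bool)
    return TwDfcImage(
        data4d, traversed, np.diag([vs, vs, vs, 1.0]), WindowSpec(2, 1),
        np.arange(data4d.shape[3]),
    )


class TestExtractSeries:
    def test_factor_one_is_identity_extraction(self, rng):
        data = rng.normal(0, 1, (4, 4, 4, 5))
        tw = make_twdfc(data)
        mask = img(np.ones((4, 4, 4)))
        series, vox = extract_series(tw, mask, 1)
        assert series.shape == (64, 5)
        np.testing.assert_array_equal(series, data.reshape(-1, 5))

    def test_constant_block_downsamples_to_constant(self):
        data = np.full((4, 4, 4, 3), 2.5)
        series, vox = extract_series(make_twdfc(data), img(np.ones((4, 4, 4))), 2)
        assert series.shape == (8, 3)
        np.testing.assert_allclose(series, 2.5)

    def test_factor_two_matches_block_mean_oracle(self, rng):
        data = rng.normal(0, 1, (6, 6, 6, 4))
        series, vox = extract_series(make_twdfc(data), img(np.ones((6, 6, 6))), 2)
        for row, v in zip(series, vox):
            x, y, z = v * 2
            block = data[x : x + 2, y : y + 2, z : z + 2, :]
            np.testing.assert_allclose(row, block.mean(axis=(0, 1, 2)), atol=1e-12)

    def test_non_integer_factor_rejected(self, rng):
        tw = make_twdfc(rng.normal(0, 1, (4, 4, 4, 3)))
        with pytest.raises(ValueError):
            extract_series(tw, img(np.ones((4, 4, 4))), 1.5)

    def test_untraversed_voxels_excluded_from_block_means(self, rng):
        data = np.zeros((2, 2, 2, 3))
        traversed = np.zeros((2, 2, 2), dtype=bool)
        data[0, 0, 0] = [1.0, 2.0, 3.0]
        traversed[0, 0, 0] = True
        series, vox = extract_series(make_twdfc(data, traversed), img(np.ones((2, 2, 2))), 2)
        np.testing.assert_allclose(series[0], [1.0, 2.0, 3.0])


class TestFingerprint:
    def test_closed_form_correlations(self):
        w = np.arange(10.0)
        roi = np.stack([w])  # r=1 with itself
        wm = np.stack([w, -w, np.sin(w)])
        fp = fingerprint(roi, wm)
        clamp = np.arctanh(1 - 1e-7)
        assert fp.matrix[0, 0] == pytest.approx(clamp)
        assert fp.matrix[0, 1] == pytest.approx(-clamp)

    def test_half_correlation_matches_atanh(self, rng):
        # construct exact r = 0.5 via orthogonal components
        a = np.tile([1.0, -1.0], 10)
        b = np.tile([1.0, 1.0, -1.0, -1.0], 5)
        y = 0.5 * a + np.sqrt(0.75) * (b - b.mean()) / b.std()
        fp = fingerprint(np.stack([a]), np.stack([y]))
        assert fp.matrix[0, 0] == pytest.approx(np.arctanh(0.5), abs=1e-12)

    def test_matrix_matches_elementwise_oracle(self, rng):
        roi = rng.normal(0, 1, (7, 30))
        wm = rng.normal(0, 1, (9, 30))
        fp = fingerprint(roi, wm)
        for i in range(7):
            for j in range(9):
                r = np.corrcoef(roi[i], wm[j])[0, 1]
                assert fp.matrix[i, j] == pytest.approx(np.arctanh(r), abs=1e-12)

    def test_zero_variance_series_maps_to_zero(self, rng):
        roi = np.vstack([np.ones(10), rng.normal(0, 1, 10)])
        wm = rng.normal(0, 1, (3, 10))
        fp = fingerprint(roi, wm)
        np.testing.assert_array_equal(fp.matrix[0], 0.0)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            fingerprint(np.ones((2, 2)), np.ones((2, 2)))

    def test_invariant_under_joint_window_permutation(self, rng):
        roi = rng.normal(0, 1, (5, 20))
        wm = rng.normal(0, 1, (6, 20))
        perm = rng.permutation(20)
        a = fingerprint(roi, wm).matrix
        b = fingerprint(roi[:, perm], wm[:, perm]).matrix
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestKmeansPartition:
    def test_recovers_well_separated_blocks(self, rng):
        x = np.vstack(
            [rng.normal(0, 0.1, (20, 5)), rng.normal(10, 0.1, (20, 5))]
        )
        p = kmeans_partition(x, 2, n_init=10, seed=1)
        assert len(set(p.labels[:20])) == 1
        assert len(set(p.labels[20:])) == 1
        assert p.labels[0] != p.labels[-1]

    def test_duplicated_rows_share_labels(self, rng):
        """Identical rows always land in the same cluster: duplicating the
        dataset duplicates the partition."""
        x = rng.normal(0, 1, (15, 4))
        p2 = kmeans_partition(np.vstack([x, x]), 3, n_init=20, seed=2)
        np.testing.assert_array_equal(p2.labels[:15], p2.labels[15:])

    def test_k_equal_n_gives_singletons(self, rng):
        x = rng.normal(0, 1, (6, 3))
        p = kmeans_partition(x, 6, n_init=5, seed=0)
        assert len(set(p.labels)) == 6

    def test_deterministic_for_fixed_seed(self, rng):
        x = rng.normal(0, 1, (30, 4))
        a = kmeans_partition(x, 3, n_init=10, seed=9)
        b = kmeans_partition(x, 3, n_init=10, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_fewer_distinct_rows_than_k_rejected(self):
        x = np.tile(np.arange(3.0), (5, 1))
        with pytest.raises(ValueError):
            kmeans_partition(x, 2, n_init=5, seed=0)


def part(labels, k=None):
    labels = np.asarray(labels)
    return Partition(labels, k or labels.max(), np.arange(len(labels))[:, None])


class TestConsensus:
    def test_coassignment_is_label_invariant(self):
        q1 = coassignment(part([1, 1, 2, 2, 3])).q
        q2 = coassignment(part([3, 3, 1, 1, 2])).q
        np.testing.assert_array_equal(q1, q2)
        assert np.array_equal(q1, q1.T) and np.all(np.diag(q1) == 1)

    def test_identical_partitions_reproduced_up_to_relabelling(self):
        from sklearn.metrics import adjusted_rand_score

        p = part([1, 1, 2, 2, 3, 3, 1, 2])
        cons = consensus([p] * 7, k=3, n_init=10, seed=4)
        assert adjusted_rand_score(cons.labels, p.labels) == 1.0

    def test_group_matrix_matches_hand_average(self):
        pa = part([1, 1, 2, 2, 1, 2], k=2)
        pb = part([2, 1, 2, 1, 1, 1], k=2)
        q = group_coassignment([pa, pb]).q
        # hand-computed for pair (0, 1): subject A same (1), subject B different (0)
        assert q[0, 1] == 0.5
        expect = (coassignment(pa).q + coassignment(pb).q) / 2
        np.testing.assert_array_equal(q, expect)

    def test_majority_partition_wins_with_noisy_minority(self, rng):
        from sklearn.metrics import adjusted_rand_score

        n = 60
        base = np.repeat([1, 2], n // 2)
        partitions = []
        for s in range(20):
            labels = base.copy()
            flip = rng.random(n) < 0.10  # 90% agreement
            labels[flip] = 3 - labels[flip]
            partitions.append(part(labels, k=2))
        cons = consensus(partitions, 2, n_init=20, seed=8)
        assert adjusted_rand_score(cons.labels, base) >= 0.9

    def test_inconsistent_voxel_lists_rejected(self):
        pa = part([1, 2, 1])
        pb = Partition(np.array([1, 2, 1]), 2, np.arange(3)[::-1][:, None])
        with pytest.raises(ValueError):
            consensus([pa, pb], 2)


def test_planted_recovery_on_default_scene(default_scene, default_parcellation):
    """Consensus at the planted k recovers the ground-truth parcellation."""
    from sklearn.metrics import adjusted_rand_score

    ari = adjusted_rand_score(
        default_parcellation.group.labels, default_scene.truth_left.labels
    )
    assert ari >= 0.9
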