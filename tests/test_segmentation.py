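"""Segmentation: pre-processing operators, 2D labelling, IoU stitching."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage import measure

from tailbud.segmentation import (
    ClassicalBackend,
    dog_filter,
    equalize_adaptive,
    extract_nuclei,
    join_labels_3d,
    label_2d,
    label_slices,
    segment_nuclei,
)
from tailbud.stack import ImageStack3D
from tailbud.synthetic import EmbryoPhantomSpec, generate_nuclear_stack
from tailbud.validation import match_centroids

ISO = (1.0, 1.0, 1.0)


def _stack(vol, spacing=ISO):
    return ImageStack3D(np.asarray(vol, dtype=float), spacing)


class TestEqualizeAdaptive:
    def test_constant_stack_stays_constant(self):
        out = equalize_adaptive(_stack(np.full((12, 24, 24), 3.0)))
        assert np.ptp(out.voxels) == 0

    def test_output_in_unit_interval(self, rng):
        out = equalize_adaptive(_stack(rng.random((16, 32, 32))))
        assert out.voxels.min() >= 0 and out.voxels.max() <= 1

    def test_kernel_smaller_than_voxel_rejected(self):
        with pytest.raises(ValueError, match="smaller than one voxel"):
            equalize_adaptive(_stack(np.zeros((8, 16, 16)), (2.0, 1.0, 1.0)), kernel_um=1.0)

    def test_low_contrast_ramp_is_stretched(self):
        # a faint ramp occupies [0.4, 0.6] of the range; local equalisation
        # must widen the used dynamic range
        ramp = np.linspace(0.4, 0.6, 32 * 32 * 16).reshape(16, 32, 32)
        out = equalize_adaptive(_stack(ramp), kernel_um=10)
        assert np.ptp(out.voxels) > 0.5

    def test_anisotropic_window(self):
        # kernel 10 µm at (2, 1, 1) µm spacing -> (5, 10, 10) voxels; just
        # verify it runs and respects spacing (no error at z window 5)
        vol = np.random.default_rng(0).random((10, 20, 20))
        out = equalize_adaptive(_stack(vol, (2.0, 1.0, 1.0)), kernel_um=10)
        assert out.voxels.shape == vol.shape


class TestDogFilter:
    def test_constant_stack_gives_zero(self):
        out = dog_filter(_stack(np.full((10, 20, 20), 5.0)))
        np.testing.assert_allclose(out.voxels, 0.0, atol=1e-12)

    def test_sigma_order_rejected(self):
        with pytest.raises(ValueError, match="low_sigma < high_sigma"):
            dog_filter(_stack(np.zeros((8, 8, 8))), low_sigma=3, high_sigma=1)

    def test_nonnegative_everywhere(self, rng):
        out = dog_filter(_stack(rng.random((12, 20, 20))))
        assert out.voxels.min() >= 0

    def test_impulse_response_matches_sampled_kernels(self):
        # independent oracle: sampled, normalised, truncated 1D Gaussians
        # combined separably, differenced and clipped at zero
        def kernel_1d(sigma, truncate=4.0):
            r = int(truncate * sigma + 0.5)
            x = np.arange(-r, r + 1)
            k = np.exp(-0.5 * (x / sigma) ** 2)
            return k / k.sum()

        n = 33
        vol = np.zeros((n, n, n))
        vol[n // 2, n // 2, n // 2] = 1.0
        out = dog_filter(_stack(vol), 1.0, 3.0).voxels

        expected = np.zeros((n, n, n))
        for sigma, sign in ((1.0, 1.0), (3.0, -1.0)):
            k = kernel_1d(sigma)
            r = len(k) // 2
            g = k[:, None, None] * k[None, :, None] * k[None, None, :]
            sub = np.zeros((n, n, n))
            c = n // 2
            sub[c - r:c + r + 1, c - r:c + r + 1, c - r:c + r + 1] = g
            expected += sign * sub
        expected = np.clip(expected, 0, None)
        np.testing.assert_allclose(out, expected, atol=1e-10)


class TestLabel2D:
    def test_two_separated_disks_two_labels(self):
        img = np.zeros((64, 64))
        yy, xx = np.mgrid[:64, :64]
        for cy, cx in ((16, 16), (48, 48)):
            r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / 25.0
            img += np.exp(-r2 / (2 * 0.5**2))
        labels = label_2d(img, ClassicalBackend())
        assert len(np.unique(labels[labels > 0])) == 2

    def test_blank_slice_no_labels(self):
        assert label_2d(np.zeros((32, 32)), ClassicalBackend()).max() == 0

    def test_phantom_slice_label_count(self, separated_phantom):
        # on the mid slice of a separated phantom, every equatorial
        # cross-section (nucleus centre within 2 µm of the slice) is
        # labelled, and no label lies outside a true footprint
        _spec, stack, gt_labels, truth = separated_phantom
        z = gt_labels.shape[0] // 2
        n_strong = int((np.abs(truth["z_um"] - z) <= 2.0).sum())
        n_total = len(np.unique(gt_labels[z][gt_labels[z] > 0]))
        labels = label_2d(stack.channel("nuclear")[z], ClassicalBackend())
        found = np.unique(labels[labels > 0])
        assert n_strong <= len(found) <= n_total
        for lid in found:  # each found blob sits on exactly one true nucleus
            on_truth = gt_labels[z][labels == lid]
            assert len(np.unique(on_truth[on_truth > 0])) == 1

    def test_bad_backend_shape_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            label_2d(np.zeros((16, 16)), lambda s: np.zeros((4, 4), dtype=int))


def _two_slice_footprints(shift):
    """Two 10x10 (100 px) footprints in adjacent slices, offset by columns."""
    labels = np.zeros((2, 20, 40), dtype=np.int32)
    labels[0, 5:15, 10:20] = 1
    labels[1, 5:15, 10 + shift:20 + shift] = 1
    return labels


class TestJoinLabels3D:
    def test_identical_footprints_single_label(self):
        joined = join_labels_3d(_two_slice_footprints(0), 0.6)
        assert joined.max() == 1

    @pytest.mark.parametrize(
        "shift,expected_labels",
        [
            (4, 2),  # overlap 60 px: IoU 60/140 ~ 0.43 < 0.6 -> split
            (2, 1),  # overlap 80 px: IoU 80/120 ~ 0.67 >= 0.6 -> joined
        ],
    )
    def test_iou_threshold_arithmetic(self, shift, expected_labels):
        joined = join_labels_3d(_two_slice_footprints(shift), 0.6)
        assert joined.max() == expected_labels

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            join_labels_3d([np.zeros((4, 4), int), np.zeros((5, 5), int)])

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError, match="iou_threshold"):
            join_labels_3d(np.zeros((2, 4, 4), int), iou_threshold=1.5)

    def test_label_conservation_and_no_slice_merge(self, rng):
        # random blobs: 3D labels never exceed total 2D labels, and two
        # distinct 2D labels in one slice never share a 3D label
        vol = rng.random((8, 40, 40)) > 0.7
        vol = ndi.binary_opening(vol, np.ones((1, 2, 2)))
        l2d = label_slices(vol)
        joined = join_labels_3d(l2d, 0.6)
        total_2d = sum(len(np.unique(l2d[z][l2d[z] > 0])) for z in range(8))
        assert joined.max() <= total_2d
        for z in range(8):
            ids_2d = np.unique(l2d[z][l2d[z] > 0])
            ids_3d = [np.unique(joined[z][l2d[z] == i]) for i in ids_2d]
            flat = [int(v[0]) for v in ids_3d]
            assert all(len(v) == 1 for v in ids_3d)
            assert len(set(flat)) == len(flat)

    def test_threshold_monotonicity(self, separated_phantom):
        _spec, _stack, gt_labels, _truth = separated_phantom
        l2d = label_slices(gt_labels > 0)
        counts = [join_labels_3d(l2d, t).max() for t in (0.3, 0.6, 0.9)]
        assert counts[0] <= counts[1] <= counts[2]

    def test_matches_connected_components_oracle(self):
        # footprints carrying a plausible-area rule stitch into exactly the
        # 3D connected components of their union
        min_area = int(np.ceil(0.65 * np.pi * 5.0**2))
        for seed in range(5):
            spec = EmbryoPhantomSpec(n_nuclei=15, shape_voxels=(36, 90, 90),
                                     min_separation_factor=1.5, seed=seed)
            _stack, gt_labels, _truth = generate_nuclear_stack(spec)
            l2d = label_slices(gt_labels > 0, min_area_px=min_area)
            joined = join_labels_3d(l2d, 0.6)
            oracle = measure.label(l2d > 0, connectivity=3)
            assert joined.max() == oracle.max()
            for j in np.unique(joined[joined > 0]):
                assert len(np.unique(oracle[joined == j])) == 1
            for o in np.unique(oracle[oracle > 0]):
                assert len(np.unique(joined[oracle == o])) == 1


class TestExtractNuclei:
    def test_cube_volume_centroid_isotropic(self):
        labels = np.zeros((10, 10, 10), dtype=int)
        labels[2:7, 2:7, 2:7] = 1
        stack = _stack(np.ones((10, 10, 10)))
        table = extract_nuclei(labels, stack)
        assert table.loc[0, "volume_um3"] == pytest.approx(125.0)
        for c in ("z_um", "y_um", "x_um"):
            assert table.loc[0, c] == pytest.approx(4.0)

    def test_anisotropic_volume_doubles(self):
        labels = np.zeros((10, 10, 10), dtype=int)
        labels[2:7, 2:7, 2:7] = 1
        table = extract_nuclei(labels, _stack(np.ones((10, 10, 10)), (2.0, 1.0, 1.0)))
        assert table.loc[0, "volume_um3"] == pytest.approx(250.0)

    def test_uniform_channel_mean_exact(self, separated_phantom):
        _spec, stack, gt_labels, _truth = separated_phantom
        uniform = ImageStack3D(
            np.full(stack.shape_zyx, 7.25), stack.voxel_size_um, ("uniform",)
        )
        table = extract_nuclei(gt_labels, uniform)
        np.testing.assert_array_equal(table["mean_uniform"].to_numpy(), 7.25)

    def test_empty_labels_empty_table(self):
        table = extract_nuclei(np.zeros((5, 5, 5), int), _stack(np.zeros((5, 5, 5))))
        assert len(table) == 0
        assert "volume_um3" in table.columns


class TestFullChain:
    def test_recovery_on_separated_phantom(self, separated_phantom):
        _spec, stack, _gt_labels, truth = separated_phantom
        labels = segment_nuclei(stack)
        table = extract_nuclei(labels, stack)
        n_matched, _ = match_centroids(
            truth[["z_um", "y_um", "x_um"]].to_numpy(),
            table[["z_um", "y_um", "x_um"]].to_numpy(),
            max_dist_um=5.0,
        )
        assert n_matched >= 0.95 * len(truth)
        assert len(table) - n_matched <= 0.05 * len(truth)
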