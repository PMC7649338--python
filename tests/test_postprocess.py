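import numpy as np
import pytest
from skimage.draw import disk

from sunseg.errors import ShapeError
from sunseg.imaging import InstanceLabelMap, RgbPatch
from sunseg.postprocess import (
    OverlapComponents,
    extract_overlap_components,
    make_stage2_input,
    merge_overlaps,
    watershed_instances,
)


def _disk_mask(shape, center, radius):
    m = np.zeros(shape, bool)
    rr, cc = disk(center, radius, shape=shape)
    m[rr, cc] = True
    return m


class TestWatershed:
    def test_empty_mask_gives_no_instances(self):
        assert len(watershed_instances(np.zeros((32, 32), bool))) == 0

    def test_single_disk_is_one_instance_equal_to_disk(self):
        mask = _disk_mask((64, 64), (32, 32), 20)
        ilm = watershed_instances(mask)
        assert len(ilm) == 1
        np.testing.assert_array_equal(ilm.objects[0][1], mask)

    def test_touching_disks_split_into_two(self):
        """Two radius-15 disks with centers 24 px apart form one blob that
        must be separated into exactly two instances covering the blob."""
        mask = _disk_mask((80, 104), (40, 40), 15) | _disk_mask((80, 104), (40, 64), 15)
        ilm = watershed_instances(mask)
        assert len(ilm) == 2
        np.testing.assert_array_equal(ilm.union_mask(), mask)

    def test_instances_partition_the_foreground(self):
        rng = np.random.default_rng(8)
        mask = np.zeros((64, 64), bool)
        for _ in range(4):
            mask |= _disk_mask((64, 64), tuple(rng.integers(10, 54, 2)), int(rng.integers(5, 10)))
        ilm = watershed_instances(mask, min_size=1)
        count = np.zeros((64, 64), np.int32)
        for _, m in ilm.objects:
            count += m
        assert count.max() <= 1  # pairwise disjoint
        np.testing.assert_array_equal(count > 0, mask)

    def test_small_objects_removed(self):
        mask = _disk_mask((32, 32), (16, 16), 2)  # ~13 px < default min_size
        assert len(watershed_instances(mask)) == 0
        assert len(watershed_instances(mask, min_size=5)) == 1


class TestStage2Input:
    def test_channels_and_binary_scaling(self):
        rng = np.random.default_rng(9)
        patch = RgbPatch(rng.integers(0, 256, (16, 16, 3), dtype=np.uint8))
        mask = rng.random((16, 16)) > 0.5
        x = make_stage2_input(patch, mask)
        assert x.shape == (16, 16, 4)
        np.testing.assert_array_equal(x[:, :, :3], patch.pixels)
        assert set(np.unique(x[:, :, 3])) <= {0, 255}

    def test_all_zero_mask_gives_zero_channel(self):
        patch = np.zeros((8, 8, 3), np.uint8)
        assert not make_stage2_input(patch, np.zeros((8, 8), bool))[:, :, 3].any()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeError):
            make_stage2_input(np.zeros((8, 8, 3), np.uint8), np.zeros((9, 9), bool))


class TestOverlapComponents:
    def test_two_separated_squares(self):
        m = np.zeros((20, 20), bool)
        m[1:6, 1:6] = True
        m[10:15, 10:15] = True
        comps = extract_overlap_components(m)
        assert len(comps.components) == 2
        assert sorted(c.sum() for _, c in comps.components) == [25, 25]

    def test_empty_mask(self):
        assert extract_overlap_components(np.zeros((8, 8), bool)).components == []

    def test_diagonal_touch_is_one_component(self):
        m = np.zeros((4, 4), bool)
        m[0, 0] = m[1, 1] = True
        assert len(extract_overlap_components(m).components) == 1


def _simple_instances(shape=(32, 32)):
    a = np.zeros(shape, bool)
    a[4:14, 4:14] = True  # instance 1: 10x10 square
    b = np.zeros(shape, bool)
    b[4:14, 20:30] = True  # instance 2
    return InstanceLabelMap(shape=shape, objects=[(1, a), (2, b)])


def _component(shape, rows, cols):
    m = np.zeros(shape, bool)
    m[rows, cols] = True
    return m


class TestMergeOverlaps:
    def test_component_with_ten_pixel_intersection_is_merged(self):
        inst = _simple_instances()
        comp = _component((32, 32), slice(12, 17), slice(4, 14))  # 2 rows in A (20 px > 10)
        comp_obj = OverlapComponents([(1, comp)])
        out = merge_overlaps(inst, comp_obj)
        grown = dict(out.objects)[1]
        np.testing.assert_array_equal(grown, dict(inst.objects)[1] | comp)

    def test_exactly_ten_pixels_merges_but_nine_does_not(self):
        inst = _simple_instances()
        hit10 = _component((32, 32), slice(13, 14), slice(4, 14))  # 10 px in A
        ten = merge_overlaps(inst, OverlapComponents([(1, hit10 | _component((32, 32), slice(14, 18), slice(4, 14)))]))
        assert dict(ten.objects)[1].sum() > dict(inst.objects)[1].sum()

        hit9 = _component((32, 32), slice(13, 14), slice(4, 13))  # 9 px in A
        nine = merge_overlaps(inst, OverlapComponents([(1, hit9 | _component((32, 32), slice(14, 18), slice(4, 13)))]))
        for lid, m in nine.objects:
            np.testing.assert_array_equal(m, dict(inst.objects)[lid])

    def test_component_joining_two_instances_is_added_to_both(self):
        shape = (32, 32)
        a = _component(shape, slice(4, 14), slice(4, 14))
        b = _component(shape, slice(4, 14), slice(16, 26))
        inst = InstanceLabelMap(shape=shape, objects=[(1, a), (2, b)])
        comp = _component(shape, slice(6, 10), slice(11, 19))  # 12 px in A, 12 px in B
        assert (comp & a).sum() >= 10 and (comp & b).sum() >= 10
        out = merge_overlaps(inst, OverlapComponents([(1, comp)]))
        ma, mb = dict(out.objects)[1], dict(out.objects)[2]
        assert (comp & ~ma).sum() == 0 and (comp & ~mb).sum() == 0
        assert ((ma & mb) & ~comp).sum() == 0 and (ma & mb).sum() == comp.sum()

    def test_unmatched_components_discarded(self):
        inst = _simple_instances()
        far = _component((32, 32), slice(25, 31), slice(0, 6))
        out = merge_overlaps(inst, OverlapComponents([(1, far)]))
        for lid, m in out.objects:
            np.testing.assert_array_equal(m, dict(inst.objects)[lid])

    def test_empty_components_is_identity_and_never_removes_pixels(self):
        inst = _simple_instances()
        out = merge_overlaps(inst, OverlapComponents([]))
        for lid, m in out.objects:
            np.testing.assert_array_equal(m, dict(inst.objects)[lid])

    def test_shape_mismatch_raises(self):
        inst = _simple_instances()
        with pytest.raises(ShapeError):
            merge_overlaps(inst, OverlapComponents([(1, np.ones((8, 8), bool))]))
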