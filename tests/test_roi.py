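"""ROI pipeline tests: Otsu against a brute-force oracle, connectivity
semantics, component suppression, box extraction and composition."""

import numpy as np
import pytest

from aneuprep import (
    BinaryMask3D,
    BoundingBox3D,
    DegenerateHistogramError,
    EmptyRoiError,
    ParameterError,
    ScaleSpaceParams,
    VesselnessResponse,
    Volume3D,
    connected_components,
    crop_to_box,
    extract_roi,
    otsu_threshold_3d,
    suppress_small_components,
    vessel_roi_box,
)


def brute_force_otsu(values: np.ndarray, n_bins: int) -> float:
    """Independent oracle: exhaustive between-class-variance maximization
    over every histogram cut point, in exact rational arithmetic so
    near-ties are resolved without float roundoff."""
    from fractions import Fraction

    counts, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    cc = [Fraction(int(c)) for c in counts]
    ce = [Fraction(c) for c in centers]
    best_var, best_thr = Fraction(-1), centers[0]
    for cut in range(1, n_bins):
        w0, w1 = sum(cc[:cut]), sum(cc[cut:])
        if w0 == 0 or w1 == 0:
            continue
        m0 = sum(c * x for c, x in zip(cc[:cut], ce[:cut])) / w0
        m1 = sum(c * x for c, x in zip(cc[cut:], ce[cut:])) / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_thr = var, centers[cut - 1]
    return best_thr


def _resp(data, spacing=(1, 1, 1)):
    return VesselnessResponse(data=np.asarray(data, dtype=float), spacing=spacing)


class TestOtsu:
    def test_bimodal_900_100_selects_bright_class(self, rng):
        data = np.zeros(1000)
        data[:100] = 1.0
        rng.shuffle(data)
        thr, mask = otsu_threshold_3d(_resp(data.reshape(10, 10, 10)))
        assert mask.n_true == 100
        assert thr == pytest.approx(brute_force_otsu(data, 256))

    def test_small_bimodal_27_voxels(self, rng):
        data = np.full(27, 0.1) + 0.005 * rng.standard_normal(27)
        data[:7] = 0.9 + 0.005 * rng.standard_normal(7)
        thr, mask = otsu_threshold_3d(_resp(data.reshape(3, 3, 3)))
        assert mask.n_true == 7

    def test_constant_volume_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold_3d(_resp(np.full((4, 4, 4), 0.5)))

    def test_matches_brute_force_oracle_on_random_volumes(self, rng):
        for _ in range(30):
            shape = tuple(rng.integers(3, 8, size=3))
            data = rng.random(shape)
            if rng.random() < 0.5:  # bimodal-ish
                data[data > 0.5] += rng.random()
                data = data / data.max()
            thr, _ = otsu_threshold_3d(_resp(data), n_bins=64)
            assert thr == pytest.approx(brute_force_otsu(data.ravel(), 64), abs=1e-12)


class TestConnectedComponents:
    def test_corner_touching_pair_depends_on_connectivity(self):
        data = np.zeros((4, 4, 4), dtype=bool)
        data[1, 1, 1] = data[2, 2, 2] = True
        mask = BinaryMask3D(data=data)
        assert connected_components(mask, 26).n_components == 1
        assert connected_components(mask, 18).n_components == 2
        assert connected_components(mask, 6).n_components == 2

    def test_edge_touching_pair(self):
        data = np.zeros((4, 4, 4), dtype=bool)
        data[1, 1, 1] = data[1, 2, 2] = True
        mask = BinaryMask3D(data=data)
        assert connected_components(mask, 18).n_components == 1
        assert connected_components(mask, 6).n_components == 2

    def test_empty_and_full_masks(self):
        empty = BinaryMask3D(data=np.zeros((3, 3, 3), dtype=bool))
        assert connected_components(empty, 26).n_components == 0
        full = BinaryMask3D(data=np.ones((3, 3, 3), dtype=bool))
        labeled = connected_components(full, 6)
        assert labeled.n_components == 1 and labeled.sizes[1] == 27

    def test_invalid_connectivity_rejected(self):
        mask = BinaryMask3D(data=np.zeros((2, 2, 2), dtype=bool))
        with pytest.raises(ParameterError):
            connected_components(mask, 4)


def _two_blob_mask(sizes=(600, 300)):
    data = np.zeros((30, 30, 30), dtype=bool)
    # blob A: rectangular block of exactly sizes[0] voxels
    a = sizes[0]
    data.flat[:0] = False
    data[:10, :10, :6] = True  # 600
    data[20:25, 20:26, 20:30] = True  # 300
    assert data[:10, :10, :6].sum() == 600 and data[20:25, 20:26, 20:30].sum() == 300
    return BinaryMask3D(data=data)


class TestSuppression:
    def test_default_threshold_removes_small_keeps_large(self):
        labeled = connected_components(_two_blob_mask(), 26)
        assert sorted(labeled.sizes.values()) == [300, 600]
        out = suppress_small_components(labeled, min_voxels=500)
        assert out.n_true == 600

    def test_all_below_min_gives_empty_mask(self):
        labeled = connected_components(_two_blob_mask(), 26)
        out = suppress_small_components(labeled, min_voxels=10_000)
        assert out.n_true == 0

    def test_min_one_is_identity_and_idempotent(self):
        mask = _two_blob_mask()
        labeled = connected_components(mask, 26)
        out = suppress_small_components(labeled, min_voxels=1)
        assert np.array_equal(out.data, mask.data)
        again = suppress_small_components(connected_components(out, 26), min_voxels=500)
        twice = suppress_small_components(connected_components(again, 26), min_voxels=500)
        assert np.array_equal(again.data, twice.data)

    def test_monotone_in_min_voxels(self):
        labeled = connected_components(_two_blob_mask(), 26)
        prev = None
        for mv in (1, 300, 500, 601):
            cur = suppress_small_components(labeled, min_voxels=mv).data
            if prev is not None:
                assert not (cur & ~prev).any()  # raising min never adds voxels
            prev = cur


class TestRoiBox:
    def test_single_voxel_box(self):
        data = np.zeros((10, 10, 10), dtype=bool)
        data[5, 5, 5] = True
        box = vessel_roi_box(BinaryMask3D(data=data), 0)
        assert box.lo == (5, 5, 5) and box.hi == (6, 6, 6)

    def test_extrema_of_two_voxels(self):
        data = np.zeros((15, 15, 15), dtype=bool)
        data[2, 3, 4] = data[10, 12, 8] = True
        box = vessel_roi_box(BinaryMask3D(data=data), 0)
        assert box.lo == (2, 3, 4) and box.hi == (11, 13, 9)

    def test_padding_clamps_at_volume_edge(self):
        data = np.zeros((10, 10, 10), dtype=bool)
        data[0, 0, 0] = True
        box = vessel_roi_box(BinaryMask3D(data=data), 2)
        assert box.lo == (0, 0, 0) and box.hi == (3, 3, 3)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyRoiError):
            vessel_roi_box(BinaryMask3D(data=np.zeros((3, 3, 3), dtype=bool)), 0)


class TestCrop:
    def test_full_volume_box_is_identity(self, random_volume):
        box = BoundingBox3D((0, 0, 0), random_volume.shape)
        out = crop_to_box(random_volume, box)
        assert np.array_equal(out.data, random_volume.data)
        assert out.origin_offset == (0, 0, 0)

    def test_crop_then_reembed_recovers_values(self, random_volume):
        box = BoundingBox3D((2, 1, 3), (7, 8, 6))
        out = crop_to_box(random_volume, box)
        assert out.origin_offset == box.lo
        rebuilt = np.zeros(random_volume.shape)
        sl = tuple(slice(o, o + n) for o, n in zip(out.origin_offset, out.shape))
        rebuilt[sl] = out.data
        assert np.array_equal(rebuilt[box.slices()], random_volume.data[box.slices()])

    def test_paired_crop_preserves_overlap(self, tube_case):
        pred = tube_case.vessel_mask
        box = BoundingBox3D((5, 5, 5), (40, 40, 40))
        before = int((tube_case.image.data[box.slices()] > 0.5).sum())
        img_c = crop_to_box(tube_case.image, box)
        mask_c = crop_to_box(pred, box)
        assert img_c.shape == mask_c.shape
        assert int((img_c.data > 0.5).sum()) == before

    def test_box_outside_volume_rejected(self, random_volume):
        with pytest.raises(ParameterError):
            crop_to_box(random_volume, BoundingBox3D((50, 50, 50), (60, 60, 60)))


class TestExtractRoi:
    params = ScaleSpaceParams(scales_mm=(1.0, 2.0))

    def test_tube_phantom_box_contains_all_vessel_voxels(self, noisy_tube_case):
        res = extract_roi(noisy_tube_case.image, self.params, min_voxels=100)
        inside = np.zeros(noisy_tube_case.image.shape, dtype=bool)
        inside[res.box.slices()] = True
        assert not (noisy_tube_case.vessel_mask.data & ~inside).any()
        assert 0.0 <= res.reduction_fraction < 1.0

    def test_far_noise_blob_excluded_from_mask_and_box(self):
        from aneuprep import Blob, PhantomSpec, Tube, make_case

        shape, spacing = (48, 48, 48), (1.0, 1.0, 1.0)
        tube = Tube(points_mm=((20.0, 20.0, 0.0), (20.0, 20.0, 47.0)), radius_mm=3.0)
        blob = Blob(center_mm=(42.0, 42.0, 42.0), diameter_mm=4.0)
        with_blob = make_case(
            PhantomSpec(shape=shape, spacing=spacing, tubes=(tube,), noise_blobs=(blob,), noise_sigma=0.02, seed=3)
        )
        without = make_case(
            PhantomSpec(shape=shape, spacing=spacing, tubes=(tube,), noise_sigma=0.02, seed=3)
        )
        res_b = extract_roi(with_blob.image, self.params, min_voxels=500)
        res_o = extract_roi(without.image, self.params, min_voxels=500)
        assert res_b.box == res_o.box  # box determined by the tube alone
        blob_region = np.zeros(shape, dtype=bool)
        blob_region[38:47, 38:47, 38:47] = True
        assert not (res_b.vessel_mask.data & blob_region).any()

    def test_vessel_mask_lies_inside_box(self, noisy_tube_case):
        res = extract_roi(noisy_tube_case.image, self.params, min_voxels=100)
        outside = np.ones(noisy_tube_case.image.shape, dtype=bool)
        outside[res.box.slices()] = False
        assert not (res.vessel_mask.data & outside).any()

    def test_strict_mode_raises_when_everything_suppressed(self, noisy_tube_case):
        with pytest.raises(EmptyRoiError):
            extract_roi(noisy_tube_case.image, self.params, min_voxels=10**6, strict=True)

    def test_fallback_keeps_largest_component(self, noisy_tube_case):
        res = extract_roi(noisy_tube_case.image, self.params, min_voxels=10**6, strict=False)
        assert res.vessel_mask.n_true == max(res.component_sizes.values())

    def test_cube_option_gives_equal_sides(self, noisy_tube_case):
        res = extract_roi(noisy_tube_case.image, self.params, min_voxels=100, cube=True)
        assert len(set(res.box.shape)) == 1
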