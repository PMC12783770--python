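import numpy as np
import pytest

from conftest import make_volume
from oracles import bruteforce_3d_labels, partitions_equal

from neuritelab.phantom import GroundTruth
from neuritelab.segmentation import (
    Contour,
    SegParams,
    assign_layer,
    calibrate_threshold,
    evaluate_fpr,
    filter_by_extent,
    link_contours,
    merge_objects,
    objects_to_label_volume,
    segment_volume,
    threshold_section,
)
from neuritelab.volume import LayerAnnotation

PERMISSIVE = SegParams(
    intensity_threshold=128, min_contour_area=1, min_overlap=1, min_sections=1
)


def noise_volume(seed, shape=(64, 64, 64)):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.2, 0.6)
    mask = rng.random(shape) < p
    return make_volume(mask), mask


class TestThresholdSection:
    def test_no_subthreshold_pixels(self):
        img = np.full((32, 32), 200, dtype=np.uint8)
        assert threshold_section(img, SegParams(intensity_threshold=100)) == []

    def test_single_block(self):
        img = np.full((32, 32), 200, dtype=np.uint8)
        img[5:15, 5:15] = 20
        contours = threshold_section(
            img, SegParams(intensity_threshold=100, min_contour_area=50)
        )
        assert len(contours) == 1
        assert contours[0].area_px == 100

    def test_min_area_filters_small_blobs(self):
        # three dark blobs of area 30, 60 and 120 px
        img = np.full((64, 64), 200, dtype=np.uint8)
        img[1:6, 1:7] = 20  # 30 px
        img[10:16, 10:20] = 20  # 60 px
        img[30:40, 30:42] = 20  # 120 px
        contours = threshold_section(
            img, SegParams(intensity_threshold=100, min_contour_area=50)
        )
        assert sorted(c.area_px for c in contours) == [60, 120]

    def test_threshold_is_strict(self):
        img = np.full((8, 8), 100, dtype=np.uint8)
        assert threshold_section(img, SegParams(intensity_threshold=100, min_contour_area=1)) == []

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            threshold_section(np.empty((0, 0), dtype=np.uint8), PERMISSIVE)

    def test_physical_contour_area(self):
        c = Contour(section=0, pixels=np.argwhere(np.ones((10, 10), dtype=bool)))
        assert c.area_um2((100.0, 200.0, 50.0)) == pytest.approx(100 * 0.1 * 0.2)


def _square(z, r0, c0, size=5):
    rows, cols = np.meshgrid(range(r0, r0 + size), range(c0, c0 + size), indexing="ij")
    return Contour(section=z, pixels=np.column_stack([rows.ravel(), cols.ravel()]))


class TestLinkContours:
    def test_single_contour(self):
        objs = link_contours({3: [_square(3, 0, 0)]}, PERMISSIVE)
        assert len(objs) == 1 and objs[0].z_extent == 1

    def test_perfect_column(self):
        contours = {z: [_square(z, 2, 2)] for z in range(20)}
        objs = link_contours(contours, PERMISSIVE)
        assert len(objs) == 1
        assert objs[0].z_extent == 20

    def test_projection_crossing_without_adjacency_stays_split(self):
        # same (row, col) footprint, but a one-section gap at z=10
        contours = {z: [_square(z, 2, 2)] for z in list(range(10)) + list(range(11, 20))}
        objs = link_contours(contours, PERMISSIVE)
        assert len(objs) == 2
        # agrees with the brute-force 3D labeling of the same mask
        mask = np.zeros((20, 10, 10), dtype=bool)
        for z in contours:
            mask[z, 2:7, 2:7] = True
        mine = objects_to_label_volume(objs, mask.shape)
        assert partitions_equal(mine, bruteforce_3d_labels(mask))

    def test_min_overlap_splits_weak_links(self):
        # two 5x5 squares sharing exactly one corner pixel between sections
        contours = {0: [_square(0, 0, 0)], 1: [_square(1, 4, 4)]}
        assert len(link_contours(contours, PERMISSIVE)) == 1
        strict = SegParams(
            intensity_threshold=128, min_contour_area=1, min_overlap=2, min_sections=1
        )
        assert len(link_contours(contours, strict)) == 2

    def test_duplicate_pixel_claim_rejected(self):
        contours = {0: [_square(0, 0, 0), _square(0, 2, 2)]}
        with pytest.raises(ValueError, match="duplicate"):
            link_contours(contours, PERMISSIVE)

    def test_contour_order_does_not_change_partition(self):
        vol, mask = noise_volume(5, shape=(16, 32, 32))
        contours = {}
        for z in range(vol.n_sections):
            cs = threshold_section(vol.data[z], PERMISSIVE)
            if cs:
                contours[z] = cs
        objs = link_contours(contours, PERMISSIVE)
        shuffled = {
            z: list(reversed(contours[z])) for z in sorted(contours, reverse=True)
        }
        objs2 = link_contours(shuffled, PERMISSIVE)
        a = objects_to_label_volume(objs, mask.shape)
        b = objects_to_label_volume(objs2, mask.shape)
        assert partitions_equal(a, b)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_noise(self, seed):
        vol, mask = noise_volume(seed, shape=(32, 32, 32))
        objs, _ = segment_volume(vol, PERMISSIVE)
        mine = objects_to_label_volume(objs, mask.shape)
        assert partitions_equal(mine, bruteforce_3d_labels(mask))


class TestFilterAndMerge:
    def _object_with_sections(self, sections, oid=1):
        return link_contours({z: [_square(z, 0, 0)] for z in sections}, PERMISSIVE)[0]

    def test_fifteen_section_rule_boundary(self):
        params = SegParams()
        short = self._object_with_sections(range(14))
        kept = self._object_with_sections(range(15))
        assert filter_by_extent([short], params) == []
        assert filter_by_extent([kept], params) == [kept]

    def test_empty_input_allowed(self):
        assert filter_by_extent([], SegParams()) == []

    def test_extent_rule_on_mixed_population(self):
        objs = [self._object_with_sections(range(n)) for n in (3, 14, 15, 120)]
        kept = filter_by_extent(objs, SegParams())
        assert [o.z_extent for o in kept] == [15, 120]

    def test_merge_identity(self):
        obj = self._object_with_sections(range(5))
        merged = merge_objects([obj], [obj.object_id])
        assert merged.z_extent == 5
        assert merged.n_voxels == obj.n_voxels

    def test_merge_disjoint_section_ranges(self):
        a = link_contours({z: [_square(z, 0, 0)] for z in range(0, 20)}, PERMISSIVE)[0]
        b = link_contours({z: [_square(z, 0, 0)] for z in range(30, 50)}, PERMISSIVE)[0]
        b.object_id = 2
        merged = merge_objects([a, b], [1, 2])
        assert merged.z_extent == 40
        assert merged.n_voxels == a.n_voxels + b.n_voxels
        assert merged.merged_from == (1, 2)

    def test_merge_unknown_id_rejected(self):
        obj = self._object_with_sections(range(5))
        with pytest.raises(KeyError):
            merge_objects([obj], [1, 99])


class TestAssignLayer:
    def _obj(self, sections):
        return link_contours({z: [_square(z, 0, 0)] for z in sections}, PERMISSIVE)[0]

    def test_object_within_one_layer(self, small_layers):
        assert assign_layer(self._obj(range(12, 18)), small_layers) == "IPL"

    def test_boundary_straddle_majority_wins(self, small_layers):
        # sections 0..11: median section index 5 -> GCL
        assert assign_layer(self._obj(range(12)), small_layers) == "GCL"

    def test_even_straddle_breaks_to_lower_z(self, small_layers):
        # sections 8,9,10,11: lower middle section 9 -> GCL
        assert assign_layer(self._obj([8, 9, 10, 11]), small_layers) == "GCL"

    def test_empty_object_rejected(self, small_layers):
        from neuritelab.segmentation import SegmentedObject

        with pytest.raises(ValueError):
            assign_layer(SegmentedObject(object_id=1), small_layers)


class TestEvaluateFpr:
    def _scene(self, n_tp, n_fp, layers):
        """n_tp+n_fp single-contour objects at z=5 (GCL); the first n_tp
        sit on dendrite truth voxels."""
        labels = np.zeros((30, 40, 60), dtype=np.uint16)
        contours = {}
        objs = []
        col = 0
        for i in range(n_tp + n_fp):
            c = _square(5, 2, col, size=3)
            objs.append(c)
            if i < n_tp:
                labels[5, 2:5, col : col + 3] = 1
            col += 5
        contours[5] = objs
        truth = GroundTruth(
            labels=labels, class_map={1: "dendrite_strong"}, parent_map={1: 1}
        )
        objects = link_contours(contours, PERMISSIVE)
        return objects, truth

    def test_all_matched_gives_zero_fpr(self, small_layers):
        objects, truth = self._scene(4, 0, small_layers)
        report = evaluate_fpr(objects, truth, small_layers)
        assert report.fpr("GCL") == 0.0

    def test_seven_of_ten_false(self, small_layers):
        objects, truth = self._scene(3, 7, small_layers)
        report = evaluate_fpr(objects, truth, small_layers)
        assert report.per_layer["GCL"]["n_objects"] == 10
        assert report.fpr("GCL") == pytest.approx(0.7)
        assert report.per_layer["IPL"]["empty"]

    def test_geometry_mismatch_rejected(self, small_layers):
        objects, truth = self._scene(1, 0, small_layers)
        truth_small = GroundTruth(
            labels=truth.labels[:, :3, :3].copy(),
            class_map=truth.class_map,
            parent_map=truth.parent_map,
        )
        with pytest.raises(ValueError, match="geometry"):
            evaluate_fpr(objects, truth_small, small_layers)


class TestSegmentVolume:
    def test_zero_threshold_finds_nothing(self):
        vol, _ = noise_volume(0, shape=(16, 16, 16))
        params = SegParams(intensity_threshold=1, min_contour_area=1, min_sections=1)
        objs, log = segment_volume(vol, params)
        assert objs == [] and log["n_contours"] == 0

    def test_object_count_monotone_in_filters(self):
        vol, _ = noise_volume(7, shape=(32, 32, 32))
        counts = []
        for min_sections in (1, 3, 5, 10):
            params = SegParams(
                intensity_threshold=128,
                min_contour_area=1,
                min_overlap=1,
                min_sections=min_sections,
            )
            counts.append(len(segment_volume(vol, params)[0]))
        assert counts == sorted(counts, reverse=True)
        # raising min_contour_area can only drop contours
        n_contours = []
        # raising min_overlap removes links, so the pre-filter partition
        # refines: object count is non-decreasing
        n_objects_by_overlap = []
        for v in (1, 2, 4):
            log_area = segment_volume(
                vol,
                SegParams(
                    intensity_threshold=128, min_contour_area=v, min_overlap=1, min_sections=1
                ),
            )[1]
            n_contours.append(log_area["n_contours"])
            log_ov = segment_volume(
                vol,
                SegParams(
                    intensity_threshold=128, min_contour_area=1, min_overlap=v, min_sections=1
                ),
            )[1]
            n_objects_by_overlap.append(log_ov["n_objects_prefilter"])
        assert n_contours == sorted(n_contours, reverse=True)
        assert n_objects_by_overlap == sorted(n_objects_by_overlap)

    def test_run_log_bookkeeping(self):
        vol, _ = noise_volume(3, shape=(24, 24, 24))
        params = SegParams(
            intensity_threshold=128, min_contour_area=1, min_overlap=1, min_sections=3
        )
        objs, log = segment_volume(vol, params)
        assert log["n_objects_postfilter"] == len(objs)
        assert log["n_objects_prefilter"] >= log["n_objects_postfilter"]
        assert log["n_contours"] >= log["n_objects_prefilter"]


def test_threshold_calibration_from_seed_pixels(clean_phantom):
    cfg, vol, truth = clean_phantom
    dend_id = truth.ids_of_class("dendrite_strong")[0]
    pix = truth.voxel_coords(dend_id)[:50]
    thr = calibrate_threshold(vol, pix)
    assert thr == pytest.approx(cfg.intensity.strong_mean, abs=1)
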