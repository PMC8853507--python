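"""Annotation workflows, mask algebra, splits, and augmentation."""

import numpy as np
import pytest

from ulcerlab import (
    BoundaryAnnotation,
    LabelMasks,
    PolygonShape,
    RegionAnnotation,
    SlicParams,
    SuperpixelSegmentation,
    TissueClass,
    augment,
    combine_classes,
    compose_ulceration,
    from_regions,
    rasterize,
    split_dataset,
    threefold_cv,
    WoundImage,
)
from ulcerlab.annotation import (
    polygon_mask,
    read_labelme,
    read_region_csv,
    write_labelme,
    write_region_csv,
    read_label_png,
    write_label_png,
)


def square(x0, y0, side):
    return [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)]


def quad_segmentation(shape=(8, 8)):
    """Four quadrant superpixels on a small raster."""
    labels = np.zeros(shape, dtype=np.int32)
    labels[: shape[0] // 2, shape[1] // 2 :] = 1
    labels[shape[0] // 2 :, : shape[1] // 2] = 2
    labels[shape[0] // 2 :, shape[1] // 2 :] = 3
    return SuperpixelSegmentation(labels=labels, k_actual=4, params=SlicParams(k=4), s=4.0)


class TestPolygonFill:
    def test_axis_aligned_square_pixel_count(self):
        assert polygon_mask(square(0, 0, 10), (20, 20)).sum() == 100

    def test_abutting_squares_partition(self):
        a = polygon_mask(square(0, 0, 10), (10, 20))
        b = polygon_mask(square(10, 0, 10), (10, 20))
        assert not (a & b).any()
        assert (a | b).sum() == 200

    def test_even_odd_on_self_intersecting_bowtie(self):
        # bowtie: the crossing point belongs to neither lobe under even-odd
        m = polygon_mask([(0, 0), (10, 10), (10, 0), (0, 10)], (10, 10))
        loop = np.zeros((10, 10), bool)  # per-pixel crossing-parity oracle
        for r in range(10):
            for c in range(10):
                # lobes of the bowtie: above both diagonals or below both
                loop[r, c] = (c > r and c > 9.99 - r) or (c < r and c < 9.99 - r)
        # interior agreement away from the diagonal edges
        assert (m == loop)[np.abs(np.arange(10)[:, None] - np.arange(10)) > 1].all()


class TestRasterize:
    def test_bare_ulceration_is_all_undefined(self):
        ann = BoundaryAnnotation(
            "x", [PolygonShape(TissueClass.ULCERATION, square(2, 2, 10))]
        )
        masks = rasterize(ann, (20, 20))
        assert masks.ulceration.sum() == 100
        assert masks.undefined.sum() == 100
        assert not masks.granulation.any()

    def test_no_polygons(self):
        masks = rasterize(BoundaryAnnotation("x", []), (8, 8))
        assert not masks.ulceration.any() and not masks.re_ep.any()

    def test_inner_tissue_halves_the_residual(self):
        ann = BoundaryAnnotation(
            "x",
            [
                PolygonShape(TissueClass.ULCERATION, square(0, 0, 10)),
                PolygonShape(
                    TissueClass.GRANULATION, [(0, 0), (10, 0), (10, 5), (0, 5)]
                ),
            ],
        )
        masks = rasterize(ann, (20, 20))
        assert masks.granulation.sum() == 50
        assert masks.undefined.sum() == 50
        assert masks.ulceration.sum() == 100

    def test_later_polygon_overrides_earlier(self):
        ann = BoundaryAnnotation(
            "x",
            [
                PolygonShape(TissueClass.ULCERATION, square(0, 0, 10)),
                PolygonShape(TissueClass.SLOUGH, square(0, 0, 10)),
                PolygonShape(TissueClass.GRANULATION, square(0, 0, 4)),
            ],
        )
        masks = rasterize(ann, (12, 12))
        assert masks.granulation.sum() == 16
        assert masks.slough.sum() == 84

    def test_re_ep_clipped_to_wound_complement(self):
        ann = BoundaryAnnotation(
            "x",
            [
                PolygonShape(TissueClass.ULCERATION, square(0, 0, 8)),
                PolygonShape(TissueClass.RE_EP, square(4, 0, 8)),
            ],
        )
        masks = rasterize(ann, (16, 16))
        assert not (masks.re_ep & masks.ulceration).any()
        assert masks.re_ep.sum() == 32  # the half outside the wound

    def test_ulceration_must_come_first(self):
        with pytest.raises(ValueError):
            BoundaryAnnotation(
                "x",
                [
                    PolygonShape(TissueClass.GRANULATION, square(0, 0, 4)),
                    PolygonShape(TissueClass.ULCERATION, square(0, 0, 8)),
                ],
            )

    def test_self_intersecting_polygon_warns(self):
        ann = BoundaryAnnotation(
            "x",
            [PolygonShape(TissueClass.ULCERATION, [(0, 0), (8, 8), (8, 0), (0, 8)])],
        )
        with pytest.warns(UserWarning, match="self-intersecting"):
            rasterize(ann, (8, 8))


class TestComposeUlceration:
    def test_empty(self):
        assert not compose_ulceration(LabelMasks.empty((4, 4))).any()

    def test_disjoint_union_counts(self):
        m = LabelMasks.empty((10, 10))
        m.granulation[:3] = True
        m.eschar[3:10] = True
        assert compose_ulceration(m).sum() == 100

    def test_matches_per_pixel_oracle(self, rng):
        masks = LabelMasks.empty((8, 8))
        order = rng.permutation(64)
        flat = np.zeros(64, bool)
        for name, ids in zip(
            ("granulation", "slough", "eschar"), np.array_split(order[:40], 3)
        ):
            arr = np.zeros(64, bool)
            arr[ids] = True
            setattr(masks, name, arr.reshape(8, 8))
            flat |= arr
        u = compose_ulceration(masks)
        for i in range(64):  # per-pixel loop oracle
            assert u.flat[i] == flat[i]

    def test_overlap_rejected(self):
        m = LabelMasks.empty((4, 4))
        overlap = np.ones((4, 4), bool)
        m.granulation = overlap
        m.slough = overlap.copy()
        with pytest.raises(ValueError):
            compose_ulceration(m)


class TestFromRegions:
    def test_all_granulation(self):
        seg = quad_segmentation()
        ann = RegionAnnotation("x", seg, {i: TissueClass.GRANULATION for i in range(4)})
        masks = from_regions(ann)
        assert masks.granulation.all() and masks.ulceration.all()

    def test_mixed_classes_match_footprints(self):
        seg = quad_segmentation()
        ann = RegionAnnotation(
            "x",
            seg,
            {0: TissueClass.GRANULATION, 1: TissueClass.SLOUGH, 2: TissueClass.ESCHAR},
        )
        masks = from_regions(ann)
        assert (masks.granulation == (seg.labels == 0)).all()
        assert (masks.slough == (seg.labels == 1)).all()
        assert (masks.eschar == (seg.labels == 2)).all()
        assert not masks.ulceration[seg.labels == 3].any()

    def test_empty_mapping(self):
        masks = from_regions(RegionAnnotation("x", quad_segmentation(), {}))
        assert not masks.ulceration.any()

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError):
            RegionAnnotation("x", quad_segmentation(), {9: TissueClass.GRANULATION})

    def test_no_pixel_leakage(self):
        # footprint identity: region pixels and only region pixels are classed
        seg = quad_segmentation((10, 10))
        ann = RegionAnnotation("x", seg, {2: TissueClass.ESCHAR})
        masks = from_regions(ann)
        assert (masks.eschar == (seg.labels == 2)).all()


class TestCombineClasses:
    def test_model1_two_classes(self):
        m = LabelMasks.empty((6, 6))
        m.undefined[1:4, 1:4] = True
        cat = combine_classes(m, "model1")
        assert set(np.unique(cat)) == {0, 1}
        assert (cat == 1).sum() == compose_ulceration(m).sum()

    def test_model2_labels_present(self, flat_scene):
        _, masks, _ = flat_scene
        cat = combine_classes(masks, "model2")
        assert {1, 2, 3, 4} <= set(np.unique(cat))

    @pytest.mark.parametrize("mode", ["model1", "model2"])
    def test_partition(self, mode, flat_scene):
        _, masks, _ = flat_scene
        cat = combine_classes(masks, mode)
        n_classes = 3 if mode == "model1" else 5
        assert cat.max() < n_classes  # every pixel exactly one class

    def test_unknown_mode(self, flat_scene):
        with pytest.raises(ValueError):
            combine_classes(flat_scene[1], "model3")


class TestSplits:
    def test_ratio_100(self):
        train, val, test = split_dataset(list(range(100)), seed=0)
        assert (len(train), len(val), len(test)) == (70, 20, 10)
        assert sorted(train + val + test) == list(range(100))

    def test_ratio_10(self):
        train, val, test = split_dataset(list(range(10)), seed=3)
        assert (len(train), len(val), len(test)) == (7, 2, 1)

    def test_deterministic(self):
        ids = [f"im{i}" for i in range(37)]
        assert split_dataset(ids, seed=9) == split_dataset(ids, seed=9)
        assert split_dataset(ids, seed=9) != split_dataset(ids, seed=10)

    def test_threefold_partition(self):
        ids = list(range(90))
        folds = threefold_cv(ids, seed=1)
        assert len(folds) == 3
        assert sorted(sum(folds, [])) == ids
        assert threefold_cv(ids, seed=1) == threefold_cv(ids, seed=1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([], seed=0)
        with pytest.raises(ValueError):
            threefold_cv([], seed=0)


class TestAugment:
    def test_identity_spec(self, noisy_scene):
        image, masks, _ = noisy_scene
        img2, masks2 = augment(image, masks, [], seed=0)
        assert (img2.pixels == image.pixels).all()
        assert (masks2.to_categorical() == masks.to_categorical()).all()

    def test_rot90_preserves_counts(self, noisy_scene):
        image, masks, _ = noisy_scene
        _, masks2 = augment(image, masks, [{"op": "rotate", "angle": 90}], seed=0)
        assert masks2.pixel_counts() == masks.pixel_counts()

    def test_photometric_leaves_masks(self, noisy_scene):
        image, masks, _ = noisy_scene
        spec = [{"op": "gaussian_blur", "sigma": 1.0}, {"op": "contrast", "gain": 1.1}]
        img2, masks2 = augment(image, masks, spec, seed=0)
        assert (masks2.to_categorical() == masks.to_categorical()).all()
        assert (img2.pixels != image.pixels).any()

    def test_invariants_survive_geometric_chain(self, noisy_scene):
        image, masks, _ = noisy_scene
        spec = [
            {"op": "rotate", "angle": 17.0},
            {"op": "shift", "dy": 3.0, "dx": -4.0},
            {"op": "scale", "factor": 1.1},
        ]
        _, masks2 = augment(image, masks, spec, seed=0)
        masks2.validate()  # disjointness/containment must survive

    def test_unsupported_op(self, noisy_scene):
        image, masks, _ = noisy_scene
        with pytest.raises(ValueError):
            augment(image, masks, [{"op": "shear"}], seed=0)


class TestSerialization:
    def test_labelme_round_trip(self, tmp_path):
        ann = BoundaryAnnotation(
            "img7",
            [
                PolygonShape(TissueClass.ULCERATION, square(1, 1, 8)),
                PolygonShape(TissueClass.GRANULATION, square(2, 2, 3)),
                PolygonShape(TissueClass.RE_EP, square(0, 0, 2)),
            ],
        )
        write_labelme(ann, tmp_path / "img7.json", shape=(16, 16))
        back = read_labelme(tmp_path / "img7.json")
        assert back == ann

    def test_region_csv_round_trip(self, tmp_path):
        seg = quad_segmentation()
        ann = RegionAnnotation(
            "r", seg, {0: TissueClass.GRANULATION, 3: TissueClass.SLOUGH}
        )
        write_region_csv(ann, tmp_path / "r.csv")
        back = read_region_csv(tmp_path / "r.csv", seg)
        assert back.assignment == ann.assignment

    def test_label_png_round_trip(self, tmp_path, flat_scene):
        _, masks, _ = flat_scene
        cat = masks.to_categorical()
        write_label_png(cat, tmp_path / "m.png")
        assert (read_label_png(tmp_path / "m.png") == cat).all()


def test_label_masks_invariant_enforced():
    bad = np.ones((4, 4), bool)
    with pytest.raises(ValueError):
        LabelMasks(bad, bad.copy(), np.zeros((4, 4), bool), np.zeros((4, 4), bool),
                   np.zeros((4, 4), bool))
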