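"""Dataset I/O, letterbox geometry, Mosaic composition and anchor clustering."""

import numpy as np
import pytest

from polypdet.data import (AnchorSet, LabeledImage, MosaicSpec, kmeans_anchors,
                           letterbox, mosaic, read_dataset, read_label_file,
                           split_dataset, unletterbox_box, write_label_file)
from polypdet.loss import Box


def _img(rng, h, w, color=None):
    if color is not None:
        return np.full((h, w, 3), color, dtype=np.uint8)
    return rng.integers(0, 255, (h, w, 3), dtype=np.uint8)


class TestLabelIO:
    def test_norm_row_converts_to_expected_pixel_box(self):
        boxes, classes = None, None
        b = Box("cxcywh_norm", (0.5, 0.5, 0.2, 0.1))
        x1, y1, x2, y2 = b.to_xyxy(640).coords
        assert (x1, y1, x2, y2) == (256, 288, 384, 352)

    def test_roundtrip_six_decimals(self, rng, tmp_path):
        boxes = [Box("cxcywh_norm", tuple(v)) for v in
                 [(0.512345, 0.25, 0.1, 0.09), (0.9, 0.9, 0.123456, 0.05)]]
        path = tmp_path / "l.txt"
        write_label_file(path, boxes, [0, 0])
        back, classes = read_label_file(path)
        for orig, rb in zip(boxes, back):
            assert np.allclose(orig.coords, rb.coords, atol=1e-6)
        assert classes == [0, 0]

    def test_empty_label_file_is_fine(self, tmp_path):
        path = tmp_path / "e.txt"
        path.write_text("")
        boxes, classes = read_label_file(path)
        assert boxes == [] and classes == []

    def test_malformed_row_names_file_and_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 0.5 0.5 0.2\n")
        with pytest.raises(ValueError, match="bad.txt:1"):
            read_label_file(path)

    def test_out_of_range_coordinate_rejected(self, tmp_path):
        path = tmp_path / "oob.txt"
        path.write_text("0 1.5 0.5 0.2 0.2\n")
        with pytest.raises(ValueError, match="outside"):
            read_label_file(path)

    def test_read_dataset_missing_label_warns_and_yields_empty(self, rng, tmp_path, caplog):
        import PIL.Image
        (tmp_path / "images").mkdir()
        (tmp_path / "labels").mkdir()
        PIL.Image.fromarray(_img(rng, 32, 32)).save(tmp_path / "images" / "a.png")
        import logging
        with caplog.at_level(logging.WARNING, logger="polypdet"):
            items = read_dataset(tmp_path / "images", tmp_path / "labels")
        assert len(items) == 1 and items[0].boxes == []
        assert any("no label file" in r.message for r in caplog.records)


class TestLetterbox:
    def test_square_input_is_identity_transform(self, rng):
        item = LabeledImage(_img(rng, 640, 640), [Box("cxcywh_norm", (0.5, 0.5, 0.2, 0.2))], [0])
        out = letterbox(item, 640)
        scale, px, py = out.letterbox_params
        assert (scale, px, py) == (1.0, 0.0, 0.0)
        assert np.array_equal(out.image, item.image)

    def test_tall_pad_shifts_centers(self, rng):
        """A 320x640 image at target 640 keeps scale 1 and pads 160 above and
        below; normalized y centers shift by 160/640 after renormalization."""
        item = LabeledImage(_img(rng, 320, 640), [Box("cxcywh_norm", (0.5, 0.5, 0.2, 0.4))], [0])
        out = letterbox(item, 640)
        scale, px, py = out.letterbox_params
        assert scale == 1.0 and px == 0.0 and py == 160.0
        cx, cy, w, h = out.boxes[0].coords
        assert cy == pytest.approx((0.5 * 320 + 160) / 640)
        assert h == pytest.approx(0.4 * 320 / 640)

    def test_inverse_mapping_recovers_source_coords(self, rng):
        item = LabeledImage(_img(rng, 200, 333), [], [])
        out = letterbox(item, 640)
        src = (50.0, 30.0, 120.0, 90.0)
        scale, px, py = out.letterbox_params
        mapped = (src[0] * scale + px, src[1] * scale + py,
                  src[2] * scale + px, src[3] * scale + py)
        back = unletterbox_box(mapped, out.letterbox_params, (200, 333))
        assert np.allclose(back, src, atol=1e-4)

    def test_non_multiple_target_rejected(self, rng):
        with pytest.raises(ValueError):
            letterbox(LabeledImage(_img(rng, 64, 64), [], []), 100)


class TestMosaic:
    def _uniform_items(self, colors, size=64):
        out = []
        for c in colors:
            img = np.full((size, size, 3), c, dtype=np.uint8)
            out.append(LabeledImage(img, [Box("cxcywh_norm", (0.5, 0.5, 0.5, 0.5))], [0]))
        return out

    def test_quadrants_hold_one_source_color_each(self):
        colors = [(250, 0, 0), (0, 250, 0), (0, 0, 250), (250, 250, 0)]
        items = self._uniform_items(colors, size=128)
        spec = MosaicSpec(canvas=128, center_jitter=0.0, rotation_deg=0.0,
                          scale_range=(2.0, 2.0), shear_deg=0.0, rng_seed=0)
        out = mosaic(items, spec)
        s = 128
        probes = {(s // 4, s // 4): colors[0], (s // 4, 3 * s // 4): colors[1],
                  (3 * s // 4, s // 4): colors[2], (3 * s // 4, 3 * s // 4): colors[3]}
        for (y, x), c in probes.items():
            assert tuple(out.image[y, x]) == c

    def test_box_count_never_increases(self, rng):
        items = []
        for i in range(4):
            boxes = [Box("cxcywh_norm", tuple(v)) for v in
                     [(0.3, 0.3, 0.2, 0.2), (0.7, 0.6, 0.15, 0.25)]]
            items.append(LabeledImage(_img(rng, 96, 96), boxes, [0, 0]))
        out = mosaic(items, MosaicSpec(canvas=192, rng_seed=3))
        assert len(out.boxes) <= 8
        for b in out.boxes:
            assert all(0.0 <= v <= 1.0 for v in b.coords)
            assert b.width > 0 and b.height > 0

    def test_same_seed_bit_identical(self, rng):
        items = [LabeledImage(_img(rng, 64, 64),
                              [Box("cxcywh_norm", (0.5, 0.5, 0.3, 0.3))], [0])
                 for _ in range(4)]
        a = mosaic(items, MosaicSpec(canvas=128, rng_seed=7))
        b = mosaic(items, MosaicSpec(canvas=128, rng_seed=7))
        assert np.array_equal(a.image, b.image)
        assert [x.coords for x in a.boxes] == [x.coords for x in b.boxes]

    def test_wrong_input_count_rejected(self, rng):
        items = [LabeledImage(_img(rng, 32, 32), [], [])] * 3
        with pytest.raises(ValueError, match="four"):
            mosaic(items, MosaicSpec(canvas=64))

    def test_label_consistency_under_pure_scaling(self):
        """Transforming the image then its boxes equals transforming annotated
        corner points directly: with a known uniform scale and no rotation the
        surviving box spans exactly the scaled corners (clipped)."""
        size, canvas = 64, 128
        img = np.zeros((size, size, 3), dtype=np.uint8)
        item = LabeledImage(img, [Box("cxcywh_norm", (0.5, 0.5, 0.25, 0.25))], [0])
        spec = MosaicSpec(canvas=canvas, center_jitter=0.0, rotation_deg=0.0,
                          scale_range=(1.0, 1.0), shear_deg=0.0, rng_seed=0)
        out = mosaic([item] * 4, spec)
        # quadrant centres hold each image centre; the box is centred there
        for b, (qy, qx) in zip(out.boxes, ((0.25, 0.25), (0.25, 0.75),
                                           (0.75, 0.25), (0.75, 0.75))):
            cx, cy, w, h = b.coords
            assert (cx, cy) == pytest.approx((qx, qy), abs=0.02)
            assert (w, h) == pytest.approx((0.25 * size / canvas,) * 2, abs=1e-6)


class TestAnchors:
    def test_degenerate_single_cluster(self):
        wh = np.tile([[10.0, 20.0]], (100, 1))
        centers = kmeans_anchors(wh, k=1, seed=0)
        assert np.allclose(centers, [[10, 20]])

    def test_planted_clusters_recovered_within_two_percent(self):
        """Nine tight clusters with separation far above spread."""
        means = np.array([[8, 10], [16, 12], [24, 30], [40, 28], [52, 60],
                          [80, 50], [100, 110], [150, 90], [200, 210]], dtype=float)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            wh = np.concatenate([m + rng.normal(0, 0.3, (40, 2)) for m in means])
            anchors = kmeans_anchors(wh, k=9, seed=seed)
            got = np.asarray(anchors.pairs)
            order = np.argsort(means.prod(axis=1))
            assert np.all(np.abs(got - means[order]) / means[order] < 0.02)

    def test_fitted_anchors_beat_random_anchors(self, rng):
        wh = np.exp(rng.normal(3.0, 0.8, (200, 2)))
        fitted = np.asarray(kmeans_anchors(wh, k=9, seed=0).pairs)
        random_anchors = np.exp(rng.normal(3.0, 0.8, (9, 2)))

        def mean_best_iou(anchors):
            inter = np.minimum(wh[:, None, 0], anchors[None, :, 0]) * \
                np.minimum(wh[:, None, 1], anchors[None, :, 1])
            union = wh.prod(1)[:, None] + anchors.prod(1)[None, :] - inter
            return (inter / union).max(axis=1).mean()

        assert mean_best_iou(fitted) >= mean_best_iou(random_anchors)

    def test_too_few_boxes_advises_fallback(self):
        with pytest.raises(ValueError, match="default anchor"):
            kmeans_anchors(np.ones((5, 2)), k=9, seed=0)

    def test_anchor_set_sorted_and_grouped(self):
        pairs = tuple((float(10 - i), float(10 - i)) for i in range(9))
        a = AnchorSet(pairs)
        areas = [w * h for w, h in a.pairs]
        assert areas == sorted(areas)
        assert a.grouped().shape == (3, 3, 2)


class TestSplit:
    def test_eight_one_one_with_twenty(self):
        splits = split_dataset([f"i{k}" for k in range(20)], seed=0)
        assert (len(splits["train"]), len(splits["val"]), len(splits["test"])) == (16, 2, 2)

    def test_membership_reproducible_and_disjoint(self):
        ids = [f"img{k}" for k in range(37)]
        a = split_dataset(ids, seed=5)
        b = split_dataset(ids, seed=5)
        assert a == b
        all_ids = a["train"] + a["val"] + a["test"]
        assert sorted(all_ids) == sorted(ids)

    def test_different_seed_changes_membership(self):
        ids = [f"img{k}" for k in range(30)]
        assert split_dataset(ids, seed=1) != split_dataset(ids, seed=2)
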