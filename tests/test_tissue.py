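"""Tile grid, labelmap cleanup, annotation polygons and the tile classifier."""

import numpy as np
import pandas as pd
import pytest

from pdl1score.stain import ODImage
from pdl1score.tissue import (TileClassifier, TileGrid, classify_tiles,
                              clean_labelmap, confusion_matrix,
                              labelmap_to_annotation, tile_image,
                              tumor_labelmap)


def _od(size_um, mpp=1.0):
    n = int(size_um / mpp)
    z = np.zeros((n, n))
    return ODImage(od_h=z, od_d=z.copy(), mpp=mpp, background_rgb=(255, 255, 255))


class TestTileImage:
    @pytest.mark.parametrize("size,tile,stride,expected", [
        (512, 256, 256, 4),
        (512, 256, 128, 9),
        (768, 256, 256, 9),
    ])
    def test_tile_counts(self, size, tile, stride, expected):
        grid = tile_image(_od(size), tile, stride)
        assert grid.n_rows * grid.n_cols == expected

    def test_image_smaller_than_tile_raises(self):
        with pytest.raises(ValueError, match="smaller"):
            tile_image(_od(255), 256)

    def test_windows_inside_bounds(self):
        grid = tile_image(_od(700), 256, 128)
        for _, _, y0, x0, y1, x1 in grid.iter_windows():
            assert 0 <= y0 < y1 <= 700 and 0 <= x0 < x1 <= 700


class TestCleanLabelmap:
    def test_single_isolated_tile_removed(self):
        m = np.zeros((8, 8), bool)
        m[3, 3] = True
        assert not clean_labelmap(m, min_region_tiles=4).any()

    def test_interior_hole_filled(self):
        m = np.ones((10, 10), bool)
        m[5, 5] = False
        out = clean_labelmap(m, max_hole_tiles=4)
        assert out.all()

    def test_region_at_min_size_kept(self):
        m = np.zeros((8, 8), bool)
        m[2:4, 2:4] = True  # exactly 4 tiles
        assert clean_labelmap(m, min_region_tiles=4).sum() == 4

    def test_idempotent_on_random_maps(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            m = rng.uniform(size=(20, 20)) < 0.45
            once = clean_labelmap(m)
            assert np.array_equal(once, clean_labelmap(once))

    def test_never_adds_positives_outside_holes(self):
        rng = np.random.default_rng(12)
        m = rng.uniform(size=(15, 15)) < 0.4
        out = clean_labelmap(m)
        from scipy import ndimage
        filled = ndimage.binary_fill_holes(m)
        assert not np.any(out & ~filled)


class TestAnnotation:
    def _grid(self, n=8, tile_um=256.0, mpp=1.0):
        od = _od(n * tile_um, mpp)
        return tile_image(od, tile_um)

    def test_two_by_two_block_area(self):
        grid = self._grid()
        m = np.zeros((grid.n_rows, grid.n_cols), bool)
        m[0:2, 0:2] = True
        ann = labelmap_to_annotation(m, grid)
        assert ann.tumor_area_um2 == pytest.approx(4 * 256.0 ** 2)
        assert ann.polygons.area == pytest.approx(ann.tumor_area_um2, rel=5e-3)

    def test_empty_map(self):
        grid = self._grid()
        ann = labelmap_to_annotation(np.zeros((grid.n_rows, grid.n_cols), bool), grid)
        assert ann.is_empty and ann.tumor_area_um2 == 0.0

    def test_polygon_area_matches_tile_count_on_random_maps(self):
        grid = self._grid()
        rng = np.random.default_rng(13)
        for _ in range(10):
            m = clean_labelmap(rng.uniform(size=(grid.n_rows, grid.n_cols)) < 0.5)
            ann = labelmap_to_annotation(m, grid)
            if m.any():
                assert ann.polygons.area == pytest.approx(ann.tumor_area_um2, rel=5e-3)

    def test_pixel_mask_area_matches(self):
        grid = self._grid(n=4)
        m = np.zeros((4, 4), bool)
        m[1, 1] = m[1, 2] = True
        ann = labelmap_to_annotation(m, grid)
        assert ann.pixel_mask().sum() == 2 * grid.tile_px ** 2

    def test_geojson_structure(self):
        grid = self._grid(n=4)
        m = np.zeros((4, 4), bool)
        m[0, 0] = True
        gj = labelmap_to_annotation(m, grid).to_geojson()
        assert gj["type"] == "FeatureCollection"
        assert gj["features"][0]["properties"] == {"classification": "Tumor"}


class _FixedModel:
    """Deterministic stand-in classifier for plumbing tests."""

    def __init__(self, classes, answer=None):
        self.classes_ = np.asarray(classes)
        self.answer = answer
        self.tile_size_um = 256.0

    def predict_proba(self, tiles):
        n = len(tiles)
        p = np.zeros((n, len(self.classes_)))
        if self.answer is None:  # "perfect": encode truth in tile mean
            for i, t in enumerate(tiles):
                p[i, int(round(np.mean(t)))] = 1.0
        else:
            p[:, list(self.classes_).index(self.answer)] = 1.0
        return p

    def predict(self, tiles):
        return self.classes_[np.argmax(self.predict_proba(tiles), axis=1)]


class TestClassifyTiles:
    def test_probabilities_and_labels(self):
        od = _od(512)
        od.od_h[0:256, 256:512] = 1.0  # tile (0,1) encodes class index 1
        grid = tile_image(od, 256)
        model = _FixedModel(["A", "B"])
        out = classify_tiles(model, grid, od)
        assert len(out) == 4
        assert out.set_index(["row", "col"]).loc[(0, 1), "label"] == "B"

    def test_tile_size_mismatch_raises(self):
        od = _od(512)
        grid = tile_image(od, 128)
        with pytest.raises(ValueError, match="tile size"):
            classify_tiles(_FixedModel(["A"]), grid, od)

    def test_labelmap_positive_only_for_tum(self):
        od = _od(512)
        grid = tile_image(od, 256)
        out = classify_tiles(_FixedModel(["ADI", "TUM"], answer="TUM"), grid, od)
        lab = tumor_labelmap(out, grid)
        assert lab.all()


class TestConfusionMatrix:
    def test_perfect_classifier(self):
        model = _FixedModel(["A", "B"], answer=None)
        tiles = [np.zeros((4, 4)), np.ones((4, 4))]
        mat, acc, per_class = confusion_matrix(model, tiles, ["A", "B"])
        assert acc == 1.0
        assert mat.loc["A", "A"] == 1 and mat.loc["B", "B"] == 1

    def test_constant_classifier_on_balanced_set(self):
        classes = list("ABCDEFGH")
        model = _FixedModel(classes, answer="A")
        tiles = [np.zeros((2, 2))] * 16
        labels = classes * 2
        _, acc, _ = confusion_matrix(model, tiles, labels)
        assert acc == pytest.approx(0.125)

    def test_row_sums_equal_class_counts(self):
        model = _FixedModel(["A", "B"], answer="A")
        tiles = [np.zeros((2, 2))] * 6
        labels = ["A", "A", "B", "B", "B", "B"]
        mat, _, _ = confusion_matrix(model, tiles, labels)
        assert mat.sum(axis=1).tolist() == [2, 4]

    def test_unknown_label_raises(self):
        model = _FixedModel(["A", "B"])
        with pytest.raises(ValueError, match="unknown"):
            confusion_matrix(model, [np.zeros((2, 2))], ["Z"])


class TestTileClassifierEstimator:
    def _toy_tiles(self, seed=0, n=12):
        # two trivially separable texture classes: empty vs dense blobs
        rng = np.random.default_rng(seed)
        tiles, labels = [], []
        for _ in range(n):
            t = np.clip(rng.normal(0, 0.01, (64, 64)), 0, None)
            tiles.append(t)
            labels.append("EMPTY")
            t2 = np.clip(rng.normal(0, 0.01, (64, 64)), 0, None)
            for _ in range(30):
                y, x = rng.integers(5, 59, 2)
                t2[y - 2:y + 2, x - 2:x + 2] = 0.8
            tiles.append(t2)
            labels.append("DENSE")
        return tiles, labels

    def test_separates_toy_classes_and_is_deterministic(self):
        tiles, labels = self._toy_tiles()
        m1 = TileClassifier(mpp=1.0, seed=7).fit(tiles, labels)
        m2 = TileClassifier(mpp=1.0, seed=7).fit(tiles, labels)
        probe, _ = self._toy_tiles(seed=99, n=4)
        assert np.array_equal(m1.predict(probe), m2.predict(probe))
        assert m1.holdout_accuracy_ == 1.0

    def test_single_class_predicts_that_class(self):
        tiles = [np.zeros((32, 32))] * 5
        m = TileClassifier(mpp=1.0).fit(tiles, ["STR"] * 5)
        assert list(m.predict(tiles[:2])) == ["STR", "STR"]

    def test_probabilities_sum_to_one(self):
        tiles, labels = self._toy_tiles()
        m = TileClassifier(mpp=1.0, seed=1).fit(tiles, labels)
        p = m.predict_proba(tiles[:6])
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_serialization_roundtrip(self, tmp_path):
        tiles, labels = self._toy_tiles()
        m = TileClassifier(mpp=1.0, seed=2).fit(tiles, labels)
        path = tmp_path / "tissue.json"
        m.save(path)
        m2 = TileClassifier.load(path)
        probe, _ = self._toy_tiles(seed=42, n=3)
        assert np.allclose(m.predict_proba(probe), m2.predict_proba(probe))
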