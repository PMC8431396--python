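"""Morphometric / intensity features and neighbor smoothing."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk

from pdl1score.cells import DetectionParams, detect_nuclei, expand_cells
from pdl1score.features import (RAW_FEATURES, SMOOTHED_PREFIX,
                                compute_feature_table, smooth_features)
from pdl1score.stain import ODImage


def _population(centers_px, radius_px=8, shape=(300, 300), mpp=0.5,
                expansion=5.0, od_h_value=0.5, uniform=False):
    od_h = np.full(shape, od_h_value) if uniform else np.zeros(shape)
    if not uniform:
        for cy, cx in centers_px:
            rr, cc = disk((cy, cx), radius_px, shape=shape)
            od_h[rr, cc] = od_h_value
    od = ODImage(od_h=od_h, od_d=np.zeros(shape), mpp=mpp,
                 background_rgb=(255, 255, 255))
    if uniform:
        # detection needs contrast; synthesize nuclei on a copy, keep stats uniform
        det_h = np.zeros(shape)
        for cy, cx in centers_px:
            rr, cc = disk((cy, cx), radius_px, shape=shape)
            det_h[rr, cc] = 0.8
        det_od = ODImage(od_h=det_h, od_d=np.zeros(shape), mpp=mpp,
                         background_rgb=(255, 255, 255))
        nuclei = detect_nuclei(det_od, np.ones(shape, bool))
    else:
        nuclei = detect_nuclei(od, np.ones(shape, bool))
    pop = expand_cells(nuclei, expansion, np.ones(shape, bool), mpp=mpp)
    return pop, od


class TestComputeFeatures:
    def test_uniform_stain_statistics(self):
        pop, od = _population([(150, 150)], uniform=True)
        t = compute_feature_table(pop, od)
        for stat in ("mean", "median", "min", "max"):
            assert t[f"nucleus_hematoxylin_{stat}"].iloc[0] == pytest.approx(0.5)
        assert t["nucleus_hematoxylin_std"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_circle_and_square_circularity(self):
        shape = (400, 400)
        od_h = np.zeros(shape)
        rr, cc = disk((100, 100), 40, shape=shape)
        od_h[rr, cc] = 0.8
        od_h[250:330, 250:330] = 0.8
        od = ODImage(od_h=od_h, od_d=np.zeros(shape), mpp=0.5,
                     background_rgb=(255, 255, 255))
        nuclei = detect_nuclei(od, np.ones(shape, bool),
                               DetectionParams(max_area_um2=5000))
        pop = expand_cells(nuclei, 0.0, np.ones(shape, bool), mpp=0.5)
        t = compute_feature_table(pop, od).sort_values("nucleus_area_um2")
        circ_circle = t["nucleus_circularity"].iloc[0]
        circ_square = t["nucleus_circularity"].iloc[1]
        assert circ_circle >= 0.95
        assert circ_square == pytest.approx(np.pi / 4, rel=0.15)
        assert circ_square < circ_circle

    def test_min_diameter_not_larger_than_max(self, small_slide_od):
        od, truth = small_slide_od
        nuclei = detect_nuclei(od, truth.tumor_pixel_mask(od.shape))
        pop = expand_cells(nuclei, 5.0, truth.tumor_pixel_mask(od.shape), mpp=od.mpp)
        t = compute_feature_table(pop, od)
        assert (t["nucleus_min_diameter_um"] <= t["nucleus_max_diameter_um"] + 1e-9).all()
        assert t["nucleus_solidity"].between(0, 1.0 + 1e-9).all()
        assert t["nucleus_cell_area_ratio"].between(0, 1.0 + 1e-9).all()

    def test_zero_expansion_defaults_compartment_stats(self):
        pop, od = _population([(150, 150)], uniform=True, expansion=0.0)
        t = compute_feature_table(pop, od)
        assert t["nucleus_cell_area_ratio"].iloc[0] == pytest.approx(1.0)
        # cytoplasm absent: stats fall back to cell-level values
        assert (t["cytoplasm_hematoxylin_mean"].iloc[0]
                == pytest.approx(t["cell_hematoxylin_mean"].iloc[0]))

    def test_translation_invariance(self):
        t1 = compute_feature_table(*_population([(100, 100)]))
        t2 = compute_feature_table(*_population([(180, 140)]))
        cols = [c for c in RAW_FEATURES]
        a = t1[cols].iloc[0].to_numpy()
        b = t2[cols].iloc[0].to_numpy()
        np.testing.assert_allclose(a, b, rtol=0.02, atol=1e-9)


class TestSmoothFeatures:
    def _table(self, rows):
        df = pd.DataFrame(rows)
        for c in RAW_FEATURES:
            if c not in df.columns:
                df[c] = 1.0
        return df

    def test_single_cell_equals_raw(self):
        t = self._table([{"centroid_x_um": 0.0, "centroid_y_um": 0.0,
                          "cell_area_um2": 7.0}])
        out = smooth_features(t, 25.0)
        assert out[SMOOTHED_PREFIX + "cell_area_um2"].iloc[0] == 7.0
        assert out[SMOOTHED_PREFIX + "nearby_count"].iloc[0] == 0

    def test_constant_field_is_fixed_point(self):
        t = self._table([
            {"centroid_x_um": 0.0, "centroid_y_um": 0.0, "cell_area_um2": 3.0},
            {"centroid_x_um": 10.0, "centroid_y_um": 0.0, "cell_area_um2": 3.0},
        ])
        out = smooth_features(t, 25.0)
        assert np.allclose(out[SMOOTHED_PREFIX + "cell_area_um2"], 3.0)
        assert out[SMOOTHED_PREFIX + "nearby_count"].tolist() == [1, 1]

    def test_two_cell_weighted_mean_matches_hand_formula(self):
        d = 10.0
        t = self._table([
            {"centroid_x_um": 0.0, "centroid_y_um": 0.0, "cell_area_um2": 0.0},
            {"centroid_x_um": d, "centroid_y_um": 0.0, "cell_area_um2": 1.0},
        ])
        out = smooth_features(t, 25.0)
        sigma = 12.5
        w = np.exp(-d**2 / (2 * sigma**2))
        expected_first = (0.0 + w * 1.0) / (1.0 + w)
        assert out[SMOOTHED_PREFIX + "cell_area_um2"].iloc[0] == pytest.approx(expected_first)

    def test_smoothing_is_convex_combination(self):
        rng = np.random.default_rng(17)
        rows = [{"centroid_x_um": float(x), "centroid_y_um": float(y),
                 "cell_area_um2": float(v)}
                for (x, y, v) in zip(rng.uniform(0, 100, 40),
                                     rng.uniform(0, 100, 40),
                                     rng.uniform(0, 10, 40))]
        t = self._table(rows)
        out = smooth_features(t, 25.0)
        lo, hi = t["cell_area_um2"].min(), t["cell_area_um2"].max()
        s = out[SMOOTHED_PREFIX + "cell_area_um2"]
        assert (s >= lo - 1e-9).all() and (s <= hi + 1e-9).all()

    def test_radius_beyond_reach_keeps_raw(self):
        t = self._table([
            {"centroid_x_um": 0.0, "centroid_y_um": 0.0, "cell_area_um2": 0.0},
            {"centroid_x_um": 100.0, "centroid_y_um": 0.0, "cell_area_um2": 1.0},
        ])
        out = smooth_features(t, 25.0)
        assert out[SMOOTHED_PREFIX + "cell_area_um2"].tolist() == [0.0, 1.0]

    def test_invalid_radius_raises(self):
        t = self._table([{"centroid_x_um": 0.0, "centroid_y_um": 0.0}])
        with pytest.raises(ValueError):
            smooth_features(t, 0.0)
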