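"""End-to-end orchestration: image in, PD-L1 score report out.

Chains the four automated stages — (1) tile classification of the
hematoxylin channel into eight tissue classes and tumor annotation,
(2) nucleus detection in the annotated tumor region, (3) feature extraction
and MLP cell typing into tumor/immune/stromal, (4) compartment-specific DAB
positivity and TPS/CPS/ICS — under a single resolved configuration that is
embedded in the report so every run is reproducible from (inputs, config,
seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cells import CellPopulation, DetectionParams, detect_nuclei, expand_cells
from .classify import CellTypeClassifier, classify_cells
from .features import SMOOTHED_PREFIX, compute_feature_table, smooth_features
from .scoring import DEFAULT_DAB_THRESHOLD_OD, ScoreReport, call_positivity, compute_scores
from .stain import HDAB_DEFAULT, ODImage, RGBImage, rgb_image_to_od
from .tissue import (TileClassifier, TissueAnnotation, classify_tiles,
                     clean_labelmap, labelmap_to_annotation, tile_image,
                     tumor_labelmap)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_agreement",
           "typing_feature_columns", "train_models_from_synthetic"]

log = logging.getLogger("pdl1score")


@dataclass
class PipelineConfig:
    """Every tunable of the scoring pipeline, with provenance tracking."""

    tile_size_um: float = 256.0
    stride_um: float | None = None
    min_region_tiles: int = 4
    max_hole_tiles: int = 4
    sigma_um: float = 1.0
    od_floor: float = 0.15
    min_distance_um: float = 3.0
    min_area_um2: float = 8.0
    max_area_um2: float = 400.0
    expansion_um: float = 5.0
    membrane_thickness_um: float = 1.0
    smoothing_radius_um: float = 25.0
    smoothing_include_self: bool = True
    dab_threshold_od: float = DEFAULT_DAB_THRESHOLD_OD
    use_dab_features_for_typing: bool = False
    seed: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if f.name != "provenance":
                self.provenance.setdefault(f.name, "default")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)} - {"provenance"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        for k in data:
            cfg.provenance[k] = "user"
        return cfg

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def detection_params(self) -> DetectionParams:
        return DetectionParams(sigma_um=self.sigma_um, od_floor=self.od_floor,
                               min_distance_um=self.min_distance_um,
                               min_area_um2=self.min_area_um2,
                               max_area_um2=self.max_area_um2)


def typing_feature_columns(table: pd.DataFrame, use_dab: bool = False) -> list[str]:
    """Feature columns the cell-type MLP trains on.

    By default DAB-derived intensities are excluded: cell typing should rest
    on morphology and hematoxylin staining so a model transfers across slides
    with different PD-L1 expression.
    """
    cols = []
    for c in table.columns:
        base = c[len(SMOOTHED_PREFIX):] if c.startswith(SMOOTHED_PREFIX) else c
        if base in ("label", "centroid_x_um", "centroid_y_um"):
            continue
        if not use_dab and "_dab_" in base:
            continue
        cols.append(c)
    return cols


@dataclass
class PipelineResult:
    report: ScoreReport
    annotation: TissueAnnotation
    tile_labels: pd.DataFrame
    population: CellPopulation
    cells: pd.DataFrame            # feature table + class + positivity
    config: PipelineConfig
    timings_s: dict

    def report_json(self) -> dict:
        d = self.report.to_dict()
        d["software"] = {"name": "pdl1score", "version": __version__}
        d["config"] = self.config.to_dict()
        d["stage_counts"] = {
            "tiles": len(self.tile_labels),
            "tumor_tiles": int(self.annotation.labelmap.sum()),
            "cells": len(self.cells),
            "cells_per_class": (self.cells["cell_class"].value_counts().to_dict()
                                if len(self.cells) else {}),
            "positives_per_class": (self.cells.loc[self.cells["positive"], "cell_class"]
                                    .value_counts().to_dict() if len(self.cells) else {}),
        }
        d["timings_s"] = self.timings_s
        return d


def _to_od(image: RGBImage | ODImage, background_rgb=None) -> ODImage:
    if isinstance(image, ODImage):
        return image
    return rgb_image_to_od(image, HDAB_DEFAULT, background_rgb=background_rgb)


def run_pipeline(image: RGBImage | ODImage, tissue_model: TileClassifier,
                 cell_model: CellTypeClassifier,
                 config: PipelineConfig | None = None,
                 background_rgb=None) -> PipelineResult:
    """Run the full automated scoring pipeline on one image.

    Returns a :class:`PipelineResult`; when no tumor tissue is detected the
    report carries undefined TPS/CPS (flagged, not raised) and an empty
    annotation so the caller can distinguish "no tumor" from failure.
    """
    config = config or PipelineConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    od = _to_od(image, background_rgb)
    timings["stain_separation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    grid = tile_image(od, config.tile_size_um, config.stride_um)
    tile_labels = classify_tiles(tissue_model, grid, od)
    labelmap = tumor_labelmap(tile_labels, grid)
    labelmap = clean_labelmap(labelmap, config.min_region_tiles, config.max_hole_tiles)
    annotation = labelmap_to_annotation(labelmap, grid)
    timings["tissue_detection"] = time.perf_counter() - t0
    log.info("tiles=%d tumor_tiles=%d", len(tile_labels), int(labelmap.sum()))

    empty_cells = pd.DataFrame(columns=["label", "cell_class", "positive",
                                        "cell_area_um2"])
    if annotation.is_empty:
        report = ScoreReport(n_tumor=0, n_tumor_pos=0, n_immune=0, n_immune_pos=0,
                             area_immune_pos_um2=0.0, tumor_area_um2=0.0,
                             tps=None, cps=None, ics=0.0, tps_defined=False,
                             categories={"TPS": None, "CPS": None, "ICS": None},
                             dab_threshold_od=config.dab_threshold_od,
                             notes=["no tumor tissue detected"])
        pop = CellPopulation([], np.zeros(od.shape, np.int32),
                             np.zeros(od.shape, np.int32),
                             np.zeros(od.shape, np.int8), od.mpp)
        return PipelineResult(report, annotation, tile_labels, pop, empty_cells,
                              config, timings)

    t0 = time.perf_counter()
    nuclei = detect_nuclei(od, annotation, config.detection_params())
    population = expand_cells(nuclei, config.expansion_um, annotation, mpp=od.mpp,
                              image_shape=od.shape,
                              membrane_thickness_um=config.membrane_thickness_um)
    timings["cell_detection"] = time.perf_counter() - t0
    log.info("nuclei=%d", len(nuclei))

    t0 = time.perf_counter()
    table = compute_feature_table(population, od)
    table = smooth_features(table, config.smoothing_radius_um,
                            include_self=config.smoothing_include_self)
    timings["features"] = time.perf_counter() - t0

    if len(table) == 0:
        report = compute_scores(
            empty_cells.assign(positive=pd.Series(dtype=bool)),
            annotation.tumor_area_um2, dab_threshold_od=config.dab_threshold_od)
        report.notes.append("no cells detected in the tumor region")
        return PipelineResult(report, annotation, tile_labels, population,
                              empty_cells, config, timings)

    t0 = time.perf_counter()
    cols = typing_feature_columns(table, config.use_dab_features_for_typing)
    feats = table[cols].fillna(0.0)
    labels, proba = classify_cells(cell_model, feats)
    cells = table.copy()
    cells["cell_class"] = labels
    cells["class_probability"] = proba.max(axis=1)
    cells["cell_area_um2"] = [c.cell_area_um2 for c in population.cells]
    cells["membrane_fallback"] = [c.membrane_fallback for c in population.cells]
    timings["cell_typing"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    scored = call_positivity(cells, config.dab_threshold_od)
    report = compute_scores(scored, annotation.tumor_area_um2,
                            dab_threshold_od=config.dab_threshold_od)
    if scored["membrane_fallback"].any():
        report.notes.append(
            f"{int(scored['membrane_fallback'].sum())} cells used the "
            "nucleus-boundary band as membrane fallback")
    timings["scoring"] = time.perf_counter() - t0
    log.info("%s", report.summary())
    return PipelineResult(report, annotation, tile_labels, population, scored,
                          config, timings)


# ---------------------------------------------------------------------------
# training on synthetic material
# ---------------------------------------------------------------------------

def train_models_from_synthetic(seed: int = 0, n_tiles_per_class: int = 60,
                                n_training_slides: int = 2,
                                config: PipelineConfig | None = None,
                                training_recipes=None
                                ) -> tuple[TileClassifier, CellTypeClassifier]:
    """Train both classifiers on generator output (no external data).

    The tissue model learns from labeled synthetic texture tiles; the cell
    model learns from cells detected in rendered training slides, labeled by
    matching each detection to the nearest ground-truth cell centroid.
    """
    from .synthetic import DEFAULT_MPP, SlideRecipe, generate_slide, generate_tile_dataset

    config = config or PipelineConfig()
    tiles, labels = generate_tile_dataset(n_tiles_per_class, config.tile_size_um,
                                          seed=seed)
    tissue_model = TileClassifier(mpp=DEFAULT_MPP, tile_size_um=config.tile_size_um,
                                  seed=seed).fit(tiles, labels)

    if training_recipes is None:
        training_recipes = [SlideRecipe(seed=seed + 1000 + i, target_tps=40.0,
                                        target_ics=2.0)
                            for i in range(n_training_slides)]
    frames = []
    targets = []
    for recipe in training_recipes:
        image, truth = generate_slide(recipe)
        od = rgb_image_to_od(image, HDAB_DEFAULT)
        region = truth.tumor_pixel_mask(od.shape)
        nuclei = detect_nuclei(od, region, config.detection_params())
        population = expand_cells(nuclei, config.expansion_um, region, mpp=od.mpp,
                                  membrane_thickness_um=config.membrane_thickness_um)
        table = compute_feature_table(population, od)
        table = smooth_features(table, config.smoothing_radius_um,
                                include_self=config.smoothing_include_self)
        # label detections by the nearest truth nucleus centroid
        from scipy.spatial import cKDTree
        truth_xy = truth.cells[["x_um", "y_um"]].to_numpy()
        tree = cKDTree(truth_xy)
        det_xy = table[["centroid_x_um", "centroid_y_um"]].to_numpy()
        dist, idx = tree.query(det_xy)
        keep = dist <= 5.0
        frames.append(table.loc[keep])
        targets.append(truth.cells["cell_class"].to_numpy()[idx[keep]])

    big = pd.concat(frames, ignore_index=True)
    y = np.concatenate(targets)
    cols = typing_feature_columns(big, config.use_dab_features_for_typing)
    cell_model = CellTypeClassifier(seed=seed,
                                    required_classes=("TUMOR", "IMMUNE", "STROMAL"))
    cell_model.fit(big[cols].fillna(0.0), y)
    return tissue_model, cell_model


def run_agreement(ratings_by_score: dict[str, pd.DataFrame],
                  cutoffs_by_score: dict[str, tuple[float, float]] | None = None,
                  machine_column: str | None = None) -> dict:
    """Full agreement battery per score type.

    For each score type: multi-rater ICC, mean-pairwise weighted kappa on the
    cutoff categories, the pairwise concordance matrix, and — when a machine
    column is flagged — machine-vs-human-mean ICC, Wilcoxon, kappa and
    concordance.
    """
    from .agreement import (cutoff_concordance, icc, mean_pairwise_kappa,
                            paired_difference, ratings_matrix, weighted_kappa)
    from .scoring import CUTOFFS

    cutoffs_by_score = cutoffs_by_score or CUTOFFS
    out: dict[str, dict] = {}
    for score_name, df in ratings_by_score.items():
        df = ratings_matrix(df)
        cutoffs = cutoffs_by_score.get(score_name, (1.0, 50.0))
        K = len(cutoffs) + 1
        cat_labels = list(range(K))

        human_cols = [c for c in df.columns if c != machine_column]
        human = df[human_cols]
        res: dict = {"n_cases": len(df), "raters": list(df.columns),
                     "cutoffs": list(cutoffs)}
        res["icc_raters"] = icc(human).to_dict()
        cat = pd.DataFrame({c: np.searchsorted(list(cutoffs), df[c], side="right")
                            for c in df.columns}, index=df.index)
        res["mean_pairwise_kappa"] = mean_pairwise_kappa(
            cat[human_cols], cat_labels).to_dict()
        conc = {}
        for i, c1 in enumerate(df.columns):
            for c2 in df.columns[i + 1:]:
                pct, _, _ = cutoff_concordance(df[c1], df[c2], cutoffs)
                conc[f"{c1}|{c2}"] = pct
        res["pairwise_concordance_pct"] = conc

        if machine_column is not None and machine_column in df.columns:
            hmean = human.mean(axis=1)
            machine = df[machine_column]
            pair = pd.DataFrame({"human_mean": hmean, "machine": machine})
            res["icc_machine_vs_human_mean"] = icc(pair).to_dict()
            res["kappa_machine_vs_human_mean"] = weighted_kappa(
                np.searchsorted(list(cutoffs), hmean, side="right"),
                np.searchsorted(list(cutoffs), machine, side="right"),
                cat_labels).to_dict()
            pct, _, _ = cutoff_concordance(hmean, machine, cutoffs)
            res["concordance_machine_vs_human_mean_pct"] = pct
            res["paired_difference"] = paired_difference(hmean, machine)
        out[score_name] = res
    return out
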