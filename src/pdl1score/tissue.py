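"""Tumor-region detection by sliding-window tile classification.

The hematoxylin channel of the slide is traversed in tiles with a physical
edge length (default 256 µm).  Each tile is classified into one of eight
tissue classes; tiles labeled tumor form a binary labelmap which is cleaned
(small regions removed, small holes filled) and polygonized into a tumor
annotation whose area is the denominator of the immune-cell score.

The tile classifier is an interface: the default implementation extracts
scale-aware texture statistics from the hematoxylin-OD patch and feeds a
small multilayer perceptron.  Any object with compatible
``predict_proba``/``classes_`` can be substituted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box, mapping
from shapely.ops import unary_union
from skimage import measure, morphology
from skimage.filters import gaussian
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .stain import ODImage

__all__ = [
    "TissueClass",
    "TileGrid",
    "tile_image",
    "TileClassifier",
    "train_tile_classifier",
    "classify_tiles",
    "clean_labelmap",
    "labelmap_to_annotation",
    "TissueAnnotation",
    "confusion_matrix",
]


class TissueClass(str, Enum):
    """The eight tissue classes distinguished by the tile classifier."""

    ADI = "ADI"  # adipose tissue
    CHR = "CHR"  # cartilage
    EPI = "EPI"  # squamous epithelium
    GLD = "GLD"  # glandular tissue
    IMU = "IMU"  # immune cells
    MUS = "MUS"  # muscle tissue
    STR = "STR"  # stromal tissue
    TUM = "TUM"  # tumor tissue


CLASS_ORDER: tuple[str, ...] = tuple(c.value for c in TissueClass)


@dataclass
class TileGrid:
    """Sliding-window tile layout over a calibrated image.

    ``windows`` holds ``(row, col, y0, x0)`` pixel origins of every full tile;
    partial tiles at the right/bottom edges are dropped.
    """

    tile_size_um: float
    stride_um: float
    tile_px: int
    stride_px: int
    mpp: float
    n_rows: int
    n_cols: int
    image_shape: tuple[int, int]

    @property
    def cell_area_um2(self) -> float:
        """Area of one labelmap cell (= tile area for the default stride)."""
        return (self.stride_px * self.mpp) ** 2

    # backwards-friendly alias; equals cell area for non-overlapping stride
    tile_area_um2 = cell_area_um2

    def window(self, row: int, col: int) -> tuple[int, int, int, int]:
        """Pixel bounds (y0, x0, y1, x1) of tile (row, col)."""
        y0 = row * self.stride_px
        x0 = col * self.stride_px
        return y0, x0, y0 + self.tile_px, x0 + self.tile_px

    def cell_bounds(self, row: int, col: int) -> tuple[int, int, int, int]:
        """Pixel bounds of one labelmap cell (stride-sized)."""
        y0 = row * self.stride_px
        x0 = col * self.stride_px
        return y0, x0, y0 + self.stride_px, x0 + self.stride_px

    def iter_windows(self):
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield r, c, *self.window(r, c)


def tile_image(od: ODImage, tile_size_um: float = 256.0,
               stride_um: float | None = None) -> TileGrid:
    """Lay a sliding-window tile grid over a calibrated OD image.

    Default stride equals the tile size (non-overlapping traversal).
    """
    if stride_um is None:
        stride_um = tile_size_um
    if not (0 < stride_um <= tile_size_um):
        raise ValueError("stride_um must lie in (0, tile_size_um]")
    h, w = od.shape
    tile_px = int(round(tile_size_um / od.mpp))
    stride_px = int(round(stride_um / od.mpp))
    if tile_px < 1 or stride_px < 1:
        raise ValueError("tile or stride below one pixel at this calibration")
    if h < tile_px or w < tile_px:
        raise ValueError("image smaller than one tile")
    n_rows = (h - tile_px) // stride_px + 1
    n_cols = (w - tile_px) // stride_px + 1
    return TileGrid(tile_size_um=tile_size_um, stride_um=stride_um,
                    tile_px=tile_px, stride_px=stride_px, mpp=od.mpp,
                    n_rows=n_rows, n_cols=n_cols, image_shape=(h, w))


# ---------------------------------------------------------------------------
# Texture features for hematoxylin-OD tiles
# ---------------------------------------------------------------------------

_TILE_FEATURE_NAMES = [
    "od_mean", "od_std", "od_p10", "od_p50", "od_p90",
    "frac_above_0.10", "frac_above_0.25", "frac_above_0.50",
    "coverage",
    "blob_density_mm2", "blob_area_mean_um2", "blob_area_sd_um2",
    "blob_ecc_mean", "blob_solidity_mean", "blob_extent_max_um",
    "blob_circ_mean", "euler_per_blob",
    "nn_dist_mean_um", "nn_dist_cv",
    "grad_mag_mean", "orient_coherence",
]


def _tile_features(tile: np.ndarray, mpp: float) -> np.ndarray:
    """Scale-aware texture statistics of one hematoxylin-OD patch."""
    t = np.asarray(tile, dtype=float)
    area_um2 = t.size * mpp * mpp
    flat = t.ravel()
    p10, p50, p90 = np.percentile(flat, [10, 50, 90])
    out = [flat.mean(), flat.std(), p10, p50, p90,
           float((flat > 0.10).mean()), float((flat > 0.25).mean()),
           float((flat > 0.50).mean())]

    sm = gaussian(t, sigma=max(1.0, 0.75 / mpp), preserve_range=True)
    binary = sm > 0.18
    binary = morphology.remove_small_objects(binary, max_size=max(1, int(2.0 / mpp**2) - 1))
    out.append(float(binary.mean()))  # coverage

    lab, n_blobs = ndimage.label(binary)
    if n_blobs > 0:
        props = measure.regionprops(lab)
        areas = np.array([p.area for p in props]) * mpp * mpp
        eccs = np.array([p.eccentricity for p in props])
        sols = np.array([p.solidity for p in props])
        exts = np.array([max(p.bbox[2] - p.bbox[0], p.bbox[3] - p.bbox[1]) for p in props]) * mpp
        perims = np.array([max(p.perimeter, 1e-6) for p in props])
        circs = 4 * np.pi * np.array([p.area for p in props]) / perims**2
        euler = measure.euler_number(binary, connectivity=2)
        cents = np.array([p.centroid for p in props]) * mpp
        out += [n_blobs / (area_um2 / 1e6), areas.mean(), areas.std(),
                eccs.mean(), sols.mean(), exts.max(),
                float(np.clip(circs, 0, 1.2).mean()), euler / n_blobs]
        if n_blobs >= 2:
            from scipy.spatial import cKDTree
            d, _ = cKDTree(cents).query(cents, k=2)
            nn = d[:, 1]
            out += [nn.mean(), nn.std() / max(nn.mean(), 1e-9)]
        else:
            out += [np.sqrt(area_um2), 0.0]
    else:
        out += [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, np.sqrt(area_um2), 0.0]

    gy, gx = np.gradient(sm)
    gmag = np.hypot(gx, gy)
    out.append(float(gmag.mean()))
    # structure-tensor orientation coherence: 1 for parallel fibers, 0 isotropic
    w = gmag > np.percentile(gmag, 75)
    if w.sum() > 16:
        jxx = float((gx[w] ** 2).mean())
        jyy = float((gy[w] ** 2).mean())
        jxy = float((gx[w] * gy[w]).mean())
        tr = jxx + jyy
        det = jxx * jyy - jxy**2
        disc = max(tr * tr / 4 - det, 0.0)
        l1 = tr / 2 + np.sqrt(disc)
        l2 = tr / 2 - np.sqrt(disc)
        out.append((l1 - l2) / tr if tr > 1e-12 else 0.0)
    else:
        out.append(0.0)
    return np.asarray(out, dtype=float)


class TileClassifier(BaseEstimator, ClassifierMixin):
    """Tissue-class classifier for hematoxylin-OD tiles.

    A scikit-learn estimator: ``fit`` on an iterable of equally sized 2-D OD
    patches plus class labels, ``predict``/``predict_proba`` on new patches.
    Texture statistics are computed in physical units so a model transfers
    between calibrations.

    Parameters
    ----------
    mpp : µm/px of the training tiles.
    tile_size_um : physical tile edge the model expects.
    hidden_units, l2, max_iter, seed : MLP hyperparameters.
    validation_fraction : stratified held-out fraction used to report
        ``holdout_accuracy_`` and ``confusion_matrix_``.
    """

    def __init__(self, mpp: float = 0.5, tile_size_um: float = 256.0,
                 hidden_units: int = 48, l2: float = 1e-4, max_iter: int = 800,
                 seed: int = 0, validation_fraction: float = 0.2):
        self.mpp = mpp
        self.tile_size_um = tile_size_um
        self.hidden_units = hidden_units
        self.l2 = l2
        self.max_iter = max_iter
        self.seed = seed
        self.validation_fraction = validation_fraction

    def _featurize(self, tiles) -> np.ndarray:
        return np.vstack([_tile_features(t, self.mpp) for t in tiles])

    def fit(self, X, y):
        y = np.asarray([str(v) for v in y])
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 1 or (len(classes) >= 2 and counts.min() < 1):
            raise ValueError("every class needs at least one tile")
        F = self._featurize(X)
        self.classes_ = classes
        self.scaler_ = StandardScaler().fit(F)
        Fs = self.scaler_.transform(F)
        mlp_kw = dict(hidden_layer_sizes=(self.hidden_units,), alpha=self.l2,
                      max_iter=self.max_iter, random_state=self.seed)
        if len(classes) == 1:
            # degenerate but legal: constant predictor
            self.mlp_ = None
            self.holdout_accuracy_ = 1.0
            self.confusion_matrix_ = np.array([[len(y)]])
        else:
            idx = np.arange(len(y))
            tr, te = train_test_split(idx, test_size=self.validation_fraction,
                                      stratify=y, random_state=self.seed)
            probe = MLPClassifier(**mlp_kw).fit(Fs[tr], y[tr])
            pred = probe.predict(Fs[te])
            self.holdout_accuracy_ = float((pred == y[te]).mean())
            self.confusion_matrix_ = _sk_confusion(y[te], pred, labels=classes)
            self.mlp_ = MLPClassifier(**mlp_kw).fit(Fs, y)
        self.n_features_in_ = F.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        F = self.scaler_.transform(self._featurize(X))
        if self.mlp_ is None:
            return np.ones((F.shape[0], 1))
        return self.mlp_.predict_proba(F)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    # -- portable serialization (versioned JSON) ---------------------------
    def save(self, path) -> None:
        if self.mlp_ is None:
            raise ValueError("cannot serialize a single-class model")
        payload = {
            "format": "pdl1score.tile_classifier",
            "version": 1,
            "params": self.get_params(),
            "classes": self.classes_.tolist(),
            "scaler_mean": self.scaler_.mean_.tolist(),
            "scaler_scale": self.scaler_.scale_.tolist(),
            "coefs": [w.tolist() for w in self.mlp_.coefs_],
            "intercepts": [b.tolist() for b in self.mlp_.intercepts_],
            "holdout_accuracy": self.holdout_accuracy_,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TileClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "pdl1score.tile_classifier":
            raise ValueError("not a tile-classifier file")
        obj = cls(**payload["params"])
        obj.classes_ = np.array(payload["classes"])
        obj.scaler_ = StandardScaler()
        obj.scaler_.mean_ = np.array(payload["scaler_mean"])
        obj.scaler_.scale_ = np.array(payload["scaler_scale"])
        obj.scaler_.var_ = obj.scaler_.scale_ ** 2
        obj.scaler_.n_features_in_ = len(obj.scaler_.mean_)
        mlp = MLPClassifier(hidden_layer_sizes=(obj.hidden_units,))
        mlp.coefs_ = [np.array(w) for w in payload["coefs"]]
        mlp.intercepts_ = [np.array(b) for b in payload["intercepts"]]
        mlp.classes_ = obj.classes_
        mlp.n_layers_ = len(mlp.coefs_) + 1
        mlp.n_outputs_ = mlp.coefs_[-1].shape[1]
        mlp.out_activation_ = "softmax" if mlp.n_outputs_ > 1 else "logistic"
        mlp._label_binarizer = None
        mlp.activation = "relu"
        obj.mlp_ = mlp
        obj.holdout_accuracy_ = payload["holdout_accuracy"]
        obj.n_features_in_ = len(obj.scaler_.mean_)
        return obj


def train_tile_classifier(tiles, labels, *, mpp: float = 0.5,
                          tile_size_um: float = 256.0, seed: int = 0,
                          **kwargs) -> TileClassifier:
    """Train the default tile classifier (thin wrapper over the estimator)."""
    return TileClassifier(mpp=mpp, tile_size_um=tile_size_um, seed=seed,
                          **kwargs).fit(tiles, labels)


def classify_tiles(model: TileClassifier, grid: TileGrid, od: ODImage) -> pd.DataFrame:
    """Classify every grid tile of the hematoxylin channel.

    Returns a DataFrame with ``row, col, label, probability`` (argmax of the
    model's class probabilities; ties broken by the model's class order).
    """
    model_tile = getattr(model, "tile_size_um", grid.tile_size_um)
    if abs(model_tile - grid.tile_size_um) > 1e-6:
        raise ValueError("model tile size does not match grid tile size")
    tiles = [od.od_h[y0:y1, x0:x1] for _, _, y0, x0, y1, x1 in grid.iter_windows()]
    proba = model.predict_proba(tiles)
    if np.any(np.abs(proba.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("classifier probabilities do not sum to 1")
    idx = np.argmax(proba, axis=1)
    rows = [(r, c) for r, c, *_ in grid.iter_windows()]
    return pd.DataFrame({
        "row": [r for r, _ in rows],
        "col": [c for _, c in rows],
        "label": model.classes_[idx],
        "probability": proba[np.arange(len(idx)), idx],
    })


def tumor_labelmap(tile_labels: pd.DataFrame, grid: TileGrid,
                   positive_class: str = TissueClass.TUM.value) -> np.ndarray:
    """Binary labelmap at tile resolution from classified tiles.

    With an overlapping stride a grid cell may be covered by several windows;
    each cell takes the label of the maximum-probability window covering it.
    """
    lab = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    best = np.full((grid.n_rows, grid.n_cols), -np.inf)
    cover = max(1, grid.tile_px // grid.stride_px)
    for _, rec in tile_labels.iterrows():
        r, c = int(rec["row"]), int(rec["col"])
        p = float(rec["probability"])
        for i in range(r, min(r + cover, grid.n_rows)):
            for j in range(c, min(c + cover, grid.n_cols)):
                if p > best[i, j]:
                    best[i, j] = p
                    lab[i, j] = rec["label"] == positive_class
    return lab


def clean_labelmap(binary_map: np.ndarray, min_region_tiles: int = 4,
                   max_hole_tiles: int = 4) -> np.ndarray:
    """Remove small connected components and fill small interior holes.

    8-connectivity for foreground regions; holes of up to ``max_hole_tiles``
    tiles are filled.  Idempotent.
    """
    m = np.asarray(binary_map, dtype=bool)
    # components strictly smaller than min_region_tiles are removed
    m = morphology.remove_small_objects(m, connectivity=2, max_size=min_region_tiles - 1)
    # fill interior holes only: background components that touch the map
    # border are bays, not holes
    bg_labels, n_bg = ndimage.label(~m, structure=np.array([[0, 1, 0],
                                                            [1, 1, 1],
                                                            [0, 1, 0]]))
    border = np.zeros_like(m)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_labels = set(np.unique(bg_labels[border])) - {0}
    sizes = np.bincount(bg_labels.ravel(), minlength=n_bg + 1)
    for lab in range(1, n_bg + 1):
        if lab not in border_labels and sizes[lab] <= max_hole_tiles:
            m[bg_labels == lab] = True
    return m


@dataclass
class TissueAnnotation:
    """Cleaned binary tumor labelmap plus polygon representation.

    ``polygons`` is a shapely (Multi)Polygon in µm coordinates (origin
    top-left, x rightward, y downward); ``tumor_area_um2`` is the positive
    tile count times the tile area.
    """

    labelmap: np.ndarray
    grid: TileGrid
    polygons: object
    tumor_area_um2: float

    @property
    def is_empty(self) -> bool:
        return not bool(self.labelmap.any())

    def pixel_mask(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        """Rasterize the labelmap to image resolution."""
        shape = shape or self.grid.image_shape
        mask = np.zeros(shape, dtype=bool)
        g = self.grid
        for r, c in zip(*np.nonzero(self.labelmap)):
            y0, x0, y1, x1 = g.cell_bounds(r, c)
            mask[y0:min(y1, shape[0]), x0:min(x1, shape[1])] = True
        return mask

    def to_geojson(self) -> dict:
        """QuPath-importable FeatureCollection (coordinates in µm)."""
        features = []
        geoms = getattr(self.polygons, "geoms", [self.polygons]) if not self.polygons.is_empty else []
        for geom in geoms:
            features.append({
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {"classification": "Tumor"},
            })
        return {"type": "FeatureCollection", "features": features}


def labelmap_to_annotation(binary_map: np.ndarray, grid: TileGrid) -> TissueAnnotation:
    """Polygonize a tile-resolution binary labelmap into a µm annotation."""
    m = np.asarray(binary_map, dtype=bool)
    if m.shape != (grid.n_rows, grid.n_cols):
        raise ValueError("labelmap does not match the tile grid")
    boxes = []
    for r, c in zip(*np.nonzero(m)):
        y0, x0, y1, x1 = grid.cell_bounds(r, c)
        boxes.append(box(x0 * grid.mpp, y0 * grid.mpp, x1 * grid.mpp, y1 * grid.mpp))
    poly = unary_union(boxes) if boxes else box(0, 0, 0, 0).buffer(0)
    area = float(m.sum()) * grid.cell_area_um2
    return TissueAnnotation(labelmap=m, grid=grid, polygons=poly, tumor_area_um2=area)


def confusion_matrix(model, tiles, labels) -> tuple[pd.DataFrame, float, dict]:
    """K×K confusion matrix (rows = truth), overall and per-class accuracy."""
    labels = np.asarray([str(v) for v in labels])
    known = set(model.classes_.tolist())
    unknown = set(labels) - known
    if unknown:
        raise ValueError(f"unknown label(s): {sorted(unknown)}")
    pred = model.predict(tiles)
    classes = model.classes_.tolist()
    mat = _sk_confusion(labels, pred, labels=classes)
    df = pd.DataFrame(mat, index=classes, columns=classes)
    overall = float(np.trace(mat)) / float(mat.sum())
    per_class = {c: (float(mat[i, i]) / s if (s := mat[i].sum()) else np.nan)
                 for i, c in enumerate(classes)}
    return df, overall, per_class
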