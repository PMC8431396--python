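"""Per-cell morphometric and stain-intensity features with neighbor smoothing.

The feature vector mirrors what brightfield cell-analysis software measures:
shape descriptors of cell and nucleus (areas, circularity, solidity, min/max
diameter, nucleus/cell area ratio) and, per compartment (nucleus, cytoplasm,
membrane, whole cell) and stain (hematoxylin, DAB), the mean, median, min,
max and dispersion (standard deviation) of optical density.  Every raw
feature is additionally smoothed over neighboring cells within a radius
(Gaussian weights, sigma = radius/2, self included) and a nearby-detection
count is appended — local context markedly improves cell typing.

Column names are canonical and stable so trained model weights and variable
importances stay aligned across runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.measure import regionprops

from .cells import CYTOPLASM, MEMBRANE, NUCLEUS, CellPopulation
from .stain import ODImage

__all__ = [
    "SHAPE_FEATURES",
    "INTENSITY_FEATURES",
    "RAW_FEATURES",
    "compute_feature_table",
    "compute_features",
    "smooth_features",
    "SMOOTHED_PREFIX",
]

SHAPE_FEATURES = [
    "cell_area_um2", "nucleus_area_um2", "nucleus_cell_area_ratio",
    "cell_circularity", "nucleus_circularity", "nucleus_solidity",
    "cell_min_diameter_um", "cell_max_diameter_um",
    "nucleus_min_diameter_um", "nucleus_max_diameter_um",
]

_STAINS = ("hematoxylin", "dab")
_COMPARTMENTS = ("nucleus", "cytoplasm", "membrane", "cell")
_STATS = ("mean", "median", "min", "max", "std")

INTENSITY_FEATURES = [f"{comp}_{stain}_{stat}"
                      for stain in _STAINS
                      for comp in _COMPARTMENTS
                      for stat in _STATS]

RAW_FEATURES = SHAPE_FEATURES + INTENSITY_FEATURES

SMOOTHED_PREFIX = "smoothed:"

_MIN_COMPARTMENT_PX = 4  # below this, compartment stats default to cell-level


def _grouped_stats(labels: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    """(n, 5) array of mean/median/min/max/std per label in 1..n.

    Labels with no pixels yield NaN rows (filled from cell level later).
    """
    out = np.full((n, 5), np.nan)
    if labels.size == 0:
        return out
    order = np.argsort(labels, kind="stable")
    lab_s = labels[order]
    val_s = values[order]
    uniq, starts, counts = np.unique(lab_s, return_index=True, return_counts=True)
    for u, s, c in zip(uniq, starts, counts):
        if u < 1 or u > n or c < _MIN_COMPARTMENT_PX:
            continue
        v = val_s[s:s + c]
        out[u - 1] = (v.mean(), np.median(v), v.min(), v.max(), v.std())
    return out


def compute_feature_table(population: CellPopulation, od: ODImage) -> pd.DataFrame:
    """Raw feature block for every cell of a population.

    Returns one row per cell (indexed like ``population.cells``) with the
    canonical ``RAW_FEATURES`` columns plus ``label``, ``centroid_x_um`` and
    ``centroid_y_um``.  Compartments smaller than 4 px take the cell-level
    intensity statistics; empty membranes additionally use the
    nucleus-boundary band (fallback flagged by the population).
    """
    if od.shape != population.cell_labels.shape:
        raise ValueError("OD image does not match the cell label image")
    mpp = population.mpp
    n = len(population.cells)
    if n == 0:
        return pd.DataFrame(columns=["label", "centroid_x_um", "centroid_y_um"] + RAW_FEATURES)

    labels_of_cells = np.array([c.label for c in population.cells])
    max_label = int(labels_of_cells.max())

    inside = population.cell_labels > 0
    cl = population.cell_labels[inside]
    comp = population.compartments[inside]
    stains = {"hematoxylin": od.od_h[inside], "dab": od.od_d[inside]}

    # per (compartment, stain) grouped stats on the raster
    stats: dict[tuple[str, str], np.ndarray] = {}
    comp_sel = {"nucleus": comp == NUCLEUS, "cytoplasm": comp == CYTOPLASM,
                "membrane": comp == MEMBRANE, "cell": np.ones_like(comp, dtype=bool)}
    # membrane fallback: nucleus pixels at the nucleus boundary stand in when
    # a cell has no membrane compartment (e.g. zero expansion)
    fb_cells = [c.label for c in population.cells if c.membrane_fallback]
    if fb_cells:
        from scipy import ndimage as _ndi
        nuc_mask = population.nucleus_labels > 0
        eroded = _ndi.binary_erosion(nuc_mask, iterations=max(1, int(round(1.0 / mpp))))
        band = nuc_mask & ~eroded
        band_in = band[inside]
        fb_set = np.zeros(max_label + 1, dtype=bool)
        fb_set[fb_cells] = True
        use_band = fb_set[cl] & band_in
        comp_sel["membrane"] = comp_sel["membrane"] | use_band

    for comp_name, sel in comp_sel.items():
        for stain_name, vals in stains.items():
            stats[(comp_name, stain_name)] = _grouped_stats(cl[sel], vals[sel], max_label)

    # default small/absent compartments to cell-level values
    for stain_name in _STAINS:
        cell_stats = stats[("cell", stain_name)]
        for comp_name in ("nucleus", "cytoplasm", "membrane"):
            s = stats[(comp_name, stain_name)]
            nanrows = np.isnan(s[:, 0])
            s[nanrows] = cell_stats[nanrows]

    # shape features from the label images
    props_nuc = {p.label: p for p in regionprops(population.nucleus_labels)}
    props_cell = {p.label: p for p in regionprops(population.cell_labels)}

    rows = []
    for c in population.cells:
        i = c.label
        pn, pc = props_nuc.get(i), props_cell.get(i)
        rec = {"label": i,
               "centroid_x_um": c.centroid_um[0], "centroid_y_um": c.centroid_um[1]}
        for name, p, area in (("cell", pc, c.cell_area_um2),
                              ("nucleus", pn, c.nucleus_area_um2)):
            if p is None:
                rec[f"{name}_circularity"] = np.nan
                rec[f"{name}_min_diameter_um"] = np.nan
                rec[f"{name}_max_diameter_um"] = np.nan
                continue
            perim = max(p.perimeter_crofton, 1e-9) * mpp
            rec[f"{name}_circularity"] = float(np.clip(4 * np.pi * area / perim**2, 0, 1.05))
            rec[f"{name}_min_diameter_um"] = p.axis_minor_length * mpp
            rec[f"{name}_max_diameter_um"] = p.feret_diameter_max * mpp
        rec["cell_area_um2"] = c.cell_area_um2
        rec["nucleus_area_um2"] = c.nucleus_area_um2
        rec["nucleus_cell_area_ratio"] = (c.nucleus_area_um2 / c.cell_area_um2
                                          if c.cell_area_um2 > 0 else np.nan)
        rec["nucleus_solidity"] = props_nuc[i].solidity if i in props_nuc else np.nan
        for stain_name in _STAINS:
            for comp_name in _COMPARTMENTS:
                s = stats[(comp_name, stain_name)][i - 1]
                for j, stat in enumerate(_STATS):
                    rec[f"{comp_name}_{stain_name}_{stat}"] = s[j]
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df[["label", "centroid_x_um", "centroid_y_um"] + RAW_FEATURES]


def compute_features(cell_index: int, population: CellPopulation,
                     od: ODImage) -> pd.Series:
    """Feature vector of a single cell (row of :func:`compute_feature_table`)."""
    table = compute_feature_table(population, od)
    return table.iloc[cell_index]


def smooth_features(table: pd.DataFrame, radius_um: float = 25.0, *,
                    include_self: bool = True,
                    feature_columns: list[str] | None = None) -> pd.DataFrame:
    """Append Gaussian-weighted neighbor means of every raw feature.

    For cell *i*, ``smoothed_f(i) = sum_j w_ij f(j) / sum_j w_ij`` over cells
    *j* with ``d_ij <= radius_um`` (including *i* itself by default), with
    ``w_ij = exp(-d_ij^2 / (2 sigma^2))`` and ``sigma = radius_um / 2``.
    Also appends ``nearby_count`` = number of other cells within the radius.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    if len(table) == 0:
        return table.copy()
    feature_columns = feature_columns or [c for c in RAW_FEATURES if c in table.columns]
    pts = table[["centroid_x_um", "centroid_y_um"]].to_numpy()
    tree = cKDTree(pts)
    sigma = radius_um / 2.0
    F = table[feature_columns].to_numpy(dtype=float)
    n = len(table)
    smoothed = np.zeros_like(F)
    nearby = np.zeros(n, dtype=int)
    neighbors = tree.query_ball_point(pts, r=radius_um)
    for i, idx in enumerate(neighbors):
        idx = np.asarray(idx)
        nearby[i] = len(idx) - 1  # excludes self
        if not include_self:
            idx = idx[idx != i]
        if len(idx) == 0:
            smoothed[i] = F[i]
            continue
        d = np.linalg.norm(pts[idx] - pts[i], axis=1)
        w = np.exp(-d**2 / (2 * sigma**2))
        smoothed[i] = (w[:, None] * F[idx]).sum(axis=0) / w.sum()
    out = table.copy()
    for j, col in enumerate(feature_columns):
        out[SMOOTHED_PREFIX + col] = smoothed[:, j]
    out[SMOOTHED_PREFIX + "nearby_count"] = nearby
    return out
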