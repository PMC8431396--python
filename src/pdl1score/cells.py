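"""Nucleus detection and cell-compartment construction inside the tumor region.

Nuclei are detected on the hematoxylin channel only (DAB signal never enters
detection): Gaussian smoothing, triangle threshold with a configurable floor,
hole filling, and a distance-transform watershed to split touching objects.
Each object is reduced to a 32-ray star-convex polygon around its centroid —
the shape model used by modern nucleus detectors — so downstream code sees a
uniform geometry regardless of which detector produced it.  A pre-trained
external star-convex detector can be plugged in by producing the same
``NucleusShape`` list.

Cells are obtained by expanding every nucleus by a fixed distance, with each
pixel assigned to its nearest nucleus (influence zones), so cells of distinct
nuclei never overlap.  The cell is partitioned into nucleus, an inward
membrane band at the cell boundary, and cytoplasm; these compartments drive
both the morphometric features and the compartment-specific DAB positivity
rule (membranous for tumor cells, whole-cell for immune cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon, mapping
from skimage.draw import polygon as draw_polygon
from skimage.filters import gaussian, threshold_triangle
from skimage.measure import find_contours
from skimage.segmentation import watershed

from .stain import ODImage
from .tissue import TissueAnnotation

__all__ = [
    "DetectionParams",
    "NucleusShape",
    "CellGeometry",
    "CellPopulation",
    "detect_nuclei",
    "expand_cells",
]

N_RAYS = 32


@dataclass
class DetectionParams:
    """Tunables of the classical nucleus detector (all physical units)."""

    sigma_um: float = 1.0            # Gaussian smoothing of od_h
    od_floor: float = 0.15           # lower bound for the triangle threshold
    min_distance_um: float = 3.0     # minimum separation of watershed seeds
    min_area_um2: float = 8.0        # discard objects outside this range
    max_area_um2: float = 400.0


@dataclass
class NucleusShape:
    """A star-convex nucleus polygon: 32 radial vertices around the centroid.

    ``center_um`` is (x, y) in µm; ``radii_um`` holds one radius per ray at
    angles ``2*pi*k/32``; ``polygon`` is the shapely polygon in µm.
    """

    center_um: tuple[float, float]
    radii_um: np.ndarray
    polygon: Polygon
    area_um2: float

    def is_star_convex(self, n_probe: int = 64) -> bool:
        """Single-crossing ray test: every radial ray exits the boundary once.

        By construction radial polygons satisfy this; the probe samples the
        boundary radius as a function of angle and checks it is single-valued.
        """
        cx, cy = self.center_um
        ext = np.asarray(self.polygon.exterior.coords)
        ang = np.arctan2(ext[:, 1] - cy, ext[:, 0] - cx)
        # vertices must be angularly sorted (mod 2pi) for a radial polygon
        unwrapped = np.unwrap(ang)
        diffs = np.diff(unwrapped[:-1])
        return bool(np.all(diffs > 0) or np.all(diffs < 0))


def _star_polygon(mask_coords_yx: np.ndarray, centroid_yx: tuple[float, float],
                  mpp: float, offset_yx: tuple[int, int] = (0, 0)) -> tuple[np.ndarray, Polygon]:
    """Radii (µm) of a 32-ray star polygon from object pixel coordinates."""
    cy, cx = centroid_yx
    dy = mask_coords_yx[:, 0] - cy
    dx = mask_coords_yx[:, 1] - cx
    # outer corner of each pixel: radius measured to pixel center + half diagonal
    r = np.hypot(dy, dx) + 0.5
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    bins = np.floor(theta / (2 * np.pi / N_RAYS)).astype(int) % N_RAYS
    radii = np.zeros(N_RAYS)
    np.maximum.at(radii, bins, r)
    # empty bins (thin objects): fill from nearest non-empty neighbors
    if np.any(radii == 0):
        good = np.nonzero(radii)[0]
        if len(good) == 0:
            radii[:] = 0.5
        else:
            for k in np.nonzero(radii == 0)[0]:
                d = np.minimum(np.abs(good - k), N_RAYS - np.abs(good - k))
                radii[k] = radii[good[np.argmin(d)]]
    radii_um = radii * mpp
    angles = 2 * np.pi * np.arange(N_RAYS) / N_RAYS
    cx_um = (cx + offset_yx[1]) * mpp
    cy_um = (cy + offset_yx[0]) * mpp
    verts = np.column_stack([cx_um + radii_um * np.cos(angles),
                             cy_um + radii_um * np.sin(angles)])
    return radii_um, Polygon(verts)


def detect_nuclei(od: ODImage, region: TissueAnnotation | np.ndarray,
                  params: DetectionParams | None = None) -> list[NucleusShape]:
    """Detect nuclei as star-convex polygons within the tumor annotation.

    Deterministic; detections are sorted by (y, x) of their centroid and all
    lie inside the region mask.  Returns an empty list for an empty region.
    """
    params = params or DetectionParams()
    if od.mpp is None or not (od.mpp > 0):
        raise ValueError("missing pixel calibration")
    mask = region.pixel_mask(od.shape) if isinstance(region, TissueAnnotation) else np.asarray(region, dtype=bool)
    if mask.shape != od.shape:
        raise ValueError("region mask shape does not match image")
    if not mask.any():
        return []

    mpp = od.mpp
    # work on the bounding box of the region for speed
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    sub = od.od_h[y0:y1, x0:x1]
    submask = mask[y0:y1, x0:x1]

    sm = gaussian(sub, sigma=params.sigma_um / mpp, preserve_range=True)
    vals = sm[submask]
    if vals.max() <= 0:
        return []
    # triangle threshold: robust when nuclei cover a small area fraction and
    # classes differ in staining intensity; floored so faint background noise
    # never counts as nuclear
    try:
        thr = max(float(threshold_triangle(vals)), params.od_floor)
    except ValueError:  # constant field
        thr = params.od_floor
    binary = (sm >= thr) & submask
    binary = ndimage.binary_fill_holes(binary)
    if not binary.any():
        return []

    distance = ndimage.distance_transform_edt(binary)
    min_dist_px = max(1, int(round(params.min_distance_um / mpp)))
    from skimage.feature import peak_local_max
    peaks = peak_local_max(distance, min_distance=min_dist_px, threshold_abs=2.0,
                           labels=binary, exclude_border=False)
    markers = np.zeros_like(distance, dtype=np.int32)
    for i, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = i
    if markers.max() == 0:
        return []
    labels = watershed(-distance, markers, mask=binary)

    out: list[NucleusShape] = []
    objects = ndimage.find_objects(labels)
    for lab, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        obj = labels[slc] == lab
        # refine to the half-max boundary on the unsmoothed channel: the
        # smoothed threshold mask systematically overshoots the true nucleus
        # edge by about the smoothing radius
        raw = sub[slc]
        half = 0.5 * float(np.median(raw[obj]))
        refined = obj & (raw >= max(half, thr * 0.5))
        if refined.sum() >= 0.25 * obj.sum():
            lab_cc, n_cc = ndimage.label(refined)
            if n_cc > 1:
                sizes = np.bincount(lab_cc.ravel())[1:]
                refined = lab_cc == (1 + int(np.argmax(sizes)))
            obj = refined
        area_um2 = float(obj.sum()) * mpp * mpp
        if not (params.min_area_um2 <= area_um2 <= params.max_area_um2):
            continue
        coords = np.column_stack(np.nonzero(obj)).astype(float)
        cy, cx = coords[:, 0].mean(), coords[:, 1].mean()
        off = (y0 + slc[0].start, x0 + slc[1].start)
        radii_um, poly = _star_polygon(coords, (cy, cx), mpp, offset_yx=off)
        center = ((cx + off[1]) * mpp, (cy + off[0]) * mpp)
        out.append(NucleusShape(center_um=center, radii_um=radii_um,
                                polygon=poly, area_um2=area_um2))
    out.sort(key=lambda n: (n.center_um[1], n.center_um[0]))
    return out


@dataclass
class CellGeometry:
    """One cell: nucleus plus expanded boundary and compartment areas (µm²)."""

    label: int
    nucleus: NucleusShape
    cell_polygon: Polygon
    centroid_um: tuple[float, float]
    nucleus_area_um2: float
    cell_area_um2: float
    membrane_area_um2: float
    cytoplasm_area_um2: float
    membrane_fallback: bool = False

    def to_geojson_feature(self) -> dict:
        return {
            "type": "Feature",
            "geometry": mapping(self.cell_polygon),
            "properties": {
                "label": self.label,
                "nucleus": mapping(self.nucleus.polygon),
                "centroid_um": list(self.centroid_um),
                "cell_area_um2": self.cell_area_um2,
                "nucleus_area_um2": self.nucleus_area_um2,
            },
        }


# compartment codes in CellPopulation.compartments
NUCLEUS, MEMBRANE, CYTOPLASM = 1, 2, 3


@dataclass
class CellPopulation:
    """Raster + vector view of all detected cells.

    ``nucleus_labels`` / ``cell_labels`` are full-frame int32 label images
    (0 = background); ``compartments`` codes each cell pixel as nucleus (1),
    membrane (2) or cytoplasm (3).  ``cells`` holds the per-cell geometry in
    detection order (labels are 1-based row indices into it).
    """

    cells: list[CellGeometry]
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    compartments: np.ndarray
    mpp: float

    def __len__(self) -> int:
        return len(self.cells)

    def to_geojson(self) -> dict:
        return {"type": "FeatureCollection",
                "features": [c.to_geojson_feature() for c in self.cells]}


def _rasterize_nuclei(nuclei: list[NucleusShape], shape: tuple[int, int],
                      mpp: float) -> np.ndarray:
    lab = np.zeros(shape, dtype=np.int32)
    for i, nuc in enumerate(nuclei, start=1):
        ext = np.asarray(nuc.polygon.exterior.coords) / mpp
        rr, cc = draw_polygon(ext[:, 1], ext[:, 0], shape=shape)
        lab[rr, cc] = i
    return lab


def _cell_contour_polygon(mask: np.ndarray, offset_yx: tuple[int, int],
                          mpp: float) -> Polygon:
    padded = np.pad(mask, 1)
    contours = find_contours(padded.astype(float), 0.5)
    if not contours:
        return Polygon()
    longest = max(contours, key=len)
    ys = (longest[:, 0] - 1 + offset_yx[0]) * mpp
    xs = (longest[:, 1] - 1 + offset_yx[1]) * mpp
    poly = Polygon(np.column_stack([xs, ys]))
    return poly if poly.is_valid else poly.buffer(0)


def expand_cells(nuclei: list[NucleusShape], expansion_um: float,
                 region: TissueAnnotation | np.ndarray, *, mpp: float,
                 image_shape: tuple[int, int] | None = None,
                 membrane_thickness_um: float = 1.0) -> CellPopulation:
    """Expand nuclei into non-overlapping cells and build compartments.

    Every pixel within ``expansion_um`` of a nucleus (and inside the region)
    joins the cell of its nearest nucleus, so cells are disjoint influence
    zones.  The membrane is the inward band of ``membrane_thickness_um`` at
    the cell boundary (excluding nucleus pixels); the cytoplasm is the rest.
    With ``expansion_um == 0`` the cell equals the nucleus and the membrane
    falls back to the nucleus-boundary band (flagged per cell).
    """
    if expansion_um < 0:
        raise ValueError("expansion must be non-negative")
    if isinstance(region, TissueAnnotation):
        image_shape = image_shape or region.grid.image_shape
        region_mask = region.pixel_mask(image_shape)
    else:
        region_mask = np.asarray(region, dtype=bool)
        image_shape = region_mask.shape

    nucleus_labels = _rasterize_nuclei(nuclei, image_shape, mpp)
    if not nuclei:
        z = np.zeros(image_shape, dtype=np.int32)
        return CellPopulation([], z, z.copy(), z.copy(), mpp)

    dist, (iy, ix) = ndimage.distance_transform_edt(
        nucleus_labels == 0, sampling=mpp, return_indices=True)
    cell_labels = nucleus_labels[iy, ix].astype(np.int32)
    # half-pixel margin: EDT measures between pixel centers, the expansion
    # distance is meant to the pixel footprint
    reach = expansion_um + 0.5 * mpp if expansion_um > 0 else 0.0
    cell_labels[dist > reach] = 0
    cell_labels[~region_mask & (nucleus_labels == 0)] = 0
    cell_labels[nucleus_labels > 0] = nucleus_labels[nucleus_labels > 0]

    # boundary pixels: cell pixel with a 4-neighbor of different label
    border = np.zeros(image_shape, dtype=bool)
    padded = np.pad(cell_labels, 1, constant_values=0)
    core = padded[1:-1, 1:-1]
    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = padded[1 + dy:padded.shape[0] - 1 + dy, 1 + dx:padded.shape[1] - 1 + dx]
        border |= (core != nb)
    border &= cell_labels > 0
    dist_border = ndimage.distance_transform_edt(~border, sampling=mpp)

    inside = cell_labels > 0
    comp = np.zeros(image_shape, dtype=np.int8)
    is_nuc = nucleus_labels > 0
    comp[inside & is_nuc] = NUCLEUS
    mem = inside & ~is_nuc & (dist_border <= membrane_thickness_um)
    comp[mem] = MEMBRANE
    comp[inside & ~is_nuc & ~mem] = CYTOPLASM

    n = len(nuclei)
    px_area = mpp * mpp
    nuc_areas = np.bincount(nucleus_labels.ravel(), minlength=n + 1)[1:] * px_area
    cell_areas = np.bincount(cell_labels.ravel(), minlength=n + 1)[1:] * px_area
    mem_areas = np.bincount(cell_labels.ravel(), weights=(comp == MEMBRANE).ravel(),
                            minlength=n + 1)[1:] * px_area
    cyt_areas = np.bincount(cell_labels.ravel(), weights=(comp == CYTOPLASM).ravel(),
                            minlength=n + 1)[1:] * px_area

    cells: list[CellGeometry] = []
    slices = ndimage.find_objects(cell_labels)
    for i, nuc in enumerate(nuclei, start=1):
        slc = slices[i - 1] if i - 1 < len(slices) else None
        if slc is None:
            continue
        mask = cell_labels[slc] == i
        poly = _cell_contour_polygon(mask, (slc[0].start, slc[1].start), mpp)
        fallback = mem_areas[i - 1] < px_area  # no membrane compartment
        cells.append(CellGeometry(
            label=i, nucleus=nuc, cell_polygon=poly, centroid_um=nuc.center_um,
            nucleus_area_um2=float(nuc_areas[i - 1]),
            cell_area_um2=float(cell_areas[i - 1]),
            membrane_area_um2=float(mem_areas[i - 1]),
            cytoplasm_area_um2=float(cyt_areas[i - 1]),
            membrane_fallback=bool(fallback)))
    return CellPopulation(cells, nucleus_labels, cell_labels, comp, mpp)
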