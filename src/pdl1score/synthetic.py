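"""Synthetic H-DAB histology with complete ground truth.

Generates brightfield-like slides of hematoxylin + DAB stained tissue at desk
scale so the whole scoring pipeline is testable without any external data:

* a tile-aligned mosaic of eight tissue textures (adipose, cartilage,
  epithelium, gland, immune, muscle, stroma, tumor) plus bare glass, each with
  distinct generative statistics on the hematoxylin channel;
* inside the tumor region, individually placed cells of three types with
  class-dependent nucleus size/shape and hematoxylin intensity — tumor nuclei
  large and pleomorphic, immune nuclei small and round, stromal nuclei
  elongated;
* DAB deposition matching the compartment rules being tested: a membranous
  ring on PD-L1-positive tumor cells (ring width = the scoring pipeline's
  default membrane thickness) and whole-cell staining on positive immune
  cells;
* known ground truth: per-cell table, region masks, and realized TPS/CPS/ICS
  computed from the truth table with the same scoring code used on real
  output (self-consistent by construction).

Positive cells are assigned by exact count (TPS) and greedy area matching
(ICS), so realized scores land within ±2 points of the recipe targets or the
recipe errors out as unreachable.  All randomness flows from one integer seed
through named substreams, so sub-generators are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon

from .scoring import ScoreReport, compute_scores
from .stain import HDAB_DEFAULT, RGBImage, od_to_rgb
from .tissue import CLASS_ORDER, TissueClass

__all__ = [
    "CellClassParams",
    "SlideRecipe",
    "SlideTruth",
    "generate_slide",
    "generate_tile_dataset",
    "generate_rater_scores",
    "standard_panel_recipes",
    "DEFAULT_MPP",
]

DEFAULT_MPP = 0.5  # µm per pixel of the synthetic material


def _rng(seed: int, *keys: int) -> np.random.Generator:
    """Counter-based substream: one root seed, named integer subkeys."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


@dataclass
class CellClassParams:
    """Generative parameters of one cell type inside the tumor region."""

    density_per_mm2: float
    radius_um_mean: float
    radius_um_sd: float
    aspect_range: tuple[float, float]
    od_h: float

    def __post_init__(self):
        if self.density_per_mm2 < 0:
            raise ValueError("density must be >= 0")


def default_cell_params() -> dict[str, CellClassParams]:
    # densities keep the majority of nuclei non-touching (the generator's
    # minimum spacing is 1.5x the mean nucleus radius, so touching pairs occur
    # but do not dominate)
    return {
        "TUMOR": CellClassParams(1400.0, 5.0, 0.9, (1.0, 2.0), 0.75),
        "IMMUNE": CellClassParams(450.0, 2.8, 0.3, (1.0, 1.2), 0.95),
        "STROMAL": CellClassParams(350.0, 3.2, 0.4, (2.5, 4.0), 0.50),
    }


@dataclass
class SlideRecipe:
    """Everything needed to synthesize one slide deterministically."""

    width_um: float = 1280.0
    height_um: float = 1280.0
    mpp: float = DEFAULT_MPP
    tile_size_um: float = 256.0
    n_tumor_tiles: int = 10
    glass_fraction: float = 0.25
    target_tps: float = 25.0
    target_ics: float = 2.0
    cell_params: dict = field(default_factory=default_cell_params)
    dab_od_tumor_membrane: float = 0.8
    dab_od_immune: float = 0.6
    expansion_um: float = 5.0
    membrane_um: float = 1.0
    stroma_od: float = 0.04
    noise_sd: float = 0.02
    background_rgb: tuple = (242, 242, 242)
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.target_tps <= 100):
            raise ValueError("target_tps must be in [0, 100]")
        if self.target_ics < 0:
            raise ValueError("target_ics must be >= 0")
        nr = int(self.height_um // self.tile_size_um)
        nc = int(self.width_um // self.tile_size_um)
        if self.n_tumor_tiles > nr * nc:
            raise ValueError("more tumor tiles than grid cells")


@dataclass
class SlideTruth:
    """Ground truth of one synthetic slide."""

    tile_classes: np.ndarray          # (nr, nc) object array: class name or "GLASS"
    tile_size_um: float
    mpp: float
    tumor_area_um2: float
    cells: pd.DataFrame               # per-cell table incl. 'positive'
    nucleus_polygons: list[Polygon]
    cell_polygons: list[Polygon]
    report: ScoreReport

    @property
    def tumor_tile_mask(self) -> np.ndarray:
        return self.tile_classes == TissueClass.TUM.value

    def region_mask(self, tissue_class: str) -> np.ndarray:
        return self.tile_classes == str(tissue_class)

    def tumor_pixel_mask(self, shape: tuple[int, int]) -> np.ndarray:
        tp = int(round(self.tile_size_um / self.mpp))
        mask = np.zeros(shape, dtype=bool)
        for r, c in zip(*np.nonzero(self.tumor_tile_mask)):
            mask[r * tp:(r + 1) * tp, c * tp:(c + 1) * tp] = True
        return mask

    @property
    def tps(self) -> float | None:
        return self.report.tps

    @property
    def cps(self) -> float | None:
        return self.report.cps

    @property
    def ics(self) -> float:
        return self.report.ics


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ellipse_polygon(cx: float, cy: float, a_um: float, b_um: float,
                     angle: float, n: int = 24) -> Polygon:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = a_um * np.cos(t)
    y = b_um * np.sin(t)
    xr = cx + x * np.cos(angle) - y * np.sin(angle)
    yr = cy + x * np.sin(angle) + y * np.cos(angle)
    return Polygon(np.column_stack([xr, yr]))


def _draw_ellipse(od: np.ndarray, cx_um: float, cy_um: float, a_um: float,
                  b_um: float, angle: float, value: float, mpp: float) -> None:
    # a_um is the semi-axis along x at angle 0 (matches _ellipse_polygon);
    # skimage wants (row_radius, col_radius) and the opposite rotation sign
    from skimage.draw import ellipse
    rr, cc = ellipse(cy_um / mpp, cx_um / mpp, max(b_um / mpp, 1.0),
                     max(a_um / mpp, 1.0), shape=od.shape, rotation=-angle)
    od[rr, cc] = np.maximum(od[rr, cc], value)


def _draw_ring(od: np.ndarray, cx_um: float, cy_um: float, r_um: float,
               w_um: float, value: float, mpp: float) -> None:
    from skimage.draw import disk
    cy, cx = cy_um / mpp, cx_um / mpp
    rr, cc = disk((cy, cx), max(r_um / mpp, 1.5), shape=od.shape)
    outer = set(zip(rr.tolist(), cc.tolist()))
    rr2, cc2 = disk((cy, cx), max((r_um - w_um) / mpp, 0.5), shape=od.shape)
    inner = set(zip(rr2.tolist(), cc2.tolist()))
    ring = outer - inner
    if ring:
        ys, xs = zip(*ring)
        od[list(ys), list(xs)] = np.maximum(od[list(ys), list(xs)], value)


def _sample_positions(allowed: np.ndarray, mpp: float, n_target: int,
                      min_spacing_um: float, rng: np.random.Generator,
                      max_tries_factor: int = 40) -> np.ndarray:
    """Poisson-disc-style dart throwing inside a boolean mask.

    Returns up to ``n_target`` (x, y) positions in µm with pairwise distance
    >= ``min_spacing_um``, using a hash grid for O(1) conflict checks.
    """
    ys, xs = np.nonzero(allowed)
    if len(ys) == 0 or n_target <= 0:
        return np.empty((0, 2))
    cell = min_spacing_um / np.sqrt(2.0)
    grid: dict[tuple[int, int], tuple[float, float]] = {}
    pts: list[tuple[float, float]] = []
    tries = int(n_target * max_tries_factor)
    choice = rng.integers(0, len(ys), size=tries)
    jitter = rng.uniform(0, 1, size=(tries, 2))
    s2 = min_spacing_um ** 2
    for t in range(tries):
        i = choice[t]
        x = (xs[i] + jitter[t, 0]) * mpp
        y = (ys[i] + jitter[t, 1]) * mpp
        gx, gy = int(x / cell), int(y / cell)
        ok = True
        for dgx in (-2, -1, 0, 1, 2):
            for dgy in (-2, -1, 0, 1, 2):
                p = grid.get((gx + dgx, gy + dgy))
                if p is not None and (p[0] - x) ** 2 + (p[1] - y) ** 2 < s2:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            grid[(gx, gy)] = (x, y)
            pts.append((x, y))
            if len(pts) >= n_target:
                break
    return np.asarray(pts)


def _make_cells(allowed_px: np.ndarray, mpp: float, cell_params: dict,
                rng: np.random.Generator, margin_um: float = 6.0) -> pd.DataFrame:
    """Place a mixed cell population inside a mask; returns the truth table."""
    area_mm2 = allowed_px.sum() * mpp * mpp / 1e6
    params = {k: v for k, v in cell_params.items() if v.density_per_mm2 > 0}
    counts = {k: int(round(v.density_per_mm2 * area_mm2)) for k, v in params.items()}
    n_total = sum(counts.values())
    if n_total == 0:
        return pd.DataFrame(columns=["cell_class", "x_um", "y_um", "radius_um",
                                     "aspect", "angle", "od_h"])
    mean_r = (sum(v.radius_um_mean * counts[k] for k, v in params.items()) / n_total)
    spacing = 1.5 * mean_r
    if margin_um > 0:
        dist_in = ndimage.distance_transform_edt(allowed_px) * mpp
        inner = dist_in >= margin_um
        if not inner.any():
            inner = allowed_px
    else:
        inner = allowed_px
    pts = _sample_positions(inner, mpp, n_total, spacing, rng)
    got = len(pts)
    if got < n_total:  # keep class proportions when space runs short
        frac = got / n_total
        counts = {k: int(round(c * frac)) for k, c in counts.items()}
        while sum(counts.values()) > got:
            counts[max(counts, key=counts.get)] -= 1
    classes = np.concatenate([[k] * c for k, c in counts.items()]) if counts else np.array([])
    classes = classes[:got]
    pts = pts[:len(classes)]
    perm = rng.permutation(len(classes))
    classes = classes[perm]

    rows = []
    for (x, y), cls in zip(pts, classes):
        p = params[cls]
        r = float(np.clip(rng.normal(p.radius_um_mean, p.radius_um_sd),
                          1.5, p.radius_um_mean + 3 * p.radius_um_sd))
        aspect = float(rng.uniform(*p.aspect_range))
        angle = float(rng.uniform(0, np.pi))
        od = float(p.od_h * rng.uniform(0.85, 1.15))
        rows.append((cls, x, y, r, aspect, angle, od))
    return pd.DataFrame(rows, columns=["cell_class", "x_um", "y_um", "radius_um",
                                       "aspect", "angle", "od_h"])


# ---------------------------------------------------------------------------
# tissue textures (hematoxylin OD per class)
# ---------------------------------------------------------------------------

def render_texture(tissue_class: str, shape_px: tuple[int, int], mpp: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Hematoxylin-OD texture of one tissue class (no noise added here)."""
    od = np.zeros(shape_px, dtype=float)
    h_um = shape_px[0] * mpp
    w_um = shape_px[1] * mpp
    area_mm2 = h_um * w_um / 1e6
    cls = str(tissue_class)

    def uniform_xy(n):
        return rng.uniform(0, w_um, n), rng.uniform(0, h_um, n)

    if cls == "ADI":
        # sparse large vacuole outlines
        n = max(3, int(round(120 * area_mm2)))
        xs, ys = uniform_xy(n)
        for x, y in zip(xs, ys):
            _draw_ring(od, x, y, rng.uniform(20, 45), 1.6, 0.35, mpp)
    elif cls == "CHR":
        # isolated lacunae in a faint uniform matrix
        od[:] = 0.12
        n = max(4, int(round(180 * area_mm2)))
        xs, ys = uniform_xy(n)
        for x, y in zip(xs, ys):
            _draw_ellipse(od, x, y, rng.uniform(5, 8), rng.uniform(5, 8), 0.0, 0.02, mpp)
            od_nuc = 0.85 * rng.uniform(0.9, 1.1)
            r = rng.uniform(3.0, 4.0)
            _draw_ellipse_over(od, x, y, r, r, 0.0, od_nuc, mpp)
    elif cls == "EPI":
        # layered bands of nuclei along a common orientation
        theta = rng.uniform(0, np.pi)
        spacing, along = 12.0, 7.0
        diag = np.hypot(h_um, w_um)
        n_lines = int(diag / spacing) + 2
        for li in range(-n_lines, n_lines):
            offset = li * spacing + rng.normal(0, 1.0)
            for s in np.arange(-diag, diag, along):
                x = w_um / 2 + s * np.cos(theta) - offset * np.sin(theta) + rng.normal(0, 1.2)
                y = h_um / 2 + s * np.sin(theta) + offset * np.cos(theta) + rng.normal(0, 1.2)
                if -5 <= x <= w_um + 5 and -5 <= y <= h_um + 5:
                    r = rng.uniform(2.6, 3.4)
                    _draw_ellipse(od, x, y, r, r * 0.8, theta, 0.7 * rng.uniform(0.9, 1.1), mpp)
    elif cls == "GLD":
        # rings of nuclei around empty lumina
        n = max(3, int(round(100 * area_mm2)))
        xs, ys = uniform_xy(n)
        for x, y in zip(xs, ys):
            ring_r = rng.uniform(15, 30)
            for phi in np.arange(0, 2 * np.pi, 7.0 / ring_r):
                px = x + ring_r * np.cos(phi) + rng.normal(0, 0.6)
                py = y + ring_r * np.sin(phi) + rng.normal(0, 0.6)
                _draw_ellipse(od, px, py, 2.8, 2.2, phi, 0.7 * rng.uniform(0.9, 1.1), mpp)
    elif cls == "IMU":
        mix = {"IMMUNE": CellClassParams(7000.0, 2.5, 0.25, (1.0, 1.15), 0.95)}
        cells = _make_cells(np.ones(shape_px, dtype=bool), mpp, mix, rng, margin_um=0.0)
        _draw_nuclei(od, cells, mpp)
    elif cls == "MUS":
        # oriented fibers plus sparse aligned nuclei
        theta = rng.uniform(0, np.pi)
        yy, xx = np.mgrid[0:shape_px[0], 0:shape_px[1]]
        xu = xx * mpp
        yu = yy * mpp
        perp = -xu * np.sin(theta) + yu * np.cos(theta)
        phase = np.mod(perp + rng.uniform(0, 8.0), 8.0)
        od[phase < 3.0] = 0.30
        mix = {"STROMAL": CellClassParams(500.0, 3.5, 0.3, (3.0, 4.0), 0.6)}
        cells = _make_cells(np.ones(shape_px, dtype=bool), mpp, mix, rng, margin_um=0.0)
        cells["angle"] = theta
        _draw_nuclei(od, cells, mpp)
    elif cls == "STR":
        od[:] = 0.03
        mix = {"STROMAL": CellClassParams(800.0, 3.2, 0.4, (2.5, 4.0), 0.55)}
        cells = _make_cells(np.ones(shape_px, dtype=bool), mpp, mix, rng, margin_um=0.0)
        _draw_nuclei(od, cells, mpp)
    elif cls == "TUM":
        cells = _make_cells(np.ones(shape_px, dtype=bool), mpp,
                            default_cell_params(), rng, margin_um=0.0)
        _draw_nuclei(od, cells, mpp)
    elif cls == "GLASS":
        pass
    else:
        raise ValueError(f"unknown tissue class: {tissue_class}")
    return od


def _draw_ellipse_over(od, cx_um, cy_um, a_um, b_um, angle, value, mpp):
    from skimage.draw import ellipse
    rr, cc = ellipse(cy_um / mpp, cx_um / mpp, max(b_um / mpp, 1.0),
                     max(a_um / mpp, 1.0), shape=od.shape, rotation=-angle)
    od[rr, cc] = value


def _draw_nuclei(od: np.ndarray, cells: pd.DataFrame, mpp: float) -> None:
    for rec in cells.itertuples(index=False):
        a = rec.radius_um * np.sqrt(rec.aspect)
        b = rec.radius_um / np.sqrt(rec.aspect)
        _draw_ellipse(od, rec.x_um, rec.y_um, a, b, rec.angle, rec.od_h, mpp)


# ---------------------------------------------------------------------------
# slide assembly
# ---------------------------------------------------------------------------

def _layout_tiles(nr: int, nc: int, n_tumor: int, glass_fraction: float,
                  rng: np.random.Generator) -> np.ndarray:
    grid = np.full((nr, nc), "", dtype=object)
    start = (int(rng.integers(0, nr)), int(rng.integers(0, nc)))
    blob = {start}
    while len(blob) < n_tumor:
        r, c = sorted(blob)[rng.integers(0, len(blob))]
        opts = [(r + dr, c + dc) for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if 0 <= r + dr < nr and 0 <= c + dc < nc and (r + dr, c + dc) not in blob]
        if opts:
            blob.add(opts[rng.integers(0, len(opts))])
    # keep the tumor region simply connected: scoring treats enclosed
    # non-tumor tiles as labelmap gaps and fills them, so the truth region
    # must not contain any
    mask = np.zeros((nr, nc), dtype=bool)
    mask[tuple(zip(*blob))] = True
    mask = ndimage.binary_fill_holes(mask)
    for r, c in zip(*np.nonzero(mask)):
        grid[r, c] = TissueClass.TUM.value
    others = [cl for cl in CLASS_ORDER if cl != TissueClass.TUM.value]
    for r in range(nr):
        for c in range(nc):
            if grid[r, c]:
                continue
            if rng.uniform() < glass_fraction:
                cls = "GLASS"
            else:
                cls = others[rng.integers(0, len(others))]
            # grow a small coherent patch
            patch = [(r, c)]
            for _ in range(int(rng.integers(1, 4))):
                rr, cc = patch[-1]
                opts = [(rr + dr, cc + dc) for dr, dc in ((1, 0), (0, 1))
                        if rr + dr < nr and cc + dc < nc and not grid[rr + dr, cc + dc]]
                if not opts:
                    break
                patch.append(opts[rng.integers(0, len(opts))])
            for pr, pc in patch:
                grid[pr, pc] = cls
    return grid


def _assign_positives(cells: pd.DataFrame, cell_polygons: list[Polygon],
                      recipe: SlideRecipe, tumor_area_um2: float,
                      rng: np.random.Generator) -> pd.DataFrame:
    cells = cells.copy()
    cells["cell_area_um2"] = [p.area for p in cell_polygons]
    cells["nucleus_area_um2"] = [
        np.pi * r * r for r in cells["radius_um"]]
    cells["positive"] = False

    tum_idx = cells.index[cells["cell_class"] == "TUMOR"].to_numpy()
    n_pos = int(round(recipe.target_tps / 100.0 * len(tum_idx)))
    if recipe.target_tps > 0 and len(tum_idx) == 0:
        raise ValueError("targets unreachable: positive TPS requested with no tumor cells")
    if n_pos > 0:
        chosen = rng.permutation(tum_idx)[:n_pos]
        cells.loc[chosen, "positive"] = True

    imm_idx = cells.index[cells["cell_class"] == "IMMUNE"].to_numpy()
    target_area = recipe.target_ics / 100.0 * tumor_area_um2
    if recipe.target_ics > 0 and len(imm_idx) == 0:
        raise ValueError("targets unreachable: positive ICS requested with no immune cells")
    if target_area > 0:
        order = rng.permutation(imm_idx)
        areas = cells.loc[order, "cell_area_um2"].to_numpy()
        cum = np.cumsum(areas)
        m = int(np.argmin(np.abs(cum - target_area))) + 1
        realized_area = cum[m - 1]
        if abs(100.0 * realized_area / tumor_area_um2 - recipe.target_ics) > 2.0:
            raise ValueError("targets unreachable: immune area cannot match the ICS target")
        cells.loc[order[:m], "positive"] = True
    return cells


def generate_slide(recipe: SlideRecipe, render_image: bool = True
                   ) -> tuple[RGBImage | None, SlideTruth]:
    """Synthesize one slide and its ground truth.

    Deterministic per recipe seed (bit-identical image and truth).  With
    ``render_image=False`` only the truth (layout + cell table + realized
    scores) is produced, which is much faster and sufficient for testing the
    scoring arithmetic.
    """
    mpp = recipe.mpp
    tp = int(round(recipe.tile_size_um / mpp))
    nr = int(recipe.height_um // recipe.tile_size_um)
    nc = int(recipe.width_um // recipe.tile_size_um)
    H, W = nr * tp, nc * tp

    grid = _layout_tiles(nr, nc, recipe.n_tumor_tiles, recipe.glass_fraction,
                         _rng(recipe.seed, 1))
    tile_area_um2 = (tp * mpp) ** 2
    tumor_area_um2 = float((grid == TissueClass.TUM.value).sum()) * tile_area_um2

    tumor_mask = np.zeros((H, W), dtype=bool)
    for r, c in zip(*np.nonzero(grid == TissueClass.TUM.value)):
        tumor_mask[r * tp:(r + 1) * tp, c * tp:(c + 1) * tp] = True

    cells = _make_cells(tumor_mask, mpp, recipe.cell_params, _rng(recipe.seed, 2),
                        margin_um=recipe.expansion_um + 2.0)
    nucleus_polygons = []
    cell_polygons = []
    for rec in cells.itertuples(index=False):
        a = rec.radius_um * np.sqrt(rec.aspect)
        b = rec.radius_um / np.sqrt(rec.aspect)
        nuc = _ellipse_polygon(rec.x_um, rec.y_um, a, b, rec.angle)
        nucleus_polygons.append(nuc)
        cell_polygons.append(nuc.buffer(recipe.expansion_um, quad_segs=6))

    cells = _assign_positives(cells, cell_polygons, recipe, tumor_area_um2,
                              _rng(recipe.seed, 3))
    cells["nucleus_area_um2"] = [p.area for p in nucleus_polygons]
    report = compute_scores(cells, tumor_area_um2)
    truth = SlideTruth(tile_classes=grid, tile_size_um=recipe.tile_size_um,
                       mpp=mpp, tumor_area_um2=tumor_area_um2, cells=cells,
                       nucleus_polygons=nucleus_polygons,
                       cell_polygons=cell_polygons, report=report)
    if not render_image:
        return None, truth

    od_h = np.zeros((H, W), dtype=float)
    od_d = np.zeros((H, W), dtype=float)
    tex_rng = _rng(recipe.seed, 4)
    for r in range(nr):
        for c in range(nc):
            cls = grid[r, c]
            if cls in (TissueClass.TUM.value, "GLASS"):
                continue
            sub = render_texture(cls, (tp, tp), mpp, tex_rng)
            od_h[r * tp:(r + 1) * tp, c * tp:(c + 1) * tp] = sub

    # faint stromal texture inside the tumor region
    field_rng = _rng(recipe.seed, 5)
    coarse = field_rng.normal(0, 1, (H // 16 + 1, W // 16 + 1))
    coarse = ndimage.zoom(coarse, 16, order=1)[:H, :W]
    od_h[tumor_mask] += np.clip(recipe.stroma_od * (1 + 0.5 * coarse[tumor_mask]), 0, None)

    _draw_nuclei(od_h, cells, mpp)

    # DAB deposition
    mem_px = max(1, int(round(recipe.membrane_um / mpp)))
    struct = ndimage.generate_binary_structure(2, 1)
    from skimage.draw import polygon as draw_polygon
    for i, rec in enumerate(cells.itertuples(index=False)):
        if not rec.positive:
            continue
        poly = cell_polygons[i]
        ext = np.asarray(poly.exterior.coords) / mpp
        y0 = max(int(ext[:, 1].min()) - 2, 0)
        x0 = max(int(ext[:, 0].min()) - 2, 0)
        y1 = min(int(ext[:, 1].max()) + 3, H)
        x1 = min(int(ext[:, 0].max()) + 3, W)
        sub_shape = (y1 - y0, x1 - x0)
        rr, cc = draw_polygon(ext[:, 1] - y0, ext[:, 0] - x0, shape=sub_shape)
        mask = np.zeros(sub_shape, dtype=bool)
        mask[rr, cc] = True
        if rec.cell_class == "IMMUNE":
            val = recipe.dab_od_immune
            target = mask
        else:  # positive tumor cell: membranous ring only
            val = recipe.dab_od_tumor_membrane
            inner = ndimage.binary_erosion(mask, structure=struct, iterations=mem_px)
            target = mask & ~inner
        block = od_d[y0:y1, x0:x1]
        block[target] = np.maximum(block[target], val)

    noise_rng = _rng(recipe.seed, 6)
    od_h = np.clip(od_h + noise_rng.normal(0, recipe.noise_sd, od_h.shape), 0, None)
    od_d = np.clip(od_d + noise_rng.normal(0, recipe.noise_sd, od_d.shape), 0, None)
    image = od_to_rgb(od_h, od_d, HDAB_DEFAULT, recipe.background_rgb, mpp)
    return image, truth


def generate_tile_dataset(n_per_class: int, tile_size_um: float = 256.0,
                          seed: int = 0, mpp: float = DEFAULT_MPP,
                          noise_sd: float = 0.02
                          ) -> tuple[list[np.ndarray], np.ndarray]:
    """Labeled hematoxylin-OD training tiles for all eight tissue classes."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    tp = int(round(tile_size_um / mpp))
    tiles: list[np.ndarray] = []
    labels: list[str] = []
    for ci, cls in enumerate(CLASS_ORDER):
        rng = _rng(seed, 10, ci)
        for _ in range(n_per_class):
            t = render_texture(cls, (tp, tp), mpp, rng)
            t = np.clip(t + rng.normal(0, noise_sd, t.shape), 0, None)
            tiles.append(t)
            labels.append(cls)
    return tiles, np.asarray(labels)


def standard_panel_recipes(seed: int = 0) -> list[SlideRecipe]:
    """The ten-slide evaluation panel: TPS spanning 0–95% with varied ICS."""
    targets = [(0.0, 0.0), (5.0, 1.0), (25.0, 2.0), (60.0, 3.0), (95.0, 5.0)]
    recipes = []
    for rep in range(2):
        for j, (tps, ics) in enumerate(targets):
            recipes.append(SlideRecipe(seed=seed + 100 * rep + j,
                                       target_tps=tps, target_ics=ics))
    return recipes


def generate_rater_scores(truth_scores, n_raters: int = 4, noise_sd: float = 5.0,
                          rounding: bool = False, seed: int = 0,
                          valid_range: tuple[float, float] = (0.0, 100.0)
                          ) -> pd.DataFrame:
    """Simulated rater table: truth plus Gaussian noise, clipped to range.

    With ``rounding=True`` scores snap to the preferred values human raters
    gravitate to (0, 1, then multiples of 5) — the "number preference" bias.
    The noise field is scaled from one seeded draw, so increasing ``noise_sd``
    at a fixed seed degrades agreement monotonically.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    truth = np.asarray(truth_scores, dtype=float)
    z = _rng(seed, 20).standard_normal((len(truth), n_raters))
    scores = np.clip(truth[:, None] + noise_sd * z, *valid_range)
    if rounding:
        preferred = np.array([0.0, 1.0] + list(np.arange(5.0, valid_range[1] + 1e-9, 5.0)))
        idx = np.argmin(np.abs(scores[..., None] - preferred), axis=-1)
        scores = preferred[idx]
    return pd.DataFrame(scores, columns=[f"rater_{i+1}" for i in range(n_raters)])
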