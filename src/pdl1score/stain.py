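"""Optical-density math for brightfield H-DAB images.

Brightfield chromogens obey Beer–Lambert absorption: the optical density
``OD_c = log10(background_c / intensity_c)`` of each RGB channel is linear in
the amount of stain, so a pixel's 3-vector OD is a non-negative combination of
per-stain unit vectors.  This module converts RGB to OD, separates hematoxylin
(blue nuclear counterstain) from DAB (brown PD-L1 chromogen) by projecting on
a stain basis, and inverts the transform for image synthesis.

OD is computed in log10 so thresholds are on the scale used throughout the
IHC quantification literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RGBImage",
    "ODImage",
    "StainMatrix",
    "HDAB_DEFAULT",
    "estimate_background",
    "rgb_to_od",
    "deconvolve",
    "od_to_rgb",
]


@dataclass
class RGBImage:
    """A calibrated RGB brightfield image.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` array of intensities in ``[0, 255]``.
    mpp
        Pixel calibration in micrometres per pixel (isotropic).
    """

    pixels: np.ndarray
    mpp: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if not (float(self.mpp) > 0):
            raise ValueError("mpp must be > 0")
        self.mpp = float(self.mpp)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class ODImage:
    """Per-stain optical densities with calibration.

    ``od_h`` and ``od_d`` are the hematoxylin and DAB loadings (log10 OD,
    clipped at 0) at every pixel; ``background_rgb`` is the white point that
    was used to compute them.
    """

    od_h: np.ndarray
    od_d: np.ndarray
    mpp: float
    background_rgb: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.od_h = np.asarray(self.od_h, dtype=float)
        self.od_d = np.asarray(self.od_d, dtype=float)
        if self.od_h.shape != self.od_d.shape:
            raise ValueError("od_h and od_d must have the same shape")
        if not (float(self.mpp) > 0):
            raise ValueError("mpp must be > 0")
        bg = tuple(float(v) for v in self.background_rgb)
        if len(bg) != 3 or any(not (0 < v <= 255) for v in bg):
            raise ValueError("background_rgb channel values must lie in (0, 255]")
        self.background_rgb = bg
        self.mpp = float(self.mpp)

    @property
    def shape(self) -> tuple[int, int]:
        return self.od_h.shape


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass
class StainMatrix:
    """Unit stain vectors in OD space (columns: hematoxylin, DAB, residual).

    The default basis is the standard Ruifrok–Johnston H-DAB basis; a residual
    (complementary) vector is derived as the normalized cross product when not
    given so the matrix is always invertible for independent H/DAB vectors.
    """

    hematoxylin: np.ndarray = field(default_factory=lambda: _unit([0.650, 0.704, 0.286]))
    dab: np.ndarray = field(default_factory=lambda: _unit([0.269, 0.568, 0.778]))
    residual: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hematoxylin = _unit(self.hematoxylin)
        self.dab = _unit(self.dab)
        cross = np.cross(self.hematoxylin, self.dab)
        if np.linalg.norm(cross) < 1e-9:
            raise ValueError("hematoxylin and DAB vectors are linearly dependent")
        if self.residual is None:
            self.residual = _unit(cross)
        else:
            self.residual = _unit(self.residual)

    @property
    def matrix(self) -> np.ndarray:
        """3x3 matrix with stain vectors as columns."""
        return np.column_stack([self.hematoxylin, self.dab, self.residual])


HDAB_DEFAULT = StainMatrix()


def estimate_background(image: RGBImage, min_luminance: float = 100.0) -> tuple[int, int, int]:
    """Estimate the white point from the glass/background region.

    Takes, per channel, the modal intensity among pixels whose luminance lies
    in the top decile of the image.  Raises if no pixel exceeds
    ``min_luminance`` (the caller may then supply an explicit white point).
    """
    px = np.asarray(image.pixels, dtype=float).reshape(-1, 3)
    lum = px @ np.array([0.299, 0.587, 0.114])
    if lum.max() < min_luminance:
        raise ValueError("no background found: no pixel above minimal luminance")
    cutoff = np.quantile(lum, 0.9)
    bright = px[lum >= cutoff].astype(np.int64)
    bg = tuple(int(np.bincount(np.clip(bright[:, c], 0, 255), minlength=256).argmax())
               for c in range(3))
    if any(v <= 0 for v in bg):
        raise ValueError("estimated background contains a non-positive channel")
    return bg


def rgb_to_od(image: RGBImage, background_rgb) -> np.ndarray:
    """Convert RGB intensities to raw 3-channel optical density.

    ``OD_c = log10(background_c / max(pixel_c, 1))`` per channel, clipped below
    at 0 (pixels brighter than the white point carry no stain).
    """
    bg = np.asarray(background_rgb, dtype=float)
    if bg.shape != (3,) or np.any(bg <= 0):
        raise ValueError("background_rgb must be three positive values")
    px = np.maximum(np.asarray(image.pixels, dtype=float), 1.0)
    od = np.log10(bg / px)
    return np.clip(od, 0.0, None)


def deconvolve(raw_od: np.ndarray, matrix: StainMatrix | None = None, *,
               mpp: float = 1.0, background_rgb=(255.0, 255.0, 255.0)) -> ODImage:
    """Separate raw OD into hematoxylin and DAB loadings.

    Per-pixel least-squares projection of the OD 3-vector onto the stain
    basis; negative loadings are clipped to 0.
    """
    matrix = matrix or HDAB_DEFAULT
    m = matrix.matrix
    if abs(np.linalg.det(m)) < 1e-9:
        raise ValueError("singular stain matrix")
    raw = np.asarray(raw_od, dtype=float)
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise ValueError("raw_od must be (H, W, 3)")
    loadings = raw.reshape(-1, 3) @ np.linalg.inv(m).T
    loadings = np.clip(loadings, 0.0, None).reshape(raw.shape)
    return ODImage(od_h=loadings[..., 0], od_d=loadings[..., 1],
                   mpp=mpp, background_rgb=tuple(background_rgb))


def rgb_image_to_od(image: RGBImage, matrix: StainMatrix | None = None,
                    background_rgb=None) -> ODImage:
    """Convenience composition: estimate background, compute OD, deconvolve."""
    if background_rgb is None:
        background_rgb = estimate_background(image)
    raw = rgb_to_od(image, background_rgb)
    return deconvolve(raw, matrix, mpp=image.mpp, background_rgb=background_rgb)


def od_to_rgb(od_h: np.ndarray, od_d: np.ndarray, matrix: StainMatrix | None = None,
              background_rgb=(255.0, 255.0, 255.0), mpp: float = 1.0) -> RGBImage:
    """Compose per-stain OD maps back into an RGB image.

    ``pixel_c = background_c * 10**-(od_h * H_c + od_d * D_c)``, rounded to
    integers in ``[0, 255]``.  Inverse of :func:`rgb_to_od` +
    :func:`deconvolve` up to quantization.
    """
    matrix = matrix or HDAB_DEFAULT
    od_h = np.asarray(od_h, dtype=float)
    od_d = np.asarray(od_d, dtype=float)
    if od_h.shape != od_d.shape:
        raise ValueError("od_h and od_d shapes differ")
    if np.any(od_h < 0) or np.any(od_d < 0):
        raise ValueError("OD maps must be non-negative")
    bg = np.asarray(background_rgb, dtype=float)
    total = od_h[..., None] * matrix.hematoxylin + od_d[..., None] * matrix.dab
    px = bg * np.power(10.0, -total)
    px = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    return RGBImage(pixels=px, mpp=mpp)
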