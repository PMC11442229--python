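"""Canonical berry-shape class templates.

Cranberry evaluators score the largest berry against five reference
silhouettes (round, oblate, oval, pyriform, spindle). The published
reference bitmaps are not available, so the templates here are synthetic
stand-ins: parametric radial silhouettes rasterized at run time that
reproduce the qualitative geometry of each class (aspect ratio and
axial asymmetry). They are normalized to a common centroid and area before
use, exactly like user-supplied rasters.
"""

from __future__ import annotations

import numpy as np

from cranqtl.chimera import normalize_shape

#: shape-class identifiers in scoring order
SHAPE_CLASSES = (1, 2, 3, 4, 5)

SHAPE_CLASS_NAMES = {
    1: "round",
    2: "oblate",
    3: "oval",
    4: "pyriform",
    5: "spindle",
}


def _raster_radial(rx: float, ry: float, taper: float, size: int) -> np.ndarray:
    """Rasterize r(theta) = ellipse(rx, ry) * (1 + taper * sin(theta))."""
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - c, xx - c
    theta = np.arctan2(dy, dx)
    r_ell = (rx * ry) / np.sqrt((ry * np.cos(theta)) ** 2 + (rx * np.sin(theta)) ** 2)
    radius = r_ell * (1.0 + taper * np.sin(theta))
    return (np.hypot(dy, dx) <= radius).astype(np.uint8)


_PARAMS = {
    1: (70.0, 70.0, 0.00),   # round: circle
    2: (80.0, 58.0, 0.00),   # oblate: wider than tall
    3: (58.0, 80.0, 0.00),   # oval: taller than wide
    4: (58.0, 80.0, 0.25),   # pyriform: oval with a tapered (pear) end
    5: (48.0, 88.0, 0.10),   # spindle: elongated, slightly asymmetric
}


def raw_template(class_id: int, size: int = 256) -> np.ndarray:
    """Un-normalized binary silhouette for one shape class."""
    if class_id not in _PARAMS:
        raise KeyError(f"unknown shape class {class_id!r}")
    rx, ry, taper = _PARAMS[class_id]
    scale = size / 256.0   # radii are calibrated on a 256-pixel raster
    return _raster_radial(rx * scale, ry * scale, taper, size=size)


def shape_templates(size: int = 256, target_area: int = 12_000) -> dict[int, np.ndarray]:
    """All five class templates, normalized to a common centroid and area."""
    return {cid: normalize_shape(raw_template(cid, size), target_area)
            for cid in SHAPE_CLASSES}


def load_template(path) -> np.ndarray:
    """Load a user raster (PNG/PGM/TIFF) as a binary {0,1} image."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    return (arr > arr.max() / 2).astype(np.uint8)
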